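"""Trial screening, congruency effects and distributional curves.

Screening follows the conventional two-step rule for speeded conflict tasks:
response times below 150 ms are discarded as anticipations and above 2000 ms
as misses (strict inequalities — the boundary values are retained), and
participants whose overall pre-trim accuracy falls below 65% are excluded.

The congruency effect (CE) is each participant's mean correct incongruent RT
minus mean correct congruent RT.  Conditional accuracy functions (CAFs) bin
all responses — correct and error — by within-condition RT quantiles and
report accuracy per bin; delta plots take correct trials only and report the
incongruent-minus-congruent RT difference per decile.  Group curves are
Vincentized: per-participant bin values averaged bin-wise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import CONDITIONS

__all__ = [
    "ScreeningReport",
    "CongruencyEffect",
    "trim_trials",
    "exclude_participants",
    "congruency_effect",
    "congruency_effects",
    "conditional_accuracy_function",
    "group_caf",
    "delta_plot",
]

ANTICIPATION_MS = 150.0
MISS_MS = 2000.0
MIN_ACCURACY = 0.65


@dataclass
class ScreeningReport:
    """Counts of trials removed by the RT screen, overall and per group."""

    n_input: int
    n_anticipations: int
    n_misses: int
    n_retained: int
    per_group: pd.DataFrame  # group, n_input, n_anticipations, n_misses, pct_*

    def __post_init__(self) -> None:
        assert self.n_anticipations + self.n_misses + self.n_retained == self.n_input

    @property
    def pct_anticipations(self) -> float:
        return 100.0 * self.n_anticipations / self.n_input if self.n_input else 0.0

    @property
    def pct_misses(self) -> float:
        return 100.0 * self.n_misses / self.n_input if self.n_input else 0.0


@dataclass(frozen=True)
class CongruencyEffect:
    """Per-participant mean correct RTs and their difference (ms)."""

    participant: str
    rt_congruent: float
    rt_incongruent: float

    @property
    def ce(self) -> float:
        return self.rt_incongruent - self.rt_congruent


def trim_trials(
    trials: pd.DataFrame,
    anticipation_ms: float = ANTICIPATION_MS,
    miss_ms: float = MISS_MS,
) -> tuple[pd.DataFrame, ScreeningReport]:
    """Remove anticipations (rt < 150) and misses (rt > 2000); idempotent."""
    rt = trials["rt"].to_numpy(dtype=float)
    anticip = rt < anticipation_ms
    miss = rt > miss_ms
    keep = ~(anticip | miss)

    if "group" in trials.columns:
        grp = trials.assign(_anticip=anticip, _miss=miss).groupby("group", sort=True)
        per_group = grp.agg(
            n_input=("rt", "size"), n_anticipations=("_anticip", "sum"), n_misses=("_miss", "sum")
        ).reset_index()
    else:
        per_group = pd.DataFrame(
            {
                "group": ["all"],
                "n_input": [len(trials)],
                "n_anticipations": [int(anticip.sum())],
                "n_misses": [int(miss.sum())],
            }
        )
    per_group["pct_anticipations"] = 100.0 * per_group["n_anticipations"] / per_group["n_input"]
    per_group["pct_misses"] = 100.0 * per_group["n_misses"] / per_group["n_input"]

    report = ScreeningReport(
        n_input=len(trials),
        n_anticipations=int(anticip.sum()),
        n_misses=int(miss.sum()),
        n_retained=int(keep.sum()),
        per_group=per_group,
    )
    return trials.loc[keep].copy(), report


def exclude_participants(
    trials: pd.DataFrame, min_accuracy: float = MIN_ACCURACY
) -> tuple[pd.DataFrame, list]:
    """Drop participants with overall accuracy < 65% (computed pre-trim).

    Accuracy exactly at the threshold is retained (strict inequality).
    Returns the retained trials and the list of excluded participant ids.
    """
    acc = trials.groupby("participant")["accuracy"].mean()
    excluded = sorted(acc.index[acc < min_accuracy].tolist())
    return trials.loc[~trials["participant"].isin(excluded)].copy(), excluded


def congruency_effect(trials: pd.DataFrame, participant: str | None = None) -> CongruencyEffect:
    """CE of a single participant's screened trials, from correct-trial means."""
    if participant is not None:
        trials = trials[trials["participant"] == participant]
    elif "participant" in trials.columns:
        ids = trials["participant"].unique()
        if len(ids) > 1:
            raise ValueError("multiple participants present; pass participant=...")
        participant = str(ids[0]) if len(ids) else "unknown"
    correct = trials[trials["accuracy"] == 1]
    means = correct.groupby("condition")["rt"].mean()
    for condition in CONDITIONS:
        if condition not in means.index:
            raise ValueError(f"no correct trials in condition {condition!r}")
    return CongruencyEffect(
        participant=str(participant),
        rt_congruent=float(means["congruent"]),
        rt_incongruent=float(means["incongruent"]),
    )


def congruency_effects(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-participant CE table: participant, group, rt per condition, ce."""
    rows = []
    for pid, sub in trials.groupby("participant", sort=True):
        try:
            eff = congruency_effect(sub, participant=pid)
        except ValueError as exc:
            warnings.warn(f"participant {pid}: {exc}; skipped")
            continue
        rows.append(
            {
                "participant": pid,
                "group": sub["group"].iloc[0] if "group" in sub.columns else "all",
                "rt_congruent": eff.rt_congruent,
                "rt_incongruent": eff.rt_incongruent,
                "ce": eff.ce,
            }
        )
    return pd.DataFrame(rows)


def _quantile_bin_index(rt: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-probability bin index (0..n_bins-1) by rank; ties broken stably."""
    order = np.argsort(rt, kind="mergesort")
    idx = np.empty(rt.size, dtype=int)
    idx[order] = np.minimum((np.arange(rt.size) * n_bins) // rt.size, n_bins - 1)
    return idx


def conditional_accuracy_function(trials: pd.DataFrame, n_bins: int = 5) -> pd.DataFrame:
    """Accuracy per within-condition RT quantile bin, per participant.

    Uses all responses (correct and error).  Bins a participant-condition cell
    cannot fill are reported as missing rows, not zeros.  Columns:
    participant, condition, bin, mean_rt, accuracy, n_trials.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if "participant" not in trials.columns:
        trials = trials.assign(participant="all")
    rows = []
    for (pid, condition), sub in trials.groupby(["participant", "condition"], sort=True):
        rt = sub["rt"].to_numpy(dtype=float)
        acc = sub["accuracy"].to_numpy(dtype=float)
        if rt.size == 0:
            continue
        idx = _quantile_bin_index(rt, n_bins)
        for b in range(n_bins):
            in_bin = idx == b
            n = int(in_bin.sum())
            rows.append(
                {
                    "participant": pid,
                    "condition": condition,
                    "bin": b,
                    "mean_rt": float(rt[in_bin].mean()) if n else np.nan,
                    "accuracy": float(acc[in_bin].mean()) if n else np.nan,
                    "n_trials": n,
                }
            )
    return pd.DataFrame(rows)


def group_caf(caf: pd.DataFrame, by_group: pd.Series | None = None) -> pd.DataFrame:
    """Vincentized group CAF: participant curves averaged bin-wise."""
    caf = caf.copy()
    if by_group is not None:
        caf["group"] = caf["participant"].map(by_group)
        keys = ["group", "condition", "bin"]
    else:
        keys = ["condition", "bin"]
    return (
        caf.groupby(keys, sort=True)
        .agg(mean_rt=("mean_rt", "mean"), accuracy=("accuracy", "mean"))
        .reset_index()
    )


def delta_plot(trials: pd.DataFrame, n_deciles: int = 10) -> pd.DataFrame:
    """Mean incongruent-minus-congruent RT difference per decile (correct trials).

    Per participant and condition, correct RTs are split into ``n_deciles``
    equal-probability bins and the bin means differenced between conditions;
    the participant curves are then averaged (Vincentized).  Participants
    without at least ``n_deciles`` correct trials in each condition are
    skipped with a warning.  Columns: decile, mean_rt, delta, n_participants.
    """
    if "participant" not in trials.columns:
        trials = trials.assign(participant="all")
    correct = trials[trials["accuracy"] == 1]
    per_participant = []
    for pid, sub in correct.groupby("participant", sort=True):
        bins = {}
        ok = True
        for condition in CONDITIONS:
            rt = sub.loc[sub["condition"] == condition, "rt"].to_numpy(dtype=float)
            if rt.size < n_deciles:
                ok = False
                break
            idx = _quantile_bin_index(rt, n_deciles)
            bins[condition] = np.array([rt[idx == b].mean() for b in range(n_deciles)])
        if not ok:
            warnings.warn(f"participant {pid}: fewer than {n_deciles} correct trials "
                          "in a condition; skipped from delta plot")
            continue
        per_participant.append(
            {
                "delta": bins["incongruent"] - bins["congruent"],
                "mean_rt": (bins["incongruent"] + bins["congruent"]) / 2.0,
            }
        )
    if not per_participant:
        raise ValueError("no participant had enough correct trials for the delta plot")
    delta = np.mean([p["delta"] for p in per_participant], axis=0)
    mean_rt = np.mean([p["mean_rt"] for p in per_participant], axis=0)
    return pd.DataFrame(
        {
            "decile": np.arange(1, n_deciles + 1),
            "mean_rt": mean_rt,
            "delta": delta,
            "n_participants": len(per_participant),
        }
    )
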