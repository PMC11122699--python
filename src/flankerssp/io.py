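"""File formats, configuration and the end-to-end analysis pipeline.

The trial CSV schema has one row per trial with columns ``participant``,
``group``, ``block``, ``trial``, ``condition`` (congruent/incongruent,
case-insensitive), ``response``, ``accuracy`` (0/1) and ``rt`` in ms.

Every random draw in the pipeline descends from a single master seed through
``numpy.random.SeedSequence`` spawning: the study generator, each
participant's fit, and the bootstrap each receive their own child stream, so
reruns with the same configuration are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import preprocess, stats
from .fitting import FitResult, FitSettings, fit_participant
from .simulate import CONDITIONS, SimulationSettings
from .synth import GroupSpec, generate_participant

logger = logging.getLogger("flankerssp")

__all__ = [
    "StudyConfig",
    "read_trials_csv",
    "write_fit_results",
    "run_pipeline",
    "run_recovery",
]

REQUIRED_COLUMNS = ("participant", "group", "block", "condition", "rt", "accuracy")


@dataclass
class StudyConfig:
    """All tunable constants of the analysis, with conventional defaults."""

    anticipation_ms: float = 150.0
    miss_ms: float = 2000.0
    min_accuracy: float = 0.65
    equivalence_bounds: tuple[float, float] = (-0.31, 0.31)
    alpha: float = 0.05
    quantiles: tuple[float, ...] = (0.1, 0.3, 0.5, 0.7, 0.9)
    stage1_maxfev: int = 1000
    stage2_maxfev: int = 50000
    n_sim_trials: int = 25000
    max_decision_time: float = 3.0
    n_boot: int = 5000
    bootstrap_method: str = "BCa"
    caf_bins: int = 5
    delta_deciles: int = 10
    # one-sided direction for the interference-time contrast: this group is
    # tested as stochastically larger than the other
    greater_group: str | None = None
    seed: int = 0

    def fit_settings(self) -> FitSettings:
        return FitSettings(
            stage1_maxfev=self.stage1_maxfev,
            stage2_maxfev=self.stage2_maxfev,
            quantiles=self.quantiles,
            sim=SimulationSettings(
                n_sim_trials=self.n_sim_trials, max_decision_time=self.max_decision_time
            ),
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["equivalence_bounds"] = list(self.equivalence_bounds)
        d["quantiles"] = list(self.quantiles)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "equivalence_bounds" in d:
            d["equivalence_bounds"] = tuple(d["equivalence_bounds"])
        if "quantiles" in d:
            d["quantiles"] = tuple(d["quantiles"])
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "StudyConfig":
        """Load from YAML or JSON (YAML is a superset, so one loader serves)."""
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def read_trials_csv(path) -> pd.DataFrame:
    """Read and validate a trial CSV; malformed rows are reported by line.

    Condition labels are normalised case-insensitively.  Raises ``ValueError``
    on missing columns, non-numeric RTs, accuracies outside {0, 1} or unknown
    condition labels, naming the offending rows (1-based data line numbers).
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")

    problems = []
    rt = pd.to_numeric(df["rt"], errors="coerce")
    for i in df.index[rt.isna()]:
        problems.append(f"row {i + 1}: non-numeric rt {df.loc[i, 'rt']!r}")
    acc = pd.to_numeric(df["accuracy"], errors="coerce")
    bad_acc = acc.isna() | ~acc.isin([0, 1])
    for i in df.index[bad_acc]:
        problems.append(f"row {i + 1}: accuracy {df.loc[i, 'accuracy']!r} not in {{0, 1}}")
    cond = df["condition"].astype(str).str.strip().str.lower()
    bad_cond = ~cond.isin(CONDITIONS)
    for i in df.index[bad_cond]:
        problems.append(f"row {i + 1}: unknown condition {df.loc[i, 'condition']!r}")
    if problems:
        head = "\n  ".join(problems[:20])
        more = f"\n  ... and {len(problems) - 20} more" if len(problems) > 20 else ""
        raise ValueError(f"{path}: malformed rows:\n  {head}{more}")

    df = df.copy()
    df["rt"] = rt.astype(float)
    df["accuracy"] = acc.astype(int)
    df["condition"] = cond
    df["participant"] = df["participant"].astype(str)
    return df


def write_fit_results(fits: dict[str, FitResult], groups: dict[str, str], path) -> pd.DataFrame:
    """Serialise per-participant fits to CSV, one row per participant."""
    rows = []
    for pid, fr in fits.items():
        row = {"participant": pid, "group": groups.get(pid, "all")}
        row.update(fr.to_dict())
        rows.append(row)
    table = pd.DataFrame(rows)
    if path is not None:
        table.to_csv(path, index=False)
    return table


def _comparison_dict(x, y, rng, config: StudyConfig, alternative: str) -> dict:
    u, p = stats.mann_whitney_u(x, y, alternative=alternative)
    est, ci = stats.bootstrap_mean_difference(
        x, y, n_boot=config.n_boot, rng=rng, method=config.bootstrap_method
    )
    return {
        "U": u,
        "p": p,
        "alternative": alternative,
        "mean_difference": est,
        "ci": list(ci),
        "d": stats.cohens_d_from_samples(x, y),
    }


def run_pipeline(
    config: StudyConfig,
    trials: pd.DataFrame,
    outdir=None,
    fit_settings: FitSettings | None = None,
) -> dict:
    """The pre-registered analysis sequence on one trial table.

    Trim -> accuracy exclusion -> congruency effects -> TOST + NHST on CE ->
    per-participant SSP fits -> normality screen and Mann-Whitney contrasts on
    interference time and the other parameters -> CAF and delta-plot tables.
    Per-participant fit failures are isolated and reported, not fatal.
    Returns a JSON-serialisable report; tables are additionally written to
    ``outdir`` when given.
    """
    t_start = time.time()
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
    if fit_settings is None:
        fit_settings = config.fit_settings()
    seeds = np.random.SeedSequence(config.seed).spawn(3)
    rng_boot = np.random.default_rng(seeds[0])
    fit_seed_seq = seeds[1]

    groups = sorted(trials["group"].astype(str).unique())
    if len(groups) != 2:
        raise ValueError(f"expected exactly two groups, found {groups}")
    g_hi = config.greater_group or groups[0]
    if g_hi not in groups:
        raise ValueError(f"greater_group {g_hi!r} not among {groups}")
    g_lo = [g for g in groups if g != g_hi][0]

    trimmed, screen = preprocess.trim_trials(trials, config.anticipation_ms, config.miss_ms)
    logger.info(
        "trimmed %d anticipations, %d misses of %d trials",
        screen.n_anticipations, screen.n_misses, screen.n_input,
    )
    kept, excluded = preprocess.exclude_participants(trials, config.min_accuracy)
    trimmed = trimmed[~trimmed["participant"].isin(excluded)]
    logger.info("excluded %d participant(s) for accuracy < %.0f%%",
                len(excluded), 100 * config.min_accuracy)

    ce = preprocess.congruency_effects(trimmed)
    ce_x = ce.loc[ce["group"] == g_hi, "ce"].to_numpy()
    ce_y = ce.loc[ce["group"] == g_lo, "ce"].to_numpy()
    tost = stats.tost_equivalence(ce_x, ce_y, config.equivalence_bounds, config.alpha)
    ce_est, ce_ci = stats.bootstrap_mean_difference(
        ce_x, ce_y, n_boot=config.n_boot, rng=rng_boot, method=config.bootstrap_method
    )

    logger.info("fitting %d participants", trimmed["participant"].nunique())
    fits: dict[str, FitResult] = {}
    failures: dict[str, str] = {}
    group_of = trimmed.groupby("participant")["group"].first().to_dict()
    pids = sorted(trimmed["participant"].unique())
    child_seeds = fit_seed_seq.spawn(len(pids))
    for pid, child in zip(pids, child_seeds):
        sub = trimmed[trimmed["participant"] == pid]
        try:
            fits[pid] = fit_participant(
                sub, fit_settings=fit_settings, rng=np.random.default_rng(child),
                seed=int(child.generate_state(1)[0] % (2**31)),
            )
        except Exception as exc:  # noqa: BLE001 - isolate per-participant failures
            logger.warning("fit failed for %s: %s", pid, exc)
            failures[pid] = str(exc)
    fit_table = write_fit_results(
        fits, group_of, None if outdir is None else Path(outdir) / "fits.csv"
    )

    param_tests = {}
    if len(fits) >= 4:
        for column, alternative in (
            ("interference_time", "greater"),
            ("p", "two-sided"),
            ("a", "two-sided"),
            ("ter", "two-sided"),
        ):
            x = fit_table.loc[fit_table["group"] == g_hi, column].to_numpy()
            y = fit_table.loc[fit_table["group"] == g_lo, column].to_numpy()
            entry = _comparison_dict(x, y, rng_boot, config, alternative)
            pooled = np.concatenate([x, y])
            if 3 <= pooled.size <= 5000 and np.ptp(pooled) > 0:
                w, p_norm = stats.normality_screen(pooled)
                entry["shapiro_w"], entry["shapiro_p"] = w, p_norm
            param_tests[column] = entry

    caf = preprocess.conditional_accuracy_function(trimmed, config.caf_bins)
    gcaf = preprocess.group_caf(caf, trimmed.groupby("participant")["group"].first())
    delta_by_group = {
        g: preprocess.delta_plot(trimmed[trimmed["group"] == g], config.delta_deciles)
        for g in groups
    }

    report = {
        "config": config.to_dict(),
        "groups": {"greater": g_hi, "lesser": g_lo},
        "screening": {
            "n_input": screen.n_input,
            "n_anticipations": screen.n_anticipations,
            "n_misses": screen.n_misses,
            "pct_anticipations": screen.pct_anticipations,
            "pct_misses": screen.pct_misses,
            "excluded_participants": excluded,
        },
        "congruency_effect": {
            "n": {g_hi: int(ce_x.size), g_lo: int(ce_y.size)},
            "mean": {g_hi: float(ce_x.mean()), g_lo: float(ce_y.mean())},
            "mean_difference": ce_est,
            "ci": list(ce_ci),
            "d": tost.d,
            "tost": {
                "bounds_d": list(tost.bounds_d),
                "df": tost.df,
                "t_lower": tost.t_lower,
                "p_lower": tost.p_lower,
                "t_upper": tost.t_upper,
                "p_upper": tost.p_upper,
                "t_nhst": tost.t_nhst,
                "p_nhst": tost.p_nhst,
                "equivalent": tost.equivalent,
            },
        },
        "fits": {"n_fitted": len(fits), "failures": failures},
        "parameter_tests": param_tests,
        "elapsed_s": round(time.time() - t_start, 3),
    }

    if outdir is not None:
        ce.to_csv(outdir / "congruency_effects.csv", index=False)
        gcaf.to_csv(outdir / "caf.csv", index=False)
        pd.concat(
            [d.assign(group=g) for g, d in delta_by_group.items()], ignore_index=True
        ).to_csv(outdir / "delta_plot.csv", index=False)
        report_for_json = dict(report)
        report_for_json["elapsed_s"] = None  # keep rerun outputs byte-identical
        with open(outdir / "report.json", "w") as fh:
            json.dump(report_for_json, fh, indent=2, sort_keys=True)
    return report


def run_recovery(
    n_participants: int = 20,
    fit_settings: FitSettings | None = None,
    specs: tuple[GroupSpec, ...] | None = None,
    seed: int = 0,
    trim: bool = True,
) -> pd.DataFrame:
    """Simulate-and-refit parameter recovery study.

    Participants are drawn alternately from the two default group specs so the
    generating parameters span both groups' ranges; each dataset is screened
    with the standard trimming rules and refit from the default start.
    Returns one row per participant with true and recovered parameters.
    """
    from .fitting import RECOVERY_SETTINGS
    from .synth import AUTISTIC_LIKE, NON_AUTISTIC_LIKE

    if fit_settings is None:
        fit_settings = RECOVERY_SETTINGS
    if specs is None:
        specs = (AUTISTIC_LIKE, NON_AUTISTIC_LIKE)
    seeds = np.random.SeedSequence(seed).spawn(n_participants)
    rows = []
    for i, child in enumerate(seeds):
        rng = np.random.default_rng(child)
        spec = specs[i % len(specs)]
        true, trials = generate_participant(spec, rng, participant_id=f"r{i + 1:03d}")
        if trim:
            trials, _ = preprocess.trim_trials(trials)
        fit = fit_participant(trials, fit_settings=fit_settings, rng=rng)
        row = {"participant": f"r{i + 1:03d}", "group": spec.label}
        for name, value in zip(
            ("a", "ter", "p", "sd_a", "rd"), true.as_array(), strict=True
        ):
            row[f"true_{name}"] = value
        row["true_interference_time"] = true.interference_time
        for name, value in fit.to_dict().items():
            row[f"fit_{name}"] = value
        rows.append(row)
        logger.info("recovered participant %d/%d", i + 1, n_participants)
    return pd.DataFrame(rows)
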