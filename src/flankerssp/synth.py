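"""Synthetic two-group flanker studies with known ground truth.

Emulates the design of a two-group online flanker study: roughly 145
participants per group, each completing 8 blocks of 48 trials (384 trials,
50% congruent), with trial-level RT/accuracy generated by the shrinking
spotlight model under participant-level parameter heterogeneity.  Contaminant
trials are injected at realistic rates: anticipations (uniform RT on
50-149 ms) and misses (uniform on 2001-3000 ms), ranges chosen so the
standard 150/2000 ms trimming rules capture exactly the injected trials.

Default group specs are centred on published group-level parameter summaries
for autistic and non-autistic adults (boundary ~0.082 vs 0.066, perceptual
strength ~0.48 vs 0.52, non-decision time ~0.31 vs 0.30 s, interference time
~43.6 vs 33.5 ms) with the initial spotlight width held at 1.5 and the
narrowing rate back-solved from the drawn interference time.  They are
illustrative study conditions, not estimates of any real population.
Parameters are drawn independently (no population correlations) from normals
truncated at the fitting bounds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .model import SSPParameters
from .simulate import SimulationSettings, simulate_trials

__all__ = [
    "GroupSpec",
    "AUTISTIC_LIKE",
    "NON_AUTISTIC_LIKE",
    "draw_parameters",
    "generate_participant",
    "generate_study",
]

TRIALS_PER_BLOCK = 48
N_BLOCKS = 8

# truncation bounds for participant-level draws, matching the fitting bounds
# (tightened away from zero so every draw yields a simulable participant)
_DRAW_BOUNDS = {
    "a": (0.01, 0.5),
    "ter": (0.05, 0.6),
    "p": (0.05, 2.0),
    "sd_a": (0.2, 5.0),
    "interference_time": (5.0, 150.0),
}


@dataclass(frozen=True)
class GroupSpec:
    """Study conditions for one group.

    Parameter means/SDs define independent truncated normals; ``sd_a`` is held
    near-constant and the narrowing rate is derived as
    ``rd = sd_a / interference_time``.  Contaminant rates are per-trial
    Bernoulli probabilities.
    """

    label: str
    n_participants: int
    a_mean: float = 0.07
    a_sd: float = 0.04
    ter_mean: float = 0.3
    ter_sd: float = 0.045
    p_mean: float = 0.5
    p_sd: float = 0.17
    sd_a_mean: float = 1.5
    sd_a_sd: float = 0.0
    interference_mean: float = 38.0
    interference_sd: float = 22.0
    anticipation_rate: float = 0.002
    miss_rate: float = 0.008
    n_trials: int = N_BLOCKS * TRIALS_PER_BLOCK
    congruent_proportion: float = 0.5

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("need at least one participant")
        if not (0 <= self.anticipation_rate < 1 and 0 <= self.miss_rate < 1):
            raise ValueError("contaminant rates must be in [0, 1)")
        if not 0 < self.congruent_proportion < 1:
            raise ValueError("congruent proportion must be in (0, 1)")


#: Group centred on the autistic-group parameter summaries.
AUTISTIC_LIKE = GroupSpec(
    label="autistic",
    n_participants=144,
    a_mean=0.082,
    a_sd=0.044,
    ter_mean=0.31,
    ter_sd=0.05,
    p_mean=0.48,
    p_sd=0.19,
    interference_mean=43.61,
    interference_sd=28.04,
    anticipation_rate=0.0028,
    miss_rate=0.0136,
)

#: Group centred on the non-autistic-group parameter summaries.
NON_AUTISTIC_LIKE = GroupSpec(
    label="non-autistic",
    n_participants=146,
    a_mean=0.066,
    a_sd=0.036,
    ter_mean=0.30,
    ter_sd=0.04,
    p_mean=0.52,
    p_sd=0.16,
    interference_mean=33.50,
    interference_sd=15.99,
    anticipation_rate=0.0011,
    miss_rate=0.0028,
)


def _draw_truncnorm(mean, sd, bounds, rng) -> float:
    lo, hi = bounds
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def draw_parameters(spec: GroupSpec, rng: np.random.Generator) -> SSPParameters:
    """One participant's generating parameters from the spec's truncated normals."""
    a = _draw_truncnorm(spec.a_mean, spec.a_sd, _DRAW_BOUNDS["a"], rng)
    ter = _draw_truncnorm(spec.ter_mean, spec.ter_sd, _DRAW_BOUNDS["ter"], rng)
    p = _draw_truncnorm(spec.p_mean, spec.p_sd, _DRAW_BOUNDS["p"], rng)
    sd_a = _draw_truncnorm(spec.sd_a_mean, spec.sd_a_sd, _DRAW_BOUNDS["sd_a"], rng)
    it = _draw_truncnorm(
        spec.interference_mean, spec.interference_sd, _DRAW_BOUNDS["interference_time"], rng
    )
    rd = float(np.clip(sd_a / it, 1e-5, 1.0))
    return SSPParameters(a=a, ter=ter, p=p, sd_a=sd_a, rd=rd)


def generate_participant(
    spec: GroupSpec,
    rng: np.random.Generator,
    participant_id: str = "p001",
    settings: SimulationSettings | None = None,
    params: SSPParameters | None = None,
) -> tuple[SSPParameters, pd.DataFrame]:
    """Ground-truth parameters and a full trial table for one participant.

    Trials are simulated per condition, interleaved in a random order over
    blocks, then a Bernoulli subset of RTs is replaced by anticipation
    (uniform 50-149 ms) and miss (uniform 2001-3000 ms) contaminants, flagged
    in the ``contaminant`` column.
    """
    if settings is None:
        settings = SimulationSettings()
    if params is None:
        params = draw_parameters(spec, rng)
    n_cong = int(round(spec.n_trials * spec.congruent_proportion))
    n_incong = spec.n_trials - n_cong

    frames = []
    for condition, n in (("congruent", n_cong), ("incongruent", n_incong)):
        rt, acc, trunc = simulate_trials(params, condition, n, settings, rng=rng)
        frames.append(
            pd.DataFrame(
                {"condition": condition, "rt": rt, "accuracy": acc.astype(int), "truncated": trunc}
            )
        )
    trials = pd.concat(frames, ignore_index=True)
    order = rng.permutation(len(trials))
    trials = trials.iloc[order].reset_index(drop=True)
    trials.insert(0, "participant", participant_id)
    trials.insert(1, "block", np.arange(len(trials)) // TRIALS_PER_BLOCK + 1)
    trials.insert(2, "trial", np.arange(1, len(trials) + 1))

    # stimulus/response bookkeeping: random target direction, response derived
    target = np.where(rng.random(len(trials)) < 0.5, "left", "right")
    correct_resp = target
    wrong = {"left": "right", "right": "left"}
    response = np.where(
        trials["accuracy"].to_numpy() == 1,
        correct_resp,
        np.vectorize(wrong.get)(correct_resp),
    )
    trials["response"] = response

    contaminant = np.full(len(trials), "none", dtype=object)
    u = rng.random(len(trials))
    is_anticip = u < spec.anticipation_rate
    is_miss = (u >= spec.anticipation_rate) & (u < spec.anticipation_rate + spec.miss_rate)
    rt = trials["rt"].to_numpy(dtype=float)
    rt[is_anticip] = rng.uniform(50.0, 149.0, size=int(is_anticip.sum()))
    rt[is_miss] = rng.uniform(2001.0, 3000.0, size=int(is_miss.sum()))
    contaminant[is_anticip] = "anticipation"
    contaminant[is_miss] = "miss"
    trials["rt"] = rt
    trials["contaminant"] = contaminant
    return params, trials


def generate_study(
    spec_a: GroupSpec = AUTISTIC_LIKE,
    spec_b: GroupSpec = NON_AUTISTIC_LIKE,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    settings: SimulationSettings | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """A full two-group study: trial table and ground-truth parameter table.

    Returns ``(trials, truth)``; ``truth`` has one row per participant with
    the generating parameters, interference time and contaminant count, and
    shares its participant id set with the trial table.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    trial_frames = []
    truth_rows = []
    for spec, prefix in ((spec_a, "A"), (spec_b, "B")):
        for i in range(spec.n_participants):
            pid = f"{prefix}{i + 1:03d}"
            params, trials = generate_participant(spec, rng, pid, settings)
            trials.insert(1, "group", spec.label)
            trial_frames.append(trials)
            truth_rows.append(
                {
                    "participant": pid,
                    "group": spec.label,
                    "a": params.a,
                    "ter": params.ter,
                    "p": params.p,
                    "sd_a": params.sd_a,
                    "rd": params.rd,
                    "interference_time": params.interference_time,
                    "n_contaminants": int((trials["contaminant"] != "none").sum()),
                }
            )
    return pd.concat(trial_frames, ignore_index=True), pd.DataFrame(truth_rows)
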