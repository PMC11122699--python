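"""Single-trial simulation of SSP evidence accumulation.

Evidence starts at 0 (no bias) and evolves by Euler–Maruyama steps

    x <- x + v(t) * dt + s * sqrt(dt) * eps,   eps ~ N(0, 1)

until it reaches ``+a`` (correct response) or ``-a`` (error); the response time
is ``ter`` plus the first-passage time.  The time-varying drift ``v(t)`` comes
from :func:`flankerssp.model.drift_rate`, with the spotlight clock running in
milliseconds of decision time while accumulation steps in seconds.

Trials that have not terminated by ``max_decision_time`` are flagged as
truncated, never silently dropped; downstream they count as misses (their
nominal RT exceeds the 2000 ms trimming threshold).

The hot loop is JIT-compiled with numba and operates on a pre-generated matrix
of standard-normal increments, which makes a common-random-numbers mode
possible: reusing one noise matrix across objective evaluations renders the
fitting surface deterministic.  A pure-NumPy cumulative-sum path is kept as a
fallback and as an internal cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import SSPParameters, StimulusLayout, drift_rate

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore[misc]
        def wrap(f):
            return f

        return wrap if not (args and callable(args[0])) else args[0]


CONDITIONS = ("congruent", "incongruent")

__all__ = [
    "CONDITIONS",
    "SimulationSettings",
    "TrialOutcome",
    "drift_path",
    "simulate_trials",
    "simulate_trial",
    "simulate_condition_set",
    "simulate_dataset",
]


@dataclass(frozen=True)
class SimulationSettings:
    """Numerical settings of the Euler–Maruyama simulation.

    dt: integration step in seconds (default 1 ms).
    s: diffusion coefficient (conventional 0.1 scaling).
    sd_floor: minimum spotlight sd after full narrowing.
    max_decision_time: truncation horizon in seconds.
    n_sim_trials: simulated trials per condition per objective evaluation.
    """

    dt: float = 0.001
    s: float = 0.1
    sd_floor: float = 0.001
    max_decision_time: float = 3.0
    n_sim_trials: int = 25000

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.s <= 0 or self.max_decision_time <= 0:
            raise ValueError("dt, s and max_decision_time must be positive")
        if self.sd_floor <= 0:
            raise ValueError("sd_floor must be positive")
        if self.n_sim_trials < 1:
            raise ValueError("n_sim_trials must be >= 1")

    @property
    def n_steps(self) -> int:
        return int(round(self.max_decision_time / self.dt))


@dataclass(frozen=True)
class TrialOutcome:
    """One simulated flanker trial."""

    rt: float  # ms, ter + decision time
    accuracy: int  # 1 = correct boundary hit first
    condition: str
    truncated: bool = False


def drift_path(
    params: SSPParameters, condition: str, settings: SimulationSettings
) -> np.ndarray:
    """Drift rate v(t_k) at the start of each integration step, shape (n_steps,)."""
    layout = StimulusLayout.for_condition(condition)
    t_ms = np.arange(settings.n_steps) * settings.dt * 1000.0
    return np.asarray(drift_rate(t_ms, params, layout, settings.sd_floor), dtype=np.float64)


@njit(cache=True)
def _first_passage_numba(drift_dt, noise, s_sqdt, a):  # pragma: no cover - numba
    n, n_steps = noise.shape
    steps = np.empty(n, dtype=np.int64)
    resp = np.empty(n, dtype=np.int8)
    for i in range(n):
        x = 0.0
        hit = 0
        last = n_steps
        for k in range(n_steps):
            x += drift_dt[k] + s_sqdt * noise[i, k]
            if x >= a:
                hit = 1
                last = k
                break
            elif x <= -a:
                hit = -1
                last = k
                break
        steps[i] = last
        resp[i] = hit
    return steps, resp


def _first_passage_numpy(drift_dt, noise, s_sqdt, a):
    """Cumulative-sum reference implementation (cross-check / fallback)."""
    x = np.cumsum(drift_dt[None, :] + s_sqdt * noise, axis=1)
    crossed = np.abs(x) >= a
    any_cross = crossed.any(axis=1)
    first = np.argmax(crossed, axis=1)
    steps = np.where(any_cross, first, noise.shape[1])
    resp = np.zeros(noise.shape[0], dtype=np.int8)
    rows = np.flatnonzero(any_cross)
    resp[rows] = np.sign(x[rows, first[rows]]).astype(np.int8)
    return steps.astype(np.int64), resp


def _first_passage(drift_dt, noise, s_sqdt, a):
    if _HAVE_NUMBA:
        return _first_passage_numba(drift_dt, noise, s_sqdt, a)
    return _first_passage_numpy(drift_dt, noise, s_sqdt, a)


def simulate_trials(
    params: SSPParameters,
    condition: str,
    n: int,
    settings: SimulationSettings | None = None,
    rng: np.random.Generator | None = None,
    noise: np.ndarray | None = None,
    chunk: int = 4000,
):
    """Simulate ``n`` trials of one condition; vectorised core.

    Returns ``(rt_ms, accuracy, truncated)`` arrays.  Noise can be supplied
    explicitly (shape ``(n, n_steps)``, standard normal) for common random
    numbers; otherwise it is drawn from ``rng`` in memory-bounded chunks.
    Truncated trials get accuracy 0 and a nominal RT at the horizon.
    """
    if settings is None:
        settings = SimulationSettings()
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    drift_dt = drift_path(params, condition, settings) * settings.dt
    s_sqdt = settings.s * np.sqrt(settings.dt)
    n_steps = settings.n_steps

    steps = np.empty(n, dtype=np.int64)
    resp = np.empty(n, dtype=np.int8)
    if noise is not None:
        if noise.shape != (n, n_steps):
            raise ValueError(f"noise must have shape {(n, n_steps)}, got {noise.shape}")
        steps, resp = _first_passage(drift_dt, np.ascontiguousarray(noise), s_sqdt, params.a)
    else:
        if rng is None:
            raise ValueError("either rng or noise must be supplied")
        for lo in range(0, n, chunk):
            hi = min(lo + chunk, n)
            eps = rng.standard_normal((hi - lo, n_steps))
            steps[lo:hi], resp[lo:hi] = _first_passage(drift_dt, eps, s_sqdt, params.a)

    truncated = steps >= n_steps
    decision_time = np.minimum(steps + 1, n_steps) * settings.dt
    rt_ms = 1000.0 * (params.ter + decision_time)
    accuracy = (resp > 0).astype(np.int8)
    return rt_ms, accuracy, truncated


def simulate_trial(
    params: SSPParameters,
    condition: str,
    settings: SimulationSettings | None = None,
    rng: np.random.Generator | None = None,
) -> TrialOutcome:
    """Simulate a single trial (thin wrapper over the vectorised core)."""
    rt, acc, trunc = simulate_trials(params, condition, 1, settings, rng)
    return TrialOutcome(
        rt=float(rt[0]), accuracy=int(acc[0]), condition=condition, truncated=bool(trunc[0])
    )


def simulate_condition_set(
    params: SSPParameters,
    n_per_condition: int,
    settings: SimulationSettings | None = None,
    rng: np.random.Generator | None = None,
) -> list[TrialOutcome]:
    """``n_per_condition`` trials of each condition, congruent first."""
    if n_per_condition < 1:
        raise ValueError("n_per_condition must be >= 1")
    out: list[TrialOutcome] = []
    for condition in CONDITIONS:
        rt, acc, trunc = simulate_trials(params, condition, n_per_condition, settings, rng)
        out.extend(
            TrialOutcome(rt=float(r), accuracy=int(a), condition=condition, truncated=bool(t))
            for r, a, t in zip(rt, acc, trunc)
        )
    return out


def simulate_dataset(
    params: SSPParameters,
    n_congruent: int,
    n_incongruent: int,
    settings: SimulationSettings | None = None,
    rng: np.random.Generator | None = None,
):
    """Condition-wise trial arrays as a dict, for bulk consumers."""
    out = {}
    for condition, n in (("congruent", n_congruent), ("incongruent", n_incongruent)):
        rt, acc, trunc = simulate_trials(params, condition, n, settings, rng)
        out[condition] = {"rt": rt, "accuracy": acc, "truncated": trunc}
    return out
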