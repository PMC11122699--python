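"""Between-group statistics for congruency effects and fitted parameters.

Implements the pre-registered comparison toolkit: pooled-SD Cohen's d with
bootstrap confidence intervals, Welch-based TOST equivalence testing with the
region of equivalence stated as standardized bounds (default d = +/-0.31),
one- and two-sided Mann-Whitney U tests, a priori power for the two-sample
t-test from the noncentral t distribution, and a Shapiro-Wilk normality
screen used to route variables to t-based or rank-based tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "GroupComparison",
    "TostResult",
    "pooled_sd",
    "cohens_d",
    "cohens_d_from_samples",
    "bootstrap_mean_difference",
    "tost_equivalence",
    "mann_whitney_u",
    "t_test_power",
    "normality_screen",
]


@dataclass(frozen=True)
class GroupSummary:
    """Size, mean and SD of one variable in one group."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("need n >= 2")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")

    @classmethod
    def from_sample(cls, x) -> "GroupSummary":
        x = np.asarray(x, dtype=float)
        return cls(n=x.size, mean=float(x.mean()), sd=float(x.std(ddof=1)))


@dataclass(frozen=True)
class GroupComparison:
    """One between-group contrast: estimate, CI, effect size, test."""

    mean_difference: float
    ci_low: float
    ci_high: float
    cohen_d: float
    statistic: float
    statistic_name: str  # "t" or "U"
    p_value: float
    alternative: str
    df: float | None = None
    d_ci_low: float | None = None
    d_ci_high: float | None = None

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.mean_difference <= self.ci_high):
            raise ValueError("CI must bracket the estimate")


def pooled_sd(a: GroupSummary, b: GroupSummary) -> float:
    num = (a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2
    return float(np.sqrt(num / (a.n + b.n - 2)))


def cohens_d(a: GroupSummary, b: GroupSummary) -> float:
    """Pooled-SD standardized mean difference ``(mean_a - mean_b) / s_p``."""
    sp = pooled_sd(a, b)
    diff = a.mean - b.mean
    if sp == 0:
        if diff == 0:
            return 0.0
        raise ValueError("zero pooled SD with unequal means")
    return diff / sp


def cohens_d_from_samples(x, y) -> float:
    return cohens_d(GroupSummary.from_sample(x), GroupSummary.from_sample(y))


def bootstrap_mean_difference(
    x,
    y,
    n_boot: int = 5000,
    rng: np.random.Generator | None = None,
    method: str = "BCa",
    confidence_level: float = 0.95,
) -> tuple[float, tuple[float, float]]:
    """Mean difference ``mean(x) - mean(y)`` with a bootstrap CI.

    Resamples within each group with replacement; the interval is
    bias-corrected and accelerated by default (``method="percentile"`` for
    plain percentile intervals).  Seeded and reproducible through ``rng``.
    """
    if n_boot < 1000:
        raise ValueError("use at least 1000 resamples")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    est = float(x.mean() - y.mean())

    def statistic(xs, ys, axis=-1):
        return np.mean(xs, axis=axis) - np.mean(ys, axis=axis)

    res = sps.bootstrap(
        (x, y),
        statistic,
        n_resamples=n_boot,
        method=method,
        confidence_level=confidence_level,
        vectorized=True,
        rng=rng,
    )
    lo, hi = float(res.confidence_interval.low), float(res.confidence_interval.high)
    return est, (lo, hi)


@dataclass(frozen=True)
class TostResult:
    """Two one-sided Welch tests against raw-scale equivalence bounds."""

    mean_difference: float
    d: float
    bounds_d: tuple[float, float]
    bounds_raw: tuple[float, float]
    df: float
    t_lower: float
    p_lower: float
    t_upper: float
    p_upper: float
    t_nhst: float
    p_nhst: float
    equivalent: bool

    @property
    def p_tost(self) -> float:
        return max(self.p_lower, self.p_upper)


def _welch(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    nx, ny = x.size, y.size
    if vx == 0 and vy == 0:
        raise ValueError("zero variance in both samples")
    se = np.sqrt(vx / nx + vy / ny)
    df = (vx / nx + vy / ny) ** 2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    return float(x.mean() - y.mean()), float(se), float(df)


def tost_equivalence(
    x, y, d_bounds: tuple[float, float] = (-0.31, 0.31), alpha: float = 0.05
) -> TostResult:
    """TOST equivalence test with the region stated in Cohen's d units.

    The d bounds are converted to the raw scale via the pooled SD of the two
    samples, then each bound gets a one-sided Welch t-test (difference above
    the lower bound; below the upper bound).  Equivalence is concluded only
    when both one-sided tests reject at ``alpha``.  The standard two-sided
    null-hypothesis test is returned alongside.
    """
    lo_d, hi_d = d_bounds
    if lo_d > hi_d:
        raise ValueError("lower bound must not exceed upper bound")
    sp = pooled_sd(GroupSummary.from_sample(x), GroupSummary.from_sample(y))
    lo_raw, hi_raw = lo_d * sp, hi_d * sp
    diff, se, df = _welch(x, y)

    t_lower = (diff - lo_raw) / se
    p_lower = float(sps.t.sf(t_lower, df))  # H1: diff > lower bound
    t_upper = (diff - hi_raw) / se
    p_upper = float(sps.t.cdf(t_upper, df))  # H1: diff < upper bound
    t_nhst = diff / se
    p_nhst = float(2 * sps.t.sf(abs(t_nhst), df))

    return TostResult(
        mean_difference=diff,
        d=diff / sp if sp > 0 else 0.0,
        bounds_d=(lo_d, hi_d),
        bounds_raw=(lo_raw, hi_raw),
        df=df,
        t_lower=float(t_lower),
        p_lower=p_lower,
        t_upper=float(t_upper),
        p_upper=p_upper,
        t_nhst=float(t_nhst),
        p_nhst=p_nhst,
        equivalent=bool(p_lower < alpha and p_upper < alpha),
    )


def mann_whitney_u(x, y, alternative: str = "two-sided") -> tuple[float, float]:
    """Mann-Whitney U of ``x`` versus ``y``.

    Exact null distribution when ``n_x * n_y <= 400`` and the pooled sample is
    tie-free; otherwise the normal approximation with tie and continuity
    corrections.  Returns ``(U, p)`` with U counting pairs where x exceeds y.
    """
    if alternative not in ("greater", "less", "two-sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("samples must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (x.size * y.size <= 400 and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def t_test_power(n_per_group: int, d: float, alpha: float = 0.05, sides: int = 1) -> float:
    """A priori power of the two-sample t-test from the noncentral t.

    ``ncp = d * sqrt(n/2)`` with ``df = 2n - 2``.  For two-sided tests the
    (negligible) mass in the opposite tail is included.
    """
    if n_per_group < 2:
        raise ValueError("need n >= 2 per group")
    if sides not in (1, 2):
        raise ValueError("sides must be 1 or 2")
    df = 2 * n_per_group - 2
    ncp = d * np.sqrt(n_per_group / 2.0)
    tcrit = sps.t.isf(alpha / sides, df)
    power = sps.nct.sf(tcrit, df, ncp)
    if sides == 2:
        power += sps.nct.cdf(-tcrit, df, ncp)
    return float(power)


def normality_screen(x) -> tuple[float, float]:
    """Shapiro-Wilk statistic and p-value; raises on degenerate input.

    Used to route the congruency effect to t-based tests and the fitted
    parameters to rank-based tests; supported for 3 <= n <= 5000.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3 or x.size > 5000:
        raise ValueError("Shapiro-Wilk supported for 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise ValueError("constant sample: normality screen undefined")
    res = sps.shapiro(x)
    return float(res.statistic), float(res.pvalue)
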