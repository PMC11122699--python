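"""Core quantities of the shrinking spotlight model (SSP).

The SSP extends the drift diffusion framework to the flanker task: a central
target is flanked by foils, and every stimulus lying under a Gaussian
attentional spotlight contributes to the drift rate of a noisy evidence
accumulation process.  The spotlight is centred on the target and narrows
linearly over decision time, so the foil contribution — which helps on
congruent trials and hurts on incongruent trials — decays within a trial.

Units
-----
Two clocks are in play, chosen so that conventional parameter scales stay
coherent with millisecond response times:

* evidence accumulation runs in **seconds** — ``ter`` is in seconds and ``p``
  is evidence per second, matching non-decision times around 0.3 and RTs around
  0.3–1.0 s;
* the spotlight narrows on a **millisecond** clock — ``rd`` is spotlight-sd
  units per millisecond of decision time, so the interference time
  ``sd_a / rd`` is in milliseconds and fits on the same scale as the
  congruency effects it explains.

Functions taking a decision time ``t`` below expect it on the spotlight
(millisecond) clock; the simulator converts.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.special import ndtr

__all__ = [
    "SSPParameters",
    "StimulusLayout",
    "DEFAULT_START",
    "spotlight_sd",
    "attention_weights",
    "drift_rate",
    "interference_time",
]


@dataclass(frozen=True)
class SSPParameters:
    """The five free parameters of one participant.

    Parameters
    ----------
    a:
        Boundary separation (evidence units); the decision terminates when the
        accumulated evidence reaches ``+a`` (correct) or ``-a`` (error).
        Indexes response caution.
    ter:
        Non-decision time in seconds (encoding + motor).
    p:
        Perceptual strength of a single attended item, in evidence per second.
    sd_a:
        Spotlight standard deviation at stimulus onset, in stimulus-width
        units.
    rd:
        Spotlight narrowing rate, in sd units per millisecond of decision
        time.
    """

    a: float
    ter: float
    p: float
    sd_a: float
    rd: float

    def __post_init__(self) -> None:
        if not self.a > 0:
            raise ValueError(f"boundary separation must be positive, got a={self.a}")
        if not self.ter >= 0:
            raise ValueError(f"non-decision time must be non-negative, got ter={self.ter}")
        if not self.p > 0:
            raise ValueError(f"perceptual strength must be positive, got p={self.p}")
        if not self.sd_a > 0:
            raise ValueError(f"initial spotlight sd must be positive, got sd_a={self.sd_a}")
        if not self.rd > 0:
            raise ValueError(f"narrowing rate must be positive, got rd={self.rd}")

    @property
    def interference_time(self) -> float:
        """Time (ms of decision time) for the spotlight to fully narrow."""
        return self.sd_a / self.rd

    def replace(self, **kwargs) -> "SSPParameters":
        return replace(self, **kwargs)

    def as_array(self) -> np.ndarray:
        return np.array([self.a, self.ter, self.p, self.sd_a, self.rd])

    @classmethod
    def from_array(cls, theta) -> "SSPParameters":
        a, ter, p, sd_a, rd = (float(x) for x in theta)
        return cls(a=a, ter=ter, p=p, sd_a=sd_a, rd=rd)


#: Conventional starting values for the fitting routine.
DEFAULT_START = SSPParameters(a=0.05, ter=0.3, p=0.4, sd_a=1.5, rd=0.05)


@dataclass(frozen=True)
class StimulusLayout:
    """Spatial arrangement of one target and four foils on a 1-D axis.

    The target sits at 0 with two foils on each side; items are contiguous
    unit-width rectangles, item *i* spanning ``[centre_i - width/2,
    centre_i + width/2]``.  ``foil_sign`` is +1 when the foils point with the
    target (congruent) and -1 when they oppose it (incongruent).
    """

    positions: tuple[float, ...] = (-2.0, -1.0, 0.0, 1.0, 2.0)
    width: float = 1.0
    foil_sign: int = -1

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.size != 5 or np.count_nonzero(pos == 0.0) != 1:
            raise ValueError("layout needs exactly one target at 0 and four foils")
        if not np.allclose(np.sort(pos), np.sort(-pos)):
            raise ValueError("layout must be symmetric about the target")
        if self.width <= 0:
            raise ValueError("item width must be positive")
        if self.foil_sign not in (-1, 1):
            raise ValueError("foil_sign must be +1 (congruent) or -1 (incongruent)")

    @property
    def target_index(self) -> int:
        return int(np.flatnonzero(np.asarray(self.positions) == 0.0)[0])

    @classmethod
    def for_condition(cls, condition: str) -> "StimulusLayout":
        """Standard five-item layout for ``"congruent"`` or ``"incongruent"``."""
        condition = condition.strip().lower()
        if condition == "congruent":
            return cls(foil_sign=+1)
        if condition == "incongruent":
            return cls(foil_sign=-1)
        raise ValueError(f"unknown condition {condition!r}")


def spotlight_sd(t, params: SSPParameters, sd_floor: float = 0.001):
    """Spotlight standard deviation after ``t`` ms of decision time.

    Linear narrowing ``max(sd_a - rd * t, sd_floor)``; the floor keeps the
    Gaussian mass computation well defined once the spotlight has fully
    collapsed onto the target.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("decision time must be non-negative")
    out = np.maximum(params.sd_a - params.rd * t, sd_floor)
    return out if out.ndim else float(out)

def attention_weights(
    t, params: SSPParameters, layout: StimulusLayout | None = None, sd_floor: float = 0.001
) -> np.ndarray:
    """Gaussian spotlight mass over each of the five items at time ``t`` (ms).

    Item *i* receives the mass of a zero-mean normal with sd ``spotlight_sd(t)``
    over its spatial extent.  Returns shape ``(5,)`` for scalar ``t`` and
    ``(len(t), 5)`` for a vector of times.
    """
    if layout is None:
        layout = StimulusLayout()
    sd = np.atleast_1d(np.asarray(spotlight_sd(t, params, sd_floor), dtype=float))
    centres = np.asarray(layout.positions, dtype=float)
    half = layout.width / 2.0
    lo = (centres - half)[None, :] / sd[:, None]
    hi = (centres + half)[None, :] / sd[:, None]
    w = ndtr(hi) - ndtr(lo)
    return w[0] if np.isscalar(t) or np.ndim(t) == 0 else w

def drift_rate(
    t, params: SSPParameters, layout: StimulusLayout, sd_floor: float = 0.001
):
    """Signed drift toward the correct boundary at decision time ``t`` (ms).

    ``v(t) = p * (w_target(t) + foil_sign * sum(w_foils(t)))`` — positive drift
    favours the correct response.  On incongruent trials the early, wide
    spotlight can make ``v`` negative, which is what produces fast errors.
    """
    w = np.atleast_2d(attention_weights(t, params, layout, sd_floor))
    ti = layout.target_index
    w_target = w[:, ti]
    w_foils = w.sum(axis=1) - w_target
    v = params.p * (w_target + layout.foil_sign * w_foils)
    return float(v[0]) if np.ndim(t) == 0 else v


def interference_time(params: SSPParameters) -> float:
    """``sd_a / rd``: how long (ms) foil interference persists within a trial."""
    if params.rd <= 0:
        raise ValueError("rd must be positive")
    return params.sd_a / params.rd
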