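"""Piecewise saturable kinetics: delayed-saturation fits and half-times.

Baseline-normalized biosensor traces that respond to a step of input are
well described by a delayed saturable rise

    f(t) = 1                      for t < τ
    f(t) = s − (s − 1)·e^{b(t−τ)} for t ≥ τ

with saturation value ``s``, adjustable delay ``τ`` and rate constant
``b < 0``, whose half-time is t½ = −ln 2 / b.  Two sequential stimulation
phases (e.g. local then global) are captured by a two-stage version that is
continuous at the second knot τ₂ by construction:

    f(t) = 1                        for t < τ₁
    f(t) = s₁ − (s₁−1)·e^{b₁(t−τ₁)} for τ₁ ≤ t ≤ τ₂
    f(t) = s₂ − (s₂−v)·e^{b₂(t−τ₂)} for t > τ₂,   v = s₁ − (s₁−1)·e^{b₁(τ₂−τ₁)}

A pulse-pair recovery experiment (peak-height ratio of a second response as
a function of recovery time) is summarized by fitting an exponential
approach to full recovery, ratio(t) = 1 − (1 − r₀)·e^{−kt}; the recovery
half-time is ln 2 / k.  That functional form is this package's choice of
summary model for recovery curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .errors import InvalidArgumentError, NonConvergenceError

__all__ = [
    "SaturableFit",
    "TwoStageFit",
    "RecoveryCurve",
    "eval_saturable",
    "eval_two_stage",
    "half_time",
    "fit_saturable",
    "fit_two_stage",
    "recovery_half_time",
]


@dataclass
class SaturableFit:
    """Fitted parameters of the delayed saturable rise."""

    s: float
    tau_s: float
    b: float  # 1/s, negative for a saturating rise
    residual_norm: float = np.nan
    non_identifiable: bool = False

    @property
    def half_time_s(self) -> float:
        return half_time(self.b)


@dataclass
class TwoStageFit:
    """Fitted parameters of the two-stage saturable function.

    ``v`` is derived, not fitted: it is the stage-1 value at τ₂, which makes
    the curve continuous there exactly.
    """

    s1: float
    tau1_s: float
    b1: float
    s2: float
    tau2_s: float
    b2: float
    residual_norm: float = np.nan
    v: float = field(init=False)

    def __post_init__(self):
        if not self.tau1_s < self.tau2_s:
            raise InvalidArgumentError("tau1 must be < tau2")
        self.v = float(self.s1 - (self.s1 - 1.0) * np.exp(self.b1 * (self.tau2_s - self.tau1_s)))

    @property
    def half_times_s(self) -> tuple[float, float]:
        return (half_time(self.b1), half_time(self.b2))


@dataclass
class RecoveryCurve:
    """Pulse-pair recovery data: second/first peak-height ratio vs recovery time."""

    recovery_times_s: np.ndarray
    peak_ratios: np.ndarray

    def __post_init__(self):
        self.recovery_times_s = np.asarray(self.recovery_times_s, dtype=float)
        self.peak_ratios = np.asarray(self.peak_ratios, dtype=float)
        if len(self.recovery_times_s) != len(self.peak_ratios):
            raise InvalidArgumentError("times and ratios must match")
        if np.any(self.peak_ratios <= 0):
            raise InvalidArgumentError("peak ratios must be positive")


def eval_saturable(t, s: float, tau: float, b: float):
    """Evaluate the delayed saturable rise; equals 1 for t < τ and
    approaches s as t → ∞ when b < 0."""
    t = np.asarray(t, dtype=float)
    out = np.where(t < tau, 1.0, s - (s - 1.0) * np.exp(b * (t - tau)))
    return out if out.ndim else float(out)


def eval_two_stage(t, s1, tau1, b1, s2, tau2, b2):
    """Evaluate the two-stage saturable function, continuous at τ₁ and τ₂."""
    if not tau1 < tau2:
        raise InvalidArgumentError("tau1 must be < tau2")
    t = np.asarray(t, dtype=float)
    v = s1 - (s1 - 1.0) * np.exp(b1 * (tau2 - tau1))
    stage1 = s1 - (s1 - 1.0) * np.exp(b1 * (t - tau1))
    stage2 = s2 - (s2 - v) * np.exp(b2 * (t - tau2))
    out = np.where(t < tau1, 1.0, np.where(t <= tau2, stage1, stage2))
    return out if out.ndim else float(out)


def half_time(b: float) -> float:
    """Half-time of a saturable rise: t½ = −ln 2 / b, requiring b < 0."""
    if b >= 0:
        raise InvalidArgumentError("b must be negative for a saturating rise")
    return -np.log(2.0) / b


def _initial_guess(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    s0 = max(float(np.max(y)), 1.0 + 1e-6)
    rise = y > 1.0 + 0.1 * (s0 - 1.0)
    tau0 = float(t[rise][0]) if rise.any() else float(t[0])
    half_level = 1.0 + 0.5 * (s0 - 1.0)
    above = y >= half_level
    t_half_rise = float(t[above][0]) - tau0 if above.any() else (t[-1] - t[0]) / 4.0
    b0 = -np.log(2.0) / max(t_half_rise, (t[1] - t[0]))
    return s0, tau0, b0


def fit_saturable(t_s, trace) -> SaturableFit:
    """Nonlinear least-squares fit of the delayed saturable rise to a
    baseline-normalized trace (pre-stimulus level ≈ 1).

    Initialization: s from the trace maximum, τ from the first excursion
    above 10% of the rise, b from the time to half-rise.  Bounds keep
    s ≥ 1, b < 0 and τ within the trace span.  Flat traces are flagged
    non-identifiable rather than fitted.
    """
    t = np.asarray(t_s, dtype=float)
    y = np.asarray(trace, dtype=float)
    if len(t) < 10:
        raise InvalidArgumentError("need >= 10 points to fit")
    if np.ptp(y) < 1e-9 or np.max(y) <= 1.0 + 1e-9:
        return SaturableFit(
            s=float(np.mean(y)), tau_s=float(t[0]), b=-1e-12,
            residual_norm=float(np.linalg.norm(y - np.mean(y))),
            non_identifiable=True,
        )
    p0 = _initial_guess(t, y)
    bounds = ([1.0, t[0], -np.inf], [np.inf, t[-1], -1e-12])
    p0 = np.clip(p0, bounds[0], bounds[1])
    try:
        popt, _ = curve_fit(eval_saturable, t, y, p0=p0, bounds=bounds, maxfev=20000)
    except RuntimeError as exc:
        raise NonConvergenceError(str(exc), best_params=tuple(p0)) from exc
    resid = y - eval_saturable(t, *popt)
    return SaturableFit(
        s=float(popt[0]), tau_s=float(popt[1]), b=float(popt[2]),
        residual_norm=float(np.linalg.norm(resid)),
    )


def fit_two_stage(t_s, trace, switch_hint_s: float) -> TwoStageFit:
    """Fit the two-stage saturable function around a known phase switch.

    ``switch_hint_s`` initializes τ₂ (the local → global switch time); both
    knots are free within the trace span subject to τ₁ < τ₂.
    """
    t = np.asarray(t_s, dtype=float)
    y = np.asarray(trace, dtype=float)
    pre = t < switch_hint_s
    post = ~pre
    if pre.sum() < 10 or post.sum() < 10:
        raise InvalidArgumentError("need >= 10 points per stage")
    s1_0, tau1_0, b1_0 = _initial_guess(t[pre], y[pre])
    s2_0 = max(float(np.max(y[post])), s1_0 + 1e-6)
    b2_0 = b1_0

    def model(tt, s1, tau1, b1, s2, dtau2, b2):
        # parametrize tau2 = tau1 + dtau2 (dtau2 > 0) to enforce ordering
        return eval_two_stage(tt, s1, tau1, b1, s2, tau1 + dtau2, b2)

    p0 = [s1_0, tau1_0, b1_0, s2_0, max(switch_hint_s - tau1_0, 1.0), b2_0]
    lb = [1.0, t[0], -np.inf, 1.0, 1e-6, -np.inf]
    ub = [np.inf, t[-1], -1e-12, np.inf, t[-1] - t[0], -1e-12]
    p0 = np.clip(p0, lb, ub)
    try:
        popt, _ = curve_fit(model, t, y, p0=p0, bounds=(lb, ub), maxfev=40000)
    except RuntimeError as exc:
        raise NonConvergenceError(str(exc), best_params=tuple(p0)) from exc
    s1, tau1, b1, s2, dtau2, b2 = popt
    resid = y - model(t, *popt)
    return TwoStageFit(
        s1=float(s1), tau1_s=float(tau1), b1=float(b1),
        s2=float(s2), tau2_s=float(tau1 + dtau2), b2=float(b2),
        residual_norm=float(np.linalg.norm(resid)),
    )


def recovery_half_time(curve: RecoveryCurve) -> float:
    """Recovery half-time from a pulse-pair recovery curve.

    Fits ratio(t) = 1 − (1 − r₀)·e^{−kt} (exponential approach to full
    recovery) and returns ln 2 / k in seconds.  Curves already at full
    recovery everywhere are flagged saturated (k unbounded) via an error.
    """
    t = curve.recovery_times_s
    r = curve.peak_ratios
    if len(t) < 3:
        raise InvalidArgumentError("need >= 3 recovery time points")
    if np.all(r >= 1.0 - 1e-9):
        raise InvalidArgumentError(
            "saturated-recovery: all ratios at or above 1; half-time unresolved"
        )

    def model(tt, r0, k):
        return 1.0 - (1.0 - r0) * np.exp(-k * tt)

    r0_0 = min(max(float(r[np.argmin(t)]), 0.0), 0.99)
    k0 = 1.0 / max(float(np.median(t)), 1e-6)
    try:
        popt, _ = curve_fit(
            model, t, r, p0=[r0_0, k0],
            bounds=([0.0, 1e-9], [1.0, np.inf]), maxfev=20000,
        )
    except RuntimeError as exc:
        raise NonConvergenceError(str(exc)) from exc
    k = float(popt[1])
    if k <= 0:
        raise NonConvergenceError("non-positive recovery rate")
    return float(np.log(2.0) / k)
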