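"""Arrhenius-like developmental-duration model for RNAi feeding times.

Embryogenesis (and, by extension, RNAi feeding-by-ingestion induction)
duration shortens with temperature roughly exponentially. With the
temperature in Celsius Tc and a reference T0 = 273 K, the duration law is

    t(Tc) = A / exp(alpha · Tc / (1 + Tc/T0)),

a reparameterised Arrhenius form: alpha·Tc/(1 + Tc/T0) equals
(alpha·T0)·(1/T0 − 1/T) with T = T0 + Tc in kelvin, so alpha·T0·kB plays the
role of an activation energy. Fitting published embryogenesis durations pins
alpha; refitting only the prefactor A on published feeding durations then
extrapolates feeding times to other culture temperatures.

Fits are least squares in log-duration (durations span a several-fold range,
so multiplicative error is the natural model). T0 is kept at 273 K.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["T0_KELVIN", "FeedingModel", "fit_alpha", "fit_prefactor", "predict_feeding"]

T0_KELVIN = 273.0


def _g(tc: np.ndarray) -> np.ndarray:
    """Regressor g(Tc) = Tc/(1 + Tc/T0); log t = log A − alpha·g(Tc)."""
    tc = np.asarray(tc, dtype=float)
    if np.any(tc <= -T0_KELVIN):
        raise ValueError(f"temperature at or below −T0 = −{T0_KELVIN} °C: singular denominator")
    return tc / (1.0 + tc / T0_KELVIN)


@dataclass(frozen=True)
class FeedingModel:
    """t(Tc) = prefactor_A / exp(alpha·Tc/(1 + Tc/T0)); durations in hours."""

    alpha: float  # dimensionless per-°C rate coefficient
    prefactor_A: float  # hours
    T0: float = T0_KELVIN
    fitted_on: tuple[tuple[float, float], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise ValueError(f"alpha must be > 0, got {self.alpha}")
        if not self.prefactor_A > 0:
            raise ValueError(f"prefactor_A must be > 0, got {self.prefactor_A}")


def _clean(points) -> tuple[np.ndarray, np.ndarray]:
    pts = [(float(tc), float(d)) for tc, d in points]
    tc = np.array([p[0] for p in pts])
    d = np.array([p[1] for p in pts])
    if np.any(d <= 0):
        raise ValueError("durations must be strictly positive")
    return tc, d


def fit_alpha(points) -> FeedingModel:
    """Fit (alpha, A) to (temperature °C, duration h) pairs.

    Least squares of log duration against g(Tc) = Tc/(1 + Tc/T0): the slope
    is −alpha, the intercept log A. Requires >= 3 points at distinct
    temperatures. Durations that do not decrease with temperature yield
    alpha <= 0, which violates the model and is rejected.
    """
    tc, d = _clean(points)
    if len(tc) < 3:
        raise ValueError(f"need >= 3 points to fit alpha, got {len(tc)}")
    if len(np.unique(tc)) < len(tc):
        raise ValueError("temperatures must be distinct")
    slope, intercept = np.polyfit(_g(tc), np.log(d), 1)
    alpha = -float(slope)
    if alpha <= 1e-12:  # numerically flat or increasing durations
        warnings.warn("fitted alpha is not positive: durations do not shorten "
                      "with temperature", stacklevel=2)
        raise ValueError(f"fitted alpha = {alpha} violates alpha > 0")
    return FeedingModel(alpha=alpha, prefactor_A=float(np.exp(intercept)),
                        fitted_on=tuple((float(t), float(x)) for t, x in zip(tc, d)))


def fit_prefactor(points, alpha: float) -> float:
    """Refit only A with the slope fixed at −alpha (log-space least squares).

    The closed form is exp(mean(log duration + alpha·g(Tc))).
    """
    if alpha <= 0:
        raise ValueError(f"alpha must be > 0, got {alpha}")
    tc, d = _clean(points)
    if len(tc) < 1:
        raise ValueError("need >= 1 point to fit the prefactor")
    return float(np.exp(np.mean(np.log(d) + alpha * _g(tc))))


def predict_feeding(model: FeedingModel, tc) -> np.ndarray | float:
    """Predicted feeding duration (hours) at temperature(s) tc in °C."""
    g = _g(tc)
    out = model.prefactor_A / np.exp(model.alpha * g)
    return float(out) if np.isscalar(tc) else out
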