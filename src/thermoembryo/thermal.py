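"""Thermal-response statistics for the embryo feature screen.

Within the thermal range a feature is classified as temperature-dependent by
Pearson correlation with Bonferroni correction across the feature family.
Beyond each thermal limit, a change in thermal response is tested by a
nested-model F-test: the within-range model (constant, linear or exponential
in temperature) is compared against the same model augmented with a linear
deviation term β·(T − limit) that is active only beyond the tested limit,

    F = ((RSS1 − RSS2)/(p2 − p1)) / (RSS2/(n − p2)),

with (p2 − p1, n − p2) degrees of freedom under the null. The same machinery
is reused on log respiration (Arrhenius within-range form) to detect
departures from exponential kinetics beyond the limits. The module also fits
Arrhenius kinetics (duration = A·exp(−E/(kB·T))) and detects the thermal
limits themselves from hatching-viability tables (>90% criterion).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares

from .synthdata import KB_EV

__all__ = [
    "ScreenResult",
    "ThermalModelFit",
    "ArrheniusFit",
    "ThermalLimits",
    "FeatureReport",
    "pearson_screen",
    "fit_within_range",
    "ftest_beyond_limit",
    "classify_feature",
    "classify_table",
    "arrhenius_fit",
    "arrhenius_r2",
    "detect_limits",
    "respiration_departure",
]

_CELSIUS_OFFSET = 273.15


@dataclass(frozen=True)
class ScreenResult:
    feature: str
    pearson_r: float
    pearson_p: float
    temperature_dependent: bool
    bonferroni_threshold: float
    n_obs: int
    untestable: bool = False


@dataclass(frozen=True)
class ThermalModelFit:
    """Nested-model comparison beyond one thermal limit."""

    feature: str
    side: str  # "lower" | "upper"
    within_kind: str  # constant | linear | exponential
    y0: float
    alpha: float
    beta: float  # beyond-limit deviation slope, units/°C
    rss1: float
    rss2: float
    p1: int
    p2: int
    n_obs: int
    F: float
    p_value: float
    changed: bool


@dataclass(frozen=True)
class ArrheniusFit:
    """duration = prefactor · exp(−E/(kB·T)); E in eV, T in kelvin."""

    prefactor: float
    E: float
    r2_percent: float
    n_obs: int
    kB: float = KB_EV


@dataclass(frozen=True)
class ThermalLimits:
    lower: float
    upper: float
    criterion: float = 0.90


@dataclass(frozen=True)
class FeatureReport:
    feature: str
    screen: ScreenResult
    within_kind: Optional[str]
    lower: Optional[ThermalModelFit]
    upper: Optional[ThermalModelFit]
    notes: tuple[str, ...] = ()

    @property
    def untestable(self) -> bool:
        return self.screen.untestable


# ---------------------------------------------------------------------------
# within-range screen


def pearson_screen(table: pd.DataFrame, range_: tuple[float, float],
                   M: Optional[int] = None, family_alpha: float = 0.05) -> list[ScreenResult]:
    """Pearson screen for temperature dependence within the thermal range.

    ``table`` is tidy (feature, temperature, value). A feature is
    temperature-dependent iff its two-sided Pearson p-value is below
    family_alpha/M (Bonferroni across the M-feature family; M defaults to the
    number of features in the table). Constant features are reported with
    r = 0; features with fewer than 3 within-range observations are flagged
    untestable.
    """
    lo, hi = range_
    features = list(dict.fromkeys(table["feature"]))
    if M is None:
        M = len(features)
    if M < 1:
        raise ValueError("M must be >= 1")
    threshold = family_alpha / M
    out = []
    for feature in features:
        sub = table[(table["feature"] == feature)
                    & (table["temperature"] >= lo) & (table["temperature"] <= hi)]
        sub = sub.dropna(subset=["value"])
        T = sub["temperature"].to_numpy(dtype=float)
        y = sub["value"].to_numpy(dtype=float)
        n = len(y)
        if n < 3 or len(np.unique(T)) < 3:
            out.append(ScreenResult(feature, np.nan, np.nan, False, threshold, n,
                                    untestable=True))
            continue
        if np.ptp(y) < 1e-300:
            out.append(ScreenResult(feature, 0.0, 1.0, False, threshold, n))
            continue
        r, p = stats.pearsonr(T, y)
        out.append(ScreenResult(feature, float(r), float(p), bool(p < threshold),
                                threshold, n))
    return out


# ---------------------------------------------------------------------------
# within-range model


def _rss(y: np.ndarray, yhat: np.ndarray) -> float:
    return float(np.sum((y - yhat) ** 2))


def fit_within_range(T, y, dependent: bool, log_space: bool = True):
    """Fit the within-range thermal-response model.

    Temperature-independent features use the constant model (1 parameter).
    Dependent features are fitted with both y = y0 + α·T and y = y0·exp(α·T)
    (2 parameters each) and the model with the smaller residual sum of squares
    in data space wins; ties go to the linear model. The exponential candidate
    requires all y > 0 and is fitted in log space by default (deterministic,
    convex), with ``log_space=False`` switching to nonlinear least squares.

    Returns (kind, params, rss) where params = (y0, alpha).
    """
    T = np.asarray(T, dtype=float)
    y = np.asarray(y, dtype=float)
    if not dependent:
        if len(y) < 1:
            raise ValueError("need at least 1 observation for the constant model")
        mu = float(np.mean(y))
        return "constant", (mu, 0.0), _rss(y, np.full_like(y, mu))
    if len(y) < 2:
        raise ValueError("need at least 2 observations for a 2-parameter model")
    slope, intercept = np.polyfit(T, y, 1)
    lin_params = (float(intercept), float(slope))
    lin_rss = _rss(y, intercept + slope * T)
    if np.all(y > 0):
        ls, li = np.polyfit(T, np.log(y), 1)
        y0, alpha = float(np.exp(li)), float(ls)
        if not log_space:
            res = least_squares(lambda p: p[0] * np.exp(p[1] * T) - y, x0=[y0, alpha])
            y0, alpha = (float(v) for v in res.x)
        exp_rss = _rss(y, y0 * np.exp(alpha * T))
        if exp_rss < lin_rss:
            return "exponential", (y0, alpha), exp_rss
    return "linear", lin_params, lin_rss


# ---------------------------------------------------------------------------
# nested-model F-test beyond a limit


def _nested_f(rss1: float, rss2: float, p1: int, p2: int, n: int):
    if n <= p2:
        raise ValueError(f"need more observations than parameters (n={n}, p2={p2})")
    scale = max(abs(rss1), 1.0)
    if rss2 > rss1 + 1e-9 * scale:
        raise RuntimeError(
            f"optimizer failure: extended model fits worse (rss2={rss2} > rss1={rss1})")
    rss2c = min(rss2, rss1)
    denom = rss2c / (n - p2)
    F = np.inf if denom == 0 else ((rss1 - rss2c) / (p2 - p1)) / denom
    F = max(float(F), 0.0)
    p = float(stats.f.sf(F, p2 - p1, n - p2))
    return F, max(p, np.finfo(float).tiny)  # keep p in (0, 1]


def _design(kind: str, T: np.ndarray, hinge: Optional[np.ndarray]):
    cols = [np.ones_like(T)]
    if kind == "linear":
        cols.append(T)
    elif kind == "arrhenius":
        cols.append(1.0 / (T + _CELSIUS_OFFSET))
    if hinge is not None:
        cols.append(hinge)
    return np.column_stack(cols)


def _lstsq_rss(X: np.ndarray, y: np.ndarray):
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    return coef, _rss(y, X @ coef)


def ftest_beyond_limit(T, y, range_: tuple[float, float], side: str,
                       dependent: bool, threshold: float = 0.0014,
                       feature: str = "", within_kind: Optional[str] = None,
                       log_space: bool = True) -> ThermalModelFit:
    """Test whether the thermal response changes beyond one thermal limit.

    The data subset is the within-range observations plus the observations
    beyond the tested side only (the edge temperature belongs to both; the
    deviation term vanishes there, so its inclusion is inert). Model 1 is the
    within-range form refit to this subset; model 2 adds β·(T − edge) active
    only beyond the tested limit, with all parameters refit jointly. ``side``
    is "lower" or "upper"; ``within_kind`` forces the within-range model form
    (e.g. "arrhenius" for log respiration: linear in 1/T[K]); otherwise it is
    chosen by :func:`fit_within_range` on the within-range observations.
    """
    if side not in ("lower", "upper"):
        raise ValueError("side must be 'lower' or 'upper'")
    T = np.asarray(T, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(T) & np.isfinite(y)
    T, y = T[mask], y[mask]
    lo, hi = range_
    within = (T >= lo) & (T <= hi)
    edge = lo if side == "lower" else hi
    beyond = (T <= lo) if side == "lower" else (T >= hi)
    if (beyond & ~within).sum() < 1:
        raise ValueError(f"need observations beyond the {side} limit")
    keep = within | beyond
    Ts, ys = T[keep], y[keep]
    n = len(ys)
    hinge = (Ts - edge) * ((Ts <= edge) if side == "lower" else (Ts >= edge))

    if within_kind is None:
        within_kind, _, _ = fit_within_range(T[within], y[within], dependent,
                                             log_space=log_space)

    if within_kind == "exponential":
        p1, p2 = 2, 3
        ls, li = np.polyfit(Ts, np.log(np.abs(ys) + 1e-300), 1) if np.all(ys > 0) \
            else (0.0, np.log(max(abs(np.mean(ys)), 1e-6)))
        x0 = [float(np.exp(li)), float(ls)]
        res1 = least_squares(lambda p: p[0] * np.exp(p[1] * Ts) - ys, x0=x0)
        rss1 = float(2.0 * res1.cost)
        y0_1, a_1 = (float(v) for v in res1.x)
        # extended model starts at the nested optimum with β = 0, so its loss
        # can only improve
        res2 = least_squares(
            lambda p: p[0] * np.exp(p[1] * Ts) + p[2] * hinge - ys,
            x0=[y0_1, a_1, 0.0])
        rss2 = float(2.0 * res2.cost)
        y0_2, a_2, beta = (float(v) for v in res2.x)
    else:
        p1 = {"constant": 1, "linear": 2, "arrhenius": 2}[within_kind]
        p2 = p1 + 1
        X1 = _design(within_kind, Ts, None)
        X2 = _design(within_kind, Ts, hinge)
        c1, rss1 = _lstsq_rss(X1, ys)
        c2, rss2 = _lstsq_rss(X2, ys)
        y0_2 = float(c2[0])
        a_2 = float(c2[1]) if p1 == 2 else 0.0
        beta = float(c2[-1])

    F, p = _nested_f(rss1, rss2, p1, p2, n)
    return ThermalModelFit(
        feature=feature, side=side, within_kind=within_kind,
        y0=y0_2, alpha=a_2, beta=beta, rss1=rss1, rss2=rss2,
        p1=p1, p2=p2, n_obs=n, F=F, p_value=p, changed=bool(p < threshold))


# ---------------------------------------------------------------------------
# per-feature classification


def classify_feature(T, y, range_: tuple[float, float], M: int,
                     family_alpha: float = 0.05, threshold: Optional[float] = None,
                     feature: str = "") -> FeatureReport:
    """Full per-feature report: Pearson screen, within-range model, and the
    beyond-limit F-test on each side.

    ``threshold`` defaults to the Bonferroni-corrected family_alpha/M, the
    same level used for the screen. Sides that lack beyond-limit data are
    reported as None with a note.
    """
    T = np.asarray(T, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(T) & np.isfinite(y)
    T, y = T[mask], y[mask]
    if threshold is None:
        threshold = family_alpha / M
    if len(T) == 0:
        screen = ScreenResult(feature, np.nan, np.nan, False, family_alpha / M, 0,
                              untestable=True)
        return FeatureReport(feature, screen, None, None, None,
                             notes=("untestable: no finite observations",))
    table = pd.DataFrame({"feature": feature or "feature", "temperature": T, "value": y})
    screen = pearson_screen(table, range_, M=M, family_alpha=family_alpha)[0]
    screen = ScreenResult(feature, screen.pearson_r, screen.pearson_p,
                          screen.temperature_dependent, screen.bonferroni_threshold,
                          screen.n_obs, screen.untestable)
    if screen.untestable:
        return FeatureReport(feature, screen, None, None, None,
                             notes=("untestable: fewer than 3 within-range observations",))

    lo, hi = range_
    within = (T >= lo) & (T <= hi)
    kind, _, _ = fit_within_range(T[within], y[within], screen.temperature_dependent)
    fits: dict[str, Optional[ThermalModelFit]] = {}
    notes = []
    for side in ("lower", "upper"):
        try:
            fits[side] = ftest_beyond_limit(T, y, range_, side,
                                            dependent=screen.temperature_dependent,
                                            threshold=threshold, feature=feature,
                                            within_kind=kind)
        except ValueError as exc:
            fits[side] = None
            notes.append(f"{side}: {exc}")
    return FeatureReport(feature, screen, kind, fits["lower"], fits["upper"],
                         notes=tuple(notes))


def classify_table(table: pd.DataFrame, range_: tuple[float, float],
                   M: Optional[int] = None, family_alpha: float = 0.05,
                   threshold: Optional[float] = None) -> list[FeatureReport]:
    """Classify every feature in a tidy (feature, temperature, value) table."""
    features = list(dict.fromkeys(table["feature"]))
    if M is None:
        M = len(features)
    reports = []
    for feature in features:
        sub = table[table["feature"] == feature]
        reports.append(classify_feature(sub["temperature"], sub["value"], range_,
                                        M=M, family_alpha=family_alpha,
                                        threshold=threshold, feature=feature))
    return reports


def reports_to_frame(reports: list[FeatureReport]) -> pd.DataFrame:
    """Flatten feature reports into the screen's output table."""
    rows = []
    for r in reports:
        row = {
            "feature": r.feature,
            "pearson_r": r.screen.pearson_r,
            "pearson_p": r.screen.pearson_p,
            "dependence": ("untestable" if r.untestable else
                           "temperature-dependent" if r.screen.temperature_dependent
                           else "temperature-independent"),
            "within_kind": r.within_kind,
        }
        for side in ("lower", "upper"):
            fit = getattr(r, side)
            row[f"{side}_F"] = fit.F if fit else np.nan
            row[f"{side}_p"] = fit.p_value if fit else np.nan
            row[f"{side}_beta"] = fit.beta if fit else np.nan
            row[f"{side}_response"] = (("changed" if fit.changed else "unchanged")
                                       if fit else "untested")
        rows.append(row)
    columns = ["feature", "pearson_r", "pearson_p", "dependence", "within_kind",
               "lower_F", "lower_p", "lower_beta", "lower_response",
               "upper_F", "upper_p", "upper_beta", "upper_response"]
    return pd.DataFrame(rows, columns=columns)


# ---------------------------------------------------------------------------
# Arrhenius kinetics


def arrhenius_fit(T, durations, range_: Optional[tuple[float, float]] = None) -> ArrheniusFit:
    """Fit duration = A·exp(−E/(kB·T[K])) by least squares in log space.

    Only within-range observations enter the fit when ``range_`` is given.
    For durations that shorten with warming, E comes out negative in this
    sign convention (the corresponding rate 1/duration has activation energy
    −E > 0); r² is the explained variance of the log-space fit in percent.
    """
    T = np.asarray(T, dtype=float)
    d = np.asarray(durations, dtype=float)
    mask = np.isfinite(T) & np.isfinite(d)
    T, d = T[mask], d[mask]
    if np.any(d <= 0):
        raise ValueError("durations must be strictly positive")
    if range_ is not None:
        lo, hi = range_
        keep = (T >= lo) & (T <= hi)
        T, d = T[keep], d[keep]
    if len(d) < 2:
        raise ValueError("need >= 2 within-range observations")
    invT = 1.0 / (T + _CELSIUS_OFFSET)
    logd = np.log(d)
    slope, intercept = np.polyfit(invT, logd, 1)
    E = -float(slope) * KB_EV
    pred = intercept + slope * invT
    rss = _rss(logd, pred)
    tss = _rss(logd, np.full_like(logd, logd.mean()))
    r2 = 100.0 if tss == 0 else 100.0 * (1.0 - rss / tss)
    return ArrheniusFit(prefactor=float(np.exp(intercept)), E=E,
                        r2_percent=float(r2), n_obs=len(d))


def arrhenius_r2(fit: ArrheniusFit, T, durations) -> float:
    """Explained variance (%) of an existing Arrhenius fit on given data.

    Used to quantify departures: including beyond-range observations against
    the within-range line lowers r² when the data leave the exponential trend.
    """
    T = np.asarray(T, dtype=float)
    d = np.asarray(durations, dtype=float)
    if np.any(d <= 0):
        raise ValueError("durations must be strictly positive")
    logd = np.log(d)
    pred = np.log(fit.prefactor) - fit.E / (KB_EV * (T + _CELSIUS_OFFSET))
    rss = _rss(logd, pred)
    tss = _rss(logd, np.full_like(logd, logd.mean()))
    return 100.0 if tss == 0 else float(100.0 * (1.0 - rss / tss))


# ---------------------------------------------------------------------------
# thermal limits from viability


def detect_limits(viability: pd.DataFrame, criterion: float = 0.90) -> ThermalLimits:
    """Edges of the widest contiguous run of tested temperatures whose
    hatching fraction exceeds ``criterion``.

    Ties are broken toward the run containing 20 °C, then toward the warmer
    run. Returns degenerate limits (T, T) with a warning when only one tested
    temperature qualifies; warns "unbounded range" when every tested
    temperature qualifies; raises when none does.
    """
    df = viability.sort_values("temperature")
    T = df["temperature"].to_numpy(dtype=float)
    frac = df["fraction"].to_numpy(dtype=float)
    if len(T) < 2:
        raise ValueError("need >= 2 tested temperatures")
    ok = frac > criterion
    if not ok.any():
        raise ValueError("no viable range: no tested temperature exceeds the criterion")

    runs = []
    start = None
    for i, good in enumerate(ok):
        if good and start is None:
            start = i
        if (not good or i == len(ok) - 1) and start is not None:
            end = i if good else i - 1
            runs.append((start, end))
            start = None

    def run_key(run):
        s, e = run
        width = T[e] - T[s]
        contains_20 = T[s] <= 20.0 <= T[e]
        return (width, contains_20, T[e])

    best = max(runs, key=run_key)
    lower, upper = float(T[best[0]]), float(T[best[1]])
    if lower == upper:
        warnings.warn(f"degenerate thermal limits: only {lower} °C exceeds the criterion",
                      stacklevel=2)
    if ok.all():
        warnings.warn("unbounded range: every tested temperature exceeds the criterion",
                      stacklevel=2)
    return ThermalLimits(lower=lower, upper=upper, criterion=criterion)


# ---------------------------------------------------------------------------
# respiration departures


def respiration_departure(resp: pd.DataFrame, range_: tuple[float, float],
                          threshold: float = 0.0014) -> dict[str, ThermalModelFit]:
    """Nested-model F-test for departure of respiration from Arrhenius
    kinetics beyond each thermal limit.

    Operates on log O2 flow with the within-range model fixed to the
    exponential (Arrhenius) form — linear in 1/T[K] on the log scale — plus
    the per-side β·(T − edge) deviation term in °C.
    """
    T = resp["temperature"].to_numpy(dtype=float)
    flow = resp["flow"].to_numpy(dtype=float)
    if np.any(flow <= 0):
        raise ValueError("flows must be strictly positive")
    logf = np.log(flow)
    out = {}
    for side in ("lower", "upper"):
        out[side] = ftest_beyond_limit(T, logf, range_, side, dependent=True,
                                       threshold=threshold, feature="respiration",
                                       within_kind="arrhenius")
    return out
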