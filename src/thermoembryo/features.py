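"""Quantification of first-cell-cycle features from tracked embryo recordings.

A recording holds per-frame tracked positions (pronuclei, spindle poles),
eggshell and cell contours, and manually annotated event times. Cytokinesis
onset defines time zero, so every analysed timestamp is non-positive. From a
single recording this module extracts the feature family used by the thermal
screen: pronuclear migration speed, the Hill-type sigmoid describing
centration–rotation with its analytic peak velocity, spectral metrics of the
transverse anaphase spindle-pole oscillations, spindle elongation speeds,
cell-cycle timings, embryo geometry and division asymmetry.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.optimize import least_squares
from scipy.signal import find_peaks, hilbert
from shapely.geometry import Polygon

__all__ = [
    "EmbryoRecording",
    "SigmoidFit",
    "OscillationMetrics",
    "GeometryMetrics",
    "FeatureRow",
    "NoOscillationError",
    "centroid_correct",
    "pronucleus_speed",
    "fit_sigmoid",
    "oscillation_metrics",
    "elongation_speed",
    "cycle_timings",
    "embryo_geometry",
    "division_asymmetry",
    "extract_all",
]

TRACK_NAMES = (
    "female_pronucleus",
    "male_pronucleus",
    "spindle_pole_anterior",
    "spindle_pole_posterior",
)

EVENT_NAMES = ("pseudo_cleavage", "pronuclear_meeting", "mitotic_entry", "cytokinesis_onset")


class NoOscillationError(ValueError):
    """Raised when a signal has no spectral peak standing out from noise."""


@dataclass
class EmbryoRecording:
    """Tracked coordinates, contours and event times for one embryo.

    Coordinates are (x, y) in micrometres: x is the anterior–posterior axis,
    y the transverse axis. Tracks are (n_frames, 2) arrays with NaN where the
    structure does not exist in that phase of the cell cycle. The eggshell
    contour is an (n_frames, n_vertices, 2) array. Optional daughter-cell
    contours (keys ``"AB"``, ``"P1"``, optionally ``"embryo"``) are single
    polygons sampled at ``cell_contours_time`` seconds after cytokinesis onset.
    """

    timestamps: np.ndarray
    tracks: dict[str, np.ndarray]
    eggshell_contour: np.ndarray
    events: dict[str, float]
    temperature: float
    group: str = "wild-type"
    cell_contours: dict[str, np.ndarray] = field(default_factory=dict)
    cell_contours_time: Optional[float] = None

    def validate(self) -> None:
        t = np.asarray(self.timestamps, dtype=float)
        if t.ndim != 1 or len(t) < 2:
            raise ValueError("timestamps must be a 1-D array with >= 2 frames")
        if not np.all(np.diff(t) > 0):
            raise ValueError("timestamps must be strictly increasing")
        ev = self.events
        missing = [k for k in EVENT_NAMES if k not in ev]
        if missing:
            raise ValueError(f"missing event annotations: {missing}")
        if ev["cytokinesis_onset"] != 0.0:
            raise ValueError("cytokinesis_onset must define time 0")
        order = [ev[k] for k in EVENT_NAMES]
        if not all(a <= b for a, b in zip(order, order[1:])):
            raise ValueError(f"event times must be ordered {EVENT_NAMES}, got {order}")
        if any(v > 0 for v in order):
            raise ValueError("all event times must be <= 0 (cytokinesis onset is time 0)")

    @property
    def n_frames(self) -> int:
        return len(self.timestamps)


@dataclass(frozen=True)
class SigmoidFit:
    """Parameters of the centration–rotation model x = A·|t|^n/(K^n+|t|^n) + cte.

    K is the (positive) time at which the process is midway to completion:
    the fitted curve passes through A/2 + cte at |t| = K by construction.
    ``velocity_max`` is the maximum of the analytic speed |dx/dt| over the
    fitted window.
    """

    A: float
    K: float
    n: float
    cte: float
    rss: float
    velocity_max: float

    def __call__(self, t: np.ndarray) -> np.ndarray:
        at = np.abs(np.asarray(t, dtype=float))
        return self.A * at**self.n / (self.K**self.n + at**self.n) + self.cte

    def velocity(self, t: np.ndarray) -> np.ndarray:
        """Analytic dx/dt; uses d|t|/dt = -1 for t < 0."""
        at = np.abs(np.asarray(t, dtype=float))
        num = self.A * self.n * self.K**self.n * at ** (self.n - 1.0)
        return -num / (self.K**self.n + at**self.n) ** 2


@dataclass(frozen=True)
class OscillationMetrics:
    """Spectral description of transverse spindle-pole oscillations."""

    omega: float  # dominant angular frequency, rad/s
    frequency: float  # omega / 2π, Hz
    amplitude: float  # max peak-to-trough distance / 2, µm (primary definition)
    duration: float  # span where the filtered envelope exceeds a fraction of its max, s
    n_peaks: int
    amplitude_max_deviation: float  # max |filtered signal|, µm (secondary definition)


@dataclass(frozen=True)
class GeometryMetrics:
    embryo_area: float  # µm²
    length: float  # extent along first principal axis, µm
    width: float  # extent along second principal axis, µm
    aspect_ratio: float  # length / width, >= 1
    area_AB: Optional[float] = None
    area_P1: Optional[float] = None
    relative_AB: Optional[float] = None  # 100·AB/(AB+P1), %


@dataclass
class FeatureRow:
    """One embryo's feature vector plus per-feature missingness reasons."""

    temperature: float
    group: str
    values: dict[str, float] = field(default_factory=dict)
    missing: dict[str, str] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# drift correction


def _polygon(contour: np.ndarray) -> Polygon:
    poly = Polygon(np.asarray(contour, dtype=float))
    if not poly.is_valid:
        raise ValueError("self-intersecting (non-simple) polygon")
    return poly


def _shoelace_centroid(pts: np.ndarray) -> np.ndarray:
    """Area-weighted polygon centroid; vertex mean for degenerate polygons."""
    x, y = pts[:, 0], pts[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    area6 = 3.0 * cross.sum()
    if abs(area6) < 1e-12:
        return pts.mean(axis=0)
    return np.array([((x + xn) * cross).sum() / area6,
                     ((y + yn) * cross).sum() / area6])


def centroid_correct(rec: EmbryoRecording) -> EmbryoRecording:
    """Subtract the same-frame eggshell centroid from every tracked coordinate.

    Removes rigid drift of the embryo within the field of view (e.g. from the
    air flow of a temperature controller). Contours are re-centred at the
    origin. A frame that carries tracked points but no eggshell contour is an
    error naming the frame.
    """
    tracks = {k: np.array(v, dtype=float, copy=True) for k, v in rec.tracks.items()}
    contour = np.array(rec.eggshell_contour, dtype=float, copy=True)
    n = rec.n_frames
    centroids = np.full((n, 2), np.nan)
    for i in range(n):
        has_points = any(np.isfinite(v[i]).any() for v in tracks.values())
        has_contour = np.isfinite(contour[i]).all()
        if has_contour:
            centroids[i] = _shoelace_centroid(contour[i])
            contour[i] -= centroids[i]
        elif has_points:
            raise ValueError(f"frame {i} has tracked points but no eggshell contour")
    for v in tracks.values():
        v -= np.where(np.isfinite(centroids), centroids, 0.0)
    cells = dict(rec.cell_contours)
    if cells:
        # daughter contours are sampled just after the last frame; use the
        # last available eggshell centroid as their drift reference
        last = np.where(np.isfinite(centroids).all(axis=1))[0]
        if last.size:
            ref = centroids[last[-1]]
            cells = {k: np.asarray(v, dtype=float) - ref for k, v in cells.items()}
    return replace(rec, tracks=tracks, eggshell_contour=contour, cell_contours=cells)


# ---------------------------------------------------------------------------
# speeds and timings


def _ols_slope(t: np.ndarray, x: np.ndarray, what: str) -> float:
    mask = np.isfinite(t) & np.isfinite(x)
    if mask.sum() < 4:
        raise ValueError(f"{what}: need >= 4 frames in the window, got {int(mask.sum())}")
    slope, _ = np.polyfit(t[mask], x[mask], 1)
    return float(slope)


def pronucleus_speed(rec: EmbryoRecording) -> float:
    """Female-pronucleus migration speed, µm/s.

    Absolute OLS slope of the x position against time from recording start to
    pronuclear meeting.
    """
    t = np.asarray(rec.timestamps, dtype=float)
    x = np.asarray(rec.tracks["female_pronucleus"], dtype=float)[:, 0]
    window = t <= rec.events["pronuclear_meeting"]
    return abs(_ols_slope(t[window], x[window], "pronucleus_speed"))


def elongation_speed(rec: EmbryoRecording) -> tuple[float, float]:
    """Spindle-pole elongation speeds (anterior, posterior) in µm/s.

    Per-pole absolute OLS slopes of the x position over the mitotic window
    (mitotic entry to cytokinesis onset).
    """
    t = np.asarray(rec.timestamps, dtype=float)
    window = (t >= rec.events["mitotic_entry"]) & (t <= 0)
    out = []
    for name in ("spindle_pole_anterior", "spindle_pole_posterior"):
        x = np.asarray(rec.tracks[name], dtype=float)[:, 0]
        out.append(abs(_ols_slope(t[window], x[window], f"elongation_speed[{name}]")))
    return out[0], out[1]


def cycle_timings(rec: EmbryoRecording) -> dict[str, float]:
    """t_PM (pronuclear meeting → cytokinesis onset), mitosis duration
    (mitotic entry → onset) and their ratio."""
    for name in ("pronuclear_meeting", "mitotic_entry", "cytokinesis_onset"):
        if name not in rec.events:
            raise ValueError(f"missing event: {name}")
    pm = rec.events["pronuclear_meeting"]
    me = rec.events["mitotic_entry"]
    if me > 0 or pm > 0:
        raise ValueError("event times must be <= 0 (cytokinesis onset is time 0)")
    if pm > me:
        raise ValueError("pronuclear meeting must precede mitotic entry")
    t_pm = -pm
    mitosis = -me
    return {
        "t_PM": t_pm,
        "mitosis_duration": mitosis,
        "relative_mitosis": mitosis / t_pm if t_pm > 0 else math.nan,
    }


# ---------------------------------------------------------------------------
# sigmoid fit of centration–rotation


def _sigmoid(t: np.ndarray, A: float, K: float, n: float, cte: float) -> np.ndarray:
    at = np.abs(t)
    return A * at**n / (K**n + at**n) + cte


def fit_sigmoid(t: np.ndarray, x: np.ndarray) -> SigmoidFit:
    """Nonlinear least-squares fit of x = A·|t|^n/(K^n+|t|^n) + cte.

    Bounds: K > 0, 0.5 <= n <= 20; A and cte free. Initialisation: cte0 from
    the mean of the last 10% of samples (|t| smallest), A0 from the first 10%,
    K0 at the sample nearest half saturation, with a multi-start over
    n0 ∈ {2, 1, 4, 8}. Raises on non-convergence, carrying best-so-far
    diagnostics.
    """
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    mask = np.isfinite(t) & np.isfinite(x)
    t, x = t[mask], x[mask]
    if len(t) < 8:
        raise ValueError(f"need >= 8 samples to fit the sigmoid, got {len(t)}")
    if np.any(t > 0):
        raise ValueError("sigmoid fit expects times <= 0 (cytokinesis onset is time 0)")
    order = np.argsort(t)  # most negative (earliest) first
    t, x = t[order], x[order]

    if np.ptp(x) < 1e-12:  # degenerate flat input
        return SigmoidFit(A=0.0, K=float(np.median(np.abs(t)) or 1.0), n=1.0,
                          cte=float(np.mean(x)), rss=0.0, velocity_max=0.0)

    k10 = max(2, len(t) // 10)
    cte0 = float(np.mean(x[-k10:]))
    A0 = float(np.mean(x[:k10]) - cte0)
    if A0 == 0.0:
        A0 = float(np.ptp(x))
    half = cte0 + A0 / 2.0
    K0 = float(np.abs(t[np.argmin(np.abs(x - half))]))
    K0 = max(K0, 1e-3)

    lower = [-np.inf, 1e-9, 0.5, -np.inf]
    upper = [np.inf, np.inf, 20.0, np.inf]

    def resid(p):
        return _sigmoid(t, *p) - x

    best = None
    for n0 in (2.0, 1.0, 4.0, 8.0):
        try:
            res = least_squares(resid, x0=[A0, K0, n0, cte0], bounds=(lower, upper),
                                x_scale="jac", max_nfev=2000)
        except Exception:  # noqa: BLE001 - optimiser failure counts as a miss
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None or not np.all(np.isfinite(best.x)):
        raise RuntimeError(
            f"sigmoid fit failed to converge (best diagnostics: {best})")

    A, K, n, cte = (float(v) for v in best.x)
    rss = float(2.0 * best.cost)
    # analytic |dx/dt| maximised on a dense grid over the fitted window
    grid = np.linspace(t.min(), 0.0, 2001)
    fit = SigmoidFit(A=A, K=K, n=n, cte=cte, rss=rss, velocity_max=0.0)
    vmax = float(np.nanmax(np.abs(fit.velocity(grid[grid < 0]))))
    return replace_sigmoid(fit, velocity_max=vmax)


def replace_sigmoid(fit: SigmoidFit, **kw) -> SigmoidFit:
    d = dict(A=fit.A, K=fit.K, n=fit.n, cte=fit.cte, rss=fit.rss, velocity_max=fit.velocity_max)
    d.update(kw)
    return SigmoidFit(**d)


# ---------------------------------------------------------------------------
# spindle-pole oscillations


def oscillation_metrics(t: np.ndarray, y: np.ndarray,
                        envelope_fraction: float = 0.25) -> OscillationMetrics:
    """Dominant frequency, amplitude and duration of an oscillatory signal.

    The dominant angular frequency ω is taken from the largest non-DC
    magnitude of the discrete Fourier transform of the mean-removed signal.
    A linear drift term is then removed, estimated jointly with the dominant
    sinusoid (OLS on {1, t, sin ωt, cos ωt}) so that a pure in-bin sinusoid is
    left untouched while a drift ramp — whose periodic discontinuity would
    otherwise bleed ringing into the pass band — is subtracted. A
    hard frequency-domain mask then keeps components in
    [0.5·f_dom, 3·f_dom] — a low-pass at three times the dominant frequency to
    remove noise and a high-pass at half of it to remove drift. The mask
    cannot change the dominant frequency (asserted). Amplitude is half the
    maximum peak-to-trough distance of the filtered signal; duration is the
    time span over which the analytic-signal envelope exceeds
    ``envelope_fraction`` of its maximum.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(t) & np.isfinite(y)
    t, y = t[mask], y[mask]
    n = len(y)
    if n < 64:
        raise ValueError(f"need >= 64 uniformly sampled points, got {n}")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise ValueError("oscillation analysis requires uniform sampling")
    dt = float(dt[0])

    y0 = y - y.mean()
    mags = np.abs(np.fft.rfft(y0))
    nondc = mags[1:]
    k_dom = int(np.argmax(nondc)) + 1
    if mags[k_dom] <= 3.0 * np.median(nondc):
        raise NoOscillationError("no oscillation detected")
    freqs = np.fft.rfftfreq(n, d=dt)
    f_dom = float(freqs[k_dom])

    # remove linear drift, estimated jointly with the dominant sinusoid so a
    # pure oscillation is untouched
    phase = 2.0 * np.pi * f_dom * t
    X = np.column_stack([np.ones(n), t, np.sin(phase), np.cos(phase)])
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    y0 = y - (coef[0] + coef[1] * t)
    spec = np.fft.rfft(y0)

    band = (freqs >= 0.5 * f_dom) & (freqs <= 3.0 * f_dom)
    filtered_spec = np.where(band, spec, 0.0)
    filtered = np.fft.irfft(filtered_spec, n=n)
    k_after = int(np.argmax(np.abs(filtered_spec[1:]))) + 1
    assert k_after == k_dom, "band filtering changed the dominant frequency"

    peaks, _ = find_peaks(filtered)
    troughs, _ = find_peaks(-filtered)
    if peaks.size and troughs.size:
        amplitude = float(filtered[peaks].max() - filtered[troughs].min()) / 2.0
    else:
        amplitude = float(np.ptp(filtered)) / 2.0

    envelope = np.abs(hilbert(filtered))
    active = envelope > envelope_fraction * envelope.max()
    duration = float(t[active].max() - t[active].min()) if active.any() else 0.0

    return OscillationMetrics(
        omega=2.0 * math.pi * f_dom,
        frequency=f_dom,
        amplitude=amplitude,
        duration=duration,
        n_peaks=int(peaks.size),
        amplitude_max_deviation=float(np.abs(filtered).max()),
    )


# ---------------------------------------------------------------------------
# geometry


def embryo_geometry(contour: np.ndarray) -> GeometryMetrics:
    """Area (shoelace), length/width (principal-axis extents) and aspect ratio.

    Invariant to rigid rotation and translation of the contour.
    """
    pts = np.asarray(contour, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 8:
        raise ValueError("contour must be an (n >= 8, 2) point array")
    poly = _polygon(pts)
    area = float(poly.area)
    centred = pts - pts.mean(axis=0)
    cov = np.cov(centred.T)
    _, vecs = np.linalg.eigh(cov)  # ascending eigenvalues
    proj = centred @ vecs
    ext_minor = float(np.ptp(proj[:, 0]))
    ext_major = float(np.ptp(proj[:, 1]))
    length, width = max(ext_major, ext_minor), min(ext_major, ext_minor)
    if width <= 0:
        raise ValueError("degenerate contour: zero width")
    return GeometryMetrics(embryo_area=area, length=length, width=width,
                           aspect_ratio=length / width)


def division_asymmetry(contour_AB: np.ndarray, contour_P1: np.ndarray) -> float:
    """Relative AB size: 100·area(AB)/(area(AB)+area(P1)), in percent.

    Daughter contours are sampled at t ≈ 0.25·t_PM after cytokinesis onset.
    """
    a_ab = _polygon(np.asarray(contour_AB, dtype=float)).area
    a_p1 = _polygon(np.asarray(contour_P1, dtype=float)).area
    total = a_ab + a_p1
    if total <= 0:
        raise ValueError("zero total daughter-cell area")
    return float(100.0 * a_ab / total)


# ---------------------------------------------------------------------------
# aggregation


def extract_all(rec: EmbryoRecording, envelope_fraction: float = 0.25) -> FeatureRow:
    """Compute every feature a recording supports, with per-feature missingness.

    Drift correction is applied first when eggshell contours are present.
    Failures of individual features are recorded as missing values with a
    reason, never raised.
    """
    row = FeatureRow(temperature=rec.temperature, group=rec.group)

    def attempt(names, fn):
        try:
            result = fn()
        except Exception as exc:  # noqa: BLE001 - reason-coded missingness
            for name in names:
                row.missing[name] = str(exc)
            return
        for name, value in result.items():
            if value is None or (isinstance(value, float) and not math.isfinite(value)):
                row.missing[name] = "not finite"
            else:
                row.values[name] = float(value)

    if np.isfinite(np.asarray(rec.eggshell_contour, dtype=float)).all():
        try:
            rec = centroid_correct(rec)
        except ValueError as exc:
            warnings.warn(f"drift correction skipped: {exc}", stacklevel=2)

    t = np.asarray(rec.timestamps, dtype=float)

    attempt(["female_pronucleus_speed"],
            lambda: {"female_pronucleus_speed": pronucleus_speed(rec)})

    def _sigmoid_features():
        window = (t >= rec.events["pronuclear_meeting"]) & (t <= rec.events["mitotic_entry"])
        mid = 0.5 * (np.asarray(rec.tracks["spindle_pole_anterior"], dtype=float)[:, 0]
                     + np.asarray(rec.tracks["spindle_pole_posterior"], dtype=float)[:, 0])
        fit = fit_sigmoid(t[window], mid[window])
        return {"centration_A": fit.A, "centration_K": fit.K, "centration_n": fit.n,
                "centration_cte": fit.cte, "centration_max_velocity": fit.velocity_max}

    attempt(["centration_A", "centration_K", "centration_n", "centration_cte",
             "centration_max_velocity"], _sigmoid_features)

    def _osc_features():
        window = (t >= rec.events["mitotic_entry"]) & (t <= 0)
        y = np.asarray(rec.tracks["spindle_pole_posterior"], dtype=float)[:, 1]
        m = oscillation_metrics(t[window], y[window], envelope_fraction=envelope_fraction)
        return {"osc_frequency_hz": m.frequency, "osc_amplitude_um": m.amplitude,
                "osc_duration_s": m.duration, "osc_n_peaks": m.n_peaks}

    attempt(["osc_frequency_hz", "osc_amplitude_um", "osc_duration_s", "osc_n_peaks"],
            _osc_features)

    def _elongation():
        a, p = elongation_speed(rec)
        return {"elongation_speed_anterior": a, "elongation_speed_posterior": p}

    attempt(["elongation_speed_anterior", "elongation_speed_posterior"], _elongation)

    def _timings():
        d = cycle_timings(rec)
        return {"t_pm_s": d["t_PM"], "mitosis_duration_s": d["mitosis_duration"],
                "relative_mitosis": d["relative_mitosis"]}

    attempt(["t_pm_s", "mitosis_duration_s", "relative_mitosis"], _timings)

    def _geometry():
        contour = np.asarray(rec.eggshell_contour, dtype=float)
        idx = [i for i in range(len(contour)) if np.isfinite(contour[i]).all()]
        if not idx:
            raise ValueError("no eggshell contour available")
        g = embryo_geometry(contour[idx[-1]])
        return {"embryo_area_um2": g.embryo_area, "embryo_length_um": g.length,
                "embryo_width_um": g.width, "embryo_aspect_ratio": g.aspect_ratio}

    attempt(["embryo_area_um2", "embryo_length_um", "embryo_width_um",
             "embryo_aspect_ratio"], _geometry)

    def _asymmetry():
        cells = rec.cell_contours
        if "AB" not in cells or "P1" not in cells:
            raise ValueError("daughter-cell contours absent")
        return {"relative_ab_pct": division_asymmetry(cells["AB"], cells["P1"])}

    attempt(["relative_ab_pct"], _asymmetry)

    return row
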