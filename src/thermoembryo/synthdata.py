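"""Seeded generators for every input the analysis pipeline consumes.

No recordings from the original experiments are publicly deposited, so the
package ships forward models with the statistical structure the downstream
estimators assume: monotone pronuclear migration, a Hill-type sigmoid for
centration–rotation, damped noisy transverse spindle-pole oscillations with
drift, temperature trends in size and shape with piecewise-linear deviations
beyond the thermal limits, binomial hatching outcomes with a >90%-viability
plateau inside the species' thermal range, and Arrhenius (exponential)
respiration with departures beyond both limits.

Every generator is deterministic given its seed. Each generator's noiseless
output, fed to the corresponding estimator, recovers the truth parameters —
this round-trip is the backbone of the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import EmbryoRecording

__all__ = [
    "KB_EV",
    "RecordingParams",
    "SpeciesPreset",
    "FeatureResponseSpec",
    "C_ELEGANS",
    "C_BRIGGSAE",
    "SPECIES_PRESETS",
    "gen_recording",
    "gen_feature_table",
    "gen_viability",
    "gen_respiration",
    "preset_recording_params",
]

KB_EV = 8.617333e-5  # Boltzmann constant, eV/K
_CELSIUS_OFFSET = 273.15


@dataclass(frozen=True)
class RecordingParams:
    """Ground truth for one simulated embryo recording.

    ``sigmoid_truth`` = (A, K, n, cte) of the centration–rotation model;
    ``osc_truth`` = (amplitude µm, frequency Hz, damping 1/s, drift µm/s) of
    the posterior-pole transverse oscillation; ``event_times`` =
    (pseudo-cleavage, pronuclear meeting, mitotic entry, cytokinesis onset)
    in seconds, strictly ordered and all <= 0 with cytokinesis onset at 0.
    """

    temperature: float = 20.0
    frame_interval: float = 1.0  # s
    egg_semi_axes: tuple[float, float] = (25.0, 15.0)  # µm
    migration_speed: float = 0.1  # µm/s
    sigmoid_truth: tuple[float, float, float, float] = (30.0, 300.0, 4.0, 5.0)
    osc_truth: tuple[float, float, float, float] = (2.0, 0.0625, 0.0, 0.0)
    event_times: tuple[float, float, float, float] = (-1300.0, -1100.0, -400.0, 0.0)
    noise_sd: float = 0.0  # µm
    seed: int = 0
    drift_step_sd: float = 0.2  # µm per frame, random-walk stage drift
    spindle_half_length: float = 2.0  # µm at mitotic entry
    elongation_speeds: tuple[float, float] = (0.02, 0.03)  # µm/s (anterior, posterior)
    relative_ab_pct: float = 57.4  # division asymmetry truth, %
    contour_vertices: int = 64
    group: str = "wild-type"

    def validate(self) -> None:
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        _, K, n, _ = self.sigmoid_truth
        if K <= 0 or n <= 0:
            raise ValueError("sigmoid truth requires K > 0 and n > 0")
        ev = self.event_times
        if any(a >= b for a, b in zip(ev, ev[1:])):
            raise ValueError(f"event times must be strictly ordered, got {ev}")
        if ev[-1] != 0.0 or any(t > 0 for t in ev):
            raise ValueError("event times must be <= 0 with cytokinesis onset at 0")
        nyquist = 1.0 / (2.0 * self.frame_interval)
        if self.osc_truth[1] >= nyquist:
            raise ValueError(
                f"oscillation frequency {self.osc_truth[1]} Hz is at or above the "
                f"Nyquist bound {nyquist} Hz for frame_interval {self.frame_interval} s")
        if self.noise_sd < 0 or self.drift_step_sd < 0:
            raise ValueError("noise_sd and drift_step_sd must be >= 0")
        if not 0 < self.relative_ab_pct < 100:
            raise ValueError("relative_ab_pct must be in (0, 100)")


@dataclass(frozen=True)
class SpeciesPreset:
    """Species-level thermal phenotype used to parameterise the generators."""

    name: str
    lower_limit: float  # °C
    upper_limit: float  # °C
    mean_relative_AB: float = 57.4  # % of total daughter area
    size_slope: float = -6.0  # µm²/°C within the thermal range (temperature-size rule)
    shape_elongation_beyond_upper: float = 0.04  # aspect-ratio increment per °C
    size_dev_beyond_lower: float = 15.0  # extra µm²/°C below the lower limit
    activation_energy: float = 0.65  # eV, cell-cycle Arrhenius kinetics
    base_area: float = 1178.0  # µm² at 20 °C (≈ π·25·15 ellipse)
    base_aspect: float = 25.0 / 15.0
    viability_max: float = 0.98
    shoulder_offset: float = 2.0  # °C outside a limit where viability crosses 50%
    shoulder_scale: float = 0.5  # °C, logistic steepness of the shoulders

    def __post_init__(self) -> None:
        if not self.lower_limit < self.upper_limit:
            raise ValueError("lower_limit must be below upper_limit")
        if not 0 < self.mean_relative_AB < 100:
            raise ValueError("mean_relative_AB must be in (0, 100)")


C_ELEGANS = SpeciesPreset(name="c_elegans", lower_limit=12.0, upper_limit=25.0)
C_BRIGGSAE = SpeciesPreset(name="c_briggsae", lower_limit=14.0, upper_limit=27.0)
SPECIES_PRESETS = {p.name: p for p in (C_ELEGANS, C_BRIGGSAE)}


@dataclass(frozen=True)
class FeatureResponseSpec:
    """Generative twin of the thermal-screen models.

    Within the thermal range the feature follows ``kind`` (constant, linear
    y0 + alpha·T, or exponential y0·exp(alpha·T)); beyond each limit an
    additive linear deviation beta·(T − limit) switches on; Gaussian noise of
    sd ``sigma`` is added to every draw.
    """

    kind: str  # constant | linear | exponential
    y0: float
    alpha: float = 0.0  # 1/°C (exponential) or units/°C (linear); 0 for constant
    beta_lower: float = 0.0  # units/°C beyond the lower limit
    beta_upper: float = 0.0  # units/°C beyond the upper limit
    sigma: float = 0.0
    limits: tuple[float, float] = (12.0, 25.0)

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "linear", "exponential"):
            raise ValueError(f"unknown response kind: {self.kind!r}")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.kind == "constant" and self.alpha != 0.0:
            raise ValueError("constant response requires alpha = 0")

    def mean(self, T: np.ndarray) -> np.ndarray:
        T = np.asarray(T, dtype=float)
        if self.kind == "constant":
            base = np.full_like(T, self.y0)
        elif self.kind == "linear":
            base = self.y0 + self.alpha * T
        else:
            base = self.y0 * np.exp(self.alpha * T)
        lo, hi = self.limits
        base = base + self.beta_lower * (T - lo) * (T <= lo)
        base = base + self.beta_upper * (T - hi) * (T >= hi)
        return base


# ---------------------------------------------------------------------------
# recordings


def _ellipse(a: float, b: float, n: int, center=(0.0, 0.0)) -> np.ndarray:
    theta = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    return np.column_stack([center[0] + a * np.cos(theta), center[1] + b * np.sin(theta)])


def _contour_noise(rng: np.random.Generator, shape: tuple, sd: float) -> np.ndarray:
    """Gaussian contour noise smoothed along the outline.

    Segmentation error is spatially correlated along a contour; smoothing a
    white draw with a circular 5-tap kernel (rescaled to preserve the marginal
    sd) keeps the noisy polygon simple, unlike i.i.d. vertex noise.
    """
    raw = rng.normal(0.0, sd, size=shape)
    kernel = np.array([1.0, 4.0, 6.0, 4.0, 1.0])
    kernel /= kernel.sum()
    kernel /= np.sqrt(np.sum(kernel**2))  # unit variance gain
    out = np.zeros_like(raw)
    for k, w in zip(range(-2, 3), kernel):
        out += w * np.roll(raw, k, axis=-2)
    return out


def gen_recording(params: RecordingParams) -> EmbryoRecording:
    """Simulate one tracked embryo recording.

    Noiseless latent signals equal the stated truths: the female pronucleus
    advances along x at ``migration_speed`` until pronuclear meeting; the
    spindle-pole mid-position follows the sigmoid during centration–rotation
    and is held at its mitotic-entry value afterwards (centration is complete
    by then); the posterior pole's transverse position follows
    amplitude·exp(damping·t)·sin(2πf·t) + drift·t during mitosis; poles
    separate linearly at the elongation speeds. A seeded random-walk stage
    drift is added to every coordinate (contours included) and removed again
    by drift correction; i.i.d. Gaussian noise of sd ``noise_sd`` is then
    added to every coordinate.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    dt = params.frame_interval
    pc, pm, me, _ = params.event_times
    n_pre = int(np.ceil(-pc / dt))
    t = (np.arange(n_pre + 1) - n_pre) * dt  # [-n_pre*dt, ..., 0]
    n = len(t)

    A, K, nn, cte = params.sigmoid_truth
    amp, freq, damping, osc_drift = params.osc_truth

    def sigmoid(tt):
        at = np.abs(tt)
        return A * at**nn / (K**nn + at**nn) + cte

    tracks = {name: np.full((n, 2), np.nan) for name in (
        "female_pronucleus", "male_pronucleus",
        "spindle_pole_anterior", "spindle_pole_posterior")}

    pre = t <= pm
    x_meet = float(sigmoid(pm))
    tracks["female_pronucleus"][pre, 0] = x_meet - params.migration_speed * (pm - t[pre])
    tracks["female_pronucleus"][pre, 1] = 0.0
    tracks["male_pronucleus"][pre, 0] = x_meet
    tracks["male_pronucleus"][pre, 1] = 0.0

    post = t >= pm
    mid = sigmoid(np.maximum(np.abs(t[post]), -me) * -1.0)  # frozen at sigmoid(me) for t > me
    mitotic = t[post] >= me
    half = np.full(post.sum(), params.spindle_half_length)
    v_ant, v_post = params.elongation_speeds
    dt_me = np.where(mitotic, t[post] - me, 0.0)
    tracks["spindle_pole_anterior"][post, 0] = mid - half - v_ant * dt_me
    tracks["spindle_pole_posterior"][post, 0] = mid + half + v_post * dt_me
    osc = amp * np.exp(damping * t[post]) * np.sin(2.0 * np.pi * freq * t[post]) \
        + osc_drift * t[post]
    tracks["spindle_pole_anterior"][post, 1] = np.where(mitotic, -0.4 * osc, 0.0)
    tracks["spindle_pole_posterior"][post, 1] = np.where(mitotic, osc, 0.0)

    a, b = params.egg_semi_axes
    shell = np.broadcast_to(_ellipse(a, b, params.contour_vertices), (n, params.contour_vertices, 2)).copy()

    # daughter-cell contours at t ≈ 0.25·t_PM after cytokinesis onset
    total_area = float(np.pi * a * b)
    area_ab = params.relative_ab_pct / 100.0 * total_area
    area_p1 = total_area - area_ab
    b_cell = 0.92 * b
    cells = {
        "AB": _ellipse(area_ab / (np.pi * b_cell), b_cell, params.contour_vertices,
                       center=(-0.4 * a, 0.0)),
        "P1": _ellipse(area_p1 / (np.pi * b_cell), b_cell, params.contour_vertices,
                       center=(0.5 * a, 0.0)),
    }

    drift = np.cumsum(rng.normal(0.0, params.drift_step_sd, size=(n, 2)), axis=0)
    for name in tracks:
        tracks[name] += drift
        tracks[name] += rng.normal(0.0, params.noise_sd, size=(n, 2))
    shell += drift[:, None, :]
    shell += _contour_noise(rng, shell.shape, params.noise_sd)
    cell_ref = drift[-1]
    cells = {k: v + cell_ref + _contour_noise(rng, v.shape, params.noise_sd)
             for k, v in cells.items()}

    rec = EmbryoRecording(
        timestamps=t,
        tracks=tracks,
        eggshell_contour=shell,
        events={"pseudo_cleavage": pc, "pronuclear_meeting": pm,
                "mitotic_entry": me, "cytokinesis_onset": 0.0},
        temperature=params.temperature,
        group=params.group,
        cell_contours=cells,
        cell_contours_time=0.25 * (-pm),
    )
    rec.validate()
    return rec


def preset_recording_params(preset: SpeciesPreset, temperature: float,
                            seed: int, noise_sd: float = 0.3) -> RecordingParams:
    """Recording truth at a given temperature under a species preset.

    Cell-cycle pace follows Arrhenius kinetics with the preset activation
    energy (referenced to 20 °C); sigmoid half-time, oscillation frequency and
    migration speed scale with the pace; embryo area follows the
    temperature-size trend with its beyond-lower-limit deviation, and aspect
    ratio elongates beyond the upper limit.
    """
    TK = temperature + _CELSIUS_OFFSET
    scale = float(np.exp(preset.activation_energy / KB_EV * (1.0 / TK - 1.0 / (20.0 + _CELSIUS_OFFSET))))
    t_pm = 1080.0 * scale
    events = (-1.18 * t_pm, -t_pm, -0.35 * t_pm, 0.0)

    area = preset.base_area + preset.size_slope * (temperature - 20.0)
    if temperature < preset.lower_limit:
        area += preset.size_dev_beyond_lower * (temperature - preset.lower_limit)
    aspect = preset.base_aspect
    if temperature > preset.upper_limit:
        aspect += preset.shape_elongation_beyond_upper * (temperature - preset.upper_limit)
    a = float(np.sqrt(area * aspect / np.pi))
    b = a / aspect

    return RecordingParams(
        temperature=temperature,
        egg_semi_axes=(a, b),
        migration_speed=0.1 / scale,
        sigmoid_truth=(0.55 * a, 0.27 * t_pm, 4.0, -0.25 * a),
        osc_truth=(2.0, 0.04 / scale, 0.002 / scale, 0.0),
        event_times=events,
        noise_sd=noise_sd,
        seed=seed,
        relative_ab_pct=preset.mean_relative_AB,
        group=preset.name,
    )


# ---------------------------------------------------------------------------
# tables


def gen_feature_table(specs: dict[str, FeatureResponseSpec], temps,
                      n_per_temp: int, seed: int) -> pd.DataFrame:
    """Tidy per-embryo feature table (feature, temperature, replicate, value)."""
    if n_per_temp < 1:
        raise ValueError("n_per_temp must be >= 1")
    temps = np.asarray(temps, dtype=float)
    rng = np.random.default_rng(seed)
    rows = []
    for feature, spec in specs.items():
        for T in temps:
            mu = float(spec.mean(np.array([T]))[0])
            draws = mu + rng.normal(0.0, spec.sigma, size=n_per_temp)
            for rep, v in enumerate(draws):
                rows.append((feature, float(T), rep, float(v)))
    return pd.DataFrame(rows, columns=["feature", "temperature", "replicate", "value"])


def viability_fraction(preset: SpeciesPreset, temps) -> np.ndarray:
    """Exact (noise-free) hatching fraction: a plateau inside the thermal
    range with logistic shoulders crossing 50% ``shoulder_offset`` °C outside
    each limit."""
    T = np.asarray(temps, dtype=float)

    def logistic(z):
        return 1.0 / (1.0 + np.exp(-z))

    lo = preset.lower_limit - preset.shoulder_offset
    hi = preset.upper_limit + preset.shoulder_offset
    s = preset.shoulder_scale
    return preset.viability_max * logistic((T - lo) / s) * logistic((hi - T) / s)


def gen_viability(preset: SpeciesPreset, temps, n_embryos: int = 100,
                  noise: bool = True, seed: int = 0) -> pd.DataFrame:
    """Progeny-test table: temperature, embryos scored, hatched, fraction.

    ``noise=False`` returns the exact fractions regardless of seed;
    ``noise=True`` draws hatched counts binomially.
    """
    temps = np.asarray(temps, dtype=float)
    if temps.size == 0:
        raise ValueError("temps must be non-empty")
    if n_embryos < 1:
        raise ValueError("n_embryos must be >= 1")
    frac = viability_fraction(preset, temps)
    if noise:
        rng = np.random.default_rng(seed)
        hatched = rng.binomial(n_embryos, frac)
    else:
        hatched = frac * n_embryos
    return pd.DataFrame({
        "temperature": temps,
        "n_embryos": n_embryos,
        "hatched": hatched,
        "fraction": hatched / n_embryos,
    })


def gen_respiration(E: float, prefactor: float, temps, range_: tuple[float, float],
                    dev_lower: float = 0.0, dev_upper: float = 0.0,
                    sigma: float = 0.0, seed: int = 0) -> pd.DataFrame:
    """Respiration (O2 flow) vs temperature with Arrhenius structure.

    Within ``range_``: log flow = log(prefactor) − E/(kB·T[K]). Beyond each
    edge the within-range prediction continues but an additive per-°C
    log-deviation (dev_lower/dev_upper × distance beyond the edge) switches
    on. Gaussian noise of sd ``sigma`` is added to log flow.
    """
    temps = np.asarray(temps, dtype=float)
    if temps.size == 0:
        raise ValueError("temps must be non-empty")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    lo, hi = range_
    TK = temps + _CELSIUS_OFFSET
    log_flow = np.log(prefactor) - E / (KB_EV * TK)
    log_flow = log_flow + dev_lower * (temps - lo) * (temps <= lo)
    log_flow = log_flow + dev_upper * (temps - hi) * (temps >= hi)
    if sigma > 0:
        rng = np.random.default_rng(seed)
        log_flow = log_flow + rng.normal(0.0, sigma, size=temps.shape)
    return pd.DataFrame({
        "temperature": temps,
        "log_flow": log_flow,
        "flow": np.exp(log_flow),
    })
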