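"""End-to-end orchestration: simulate or analyze, screen, and report.

``simulate`` mode generates everything from a seed — tracked recordings at a
grid of temperatures, a viability table, a respiration table — then extracts
features, runs the thermal screen, detects the thermal limits, tests
respiration departures, and writes tables plus a manifest with input digests.
``analyze`` mode runs the same downstream stages on user-supplied CSVs.

Outputs are byte-deterministic given (seed, config), except the ``created``
timestamp in the manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
import warnings
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import io as teio
from .features import extract_all
from .synthdata import (SPECIES_PRESETS, gen_recording, gen_respiration,
                        gen_viability, preset_recording_params)
from .thermal import (arrhenius_fit, classify_table, detect_limits,
                      reports_to_frame, respiration_departure)

__all__ = ["RunConfig", "Thresholds", "run"]

log = logging.getLogger("thermoembryo")
if not log.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("[%(name)s] %(message)s"))
    log.addHandler(_h)
    log.setLevel(logging.INFO)


class Thresholds(BaseModel):
    criterion: float = Field(0.90, gt=0, lt=1)  # hatching-fraction limit criterion
    family_alpha: float = Field(0.05, gt=0, lt=1)
    ftest_threshold: float = Field(0.0014, gt=0, lt=1)
    m_features: int = Field(35, ge=1)  # Bonferroni family size


class RunConfig(BaseModel):
    mode: Literal["simulate", "analyze"]
    seed: Optional[int] = None
    species: Literal["c_elegans", "c_briggsae"] = "c_elegans"
    temps_recordings: list[float] = [9.0, 12.0, 16.0, 20.0, 24.0, 25.0, 27.0]
    n_per_temp: int = Field(3, ge=1)
    temps_viability: Optional[list[float]] = None
    temps_respiration: Optional[list[float]] = None
    n_embryos: int = Field(200, ge=1)
    thermal_range: Optional[tuple[float, float]] = None  # default: detected limits
    thresholds: Thresholds = Thresholds()
    outdir: Path = Path("results/run")
    write_recordings: bool = False
    # analyze mode inputs
    features_csv: Optional[Path] = None
    viability_csv: Optional[Path] = None
    respiration_csv: Optional[Path] = None

    @model_validator(mode="after")
    def _check(self):
        if self.mode == "simulate" and self.seed is None:
            raise ValueError("simulate mode requires a seed")
        if self.mode == "analyze" and self.features_csv is None:
            raise ValueError("analyze mode requires features_csv")
        return self


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _simulate_inputs(config: RunConfig):
    preset = SPECIES_PRESETS[config.species]
    ss = np.random.SeedSequence(config.seed)
    rec_seeds, via_seed, resp_seed = ss.spawn(3)
    rec_children = rec_seeds.spawn(len(config.temps_recordings) * config.n_per_temp)

    rows = []
    recordings = []
    k = 0
    for T in config.temps_recordings:
        for _ in range(config.n_per_temp):
            child = int(rec_children[k].generate_state(1)[0] % (2**31))
            k += 1
            params = preset_recording_params(preset, T, seed=child)
            rec = gen_recording(params)
            recordings.append(rec)
            row = extract_all(rec)
            for name, value in row.values.items():
                rows.append((name, T, row.group, value))
    features = pd.DataFrame(rows, columns=["feature", "temperature", "group", "value"])

    temps_v = config.temps_viability or [7.5] + list(np.arange(8.0, 30.5, 1.0))
    viability = gen_viability(preset, temps_v, n_embryos=config.n_embryos, noise=True,
                              seed=int(via_seed.generate_state(1)[0] % (2**31)))
    temps_r = config.temps_respiration or list(np.arange(9.0, 29.0, 1.0))
    respiration = gen_respiration(
        E=preset.activation_energy, prefactor=np.exp(preset.activation_energy
                                                     / (8.617333e-5 * 293.15)),
        temps=temps_r, range_=(preset.lower_limit, preset.upper_limit),
        dev_lower=0.15, dev_upper=-0.2, sigma=0.02,
        seed=int(resp_seed.generate_state(1)[0] % (2**31)))
    return features, viability, respiration, recordings


def run(config: RunConfig) -> dict:
    """Execute one pipeline run and write its report files.

    Returns the report dictionary (also written as JSON to the output
    directory).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    th = config.thresholds
    t0 = time.perf_counter()
    outputs: dict[str, Path] = {}

    if config.mode == "simulate":
        log.info("simulate: generating recordings and tables (seed=%s)", config.seed)
        features, viability, respiration, recordings = _simulate_inputs(config)
        outputs["features"] = teio.write_table(features, outdir / "features.csv")
        outputs["viability"] = teio.write_table(viability, outdir / "viability.csv")
        outputs["respiration"] = teio.write_table(respiration, outdir / "respiration.csv")
        if config.write_recordings:
            for i, rec in enumerate(recordings):
                teio.write_recording(rec, outdir / "recordings" / f"rec_{i:03d}")
    else:
        log.info("analyze: reading input tables")
        features = teio.read_feature_table(config.features_csv)
        viability = teio.read_table(config.viability_csv) if config.viability_csv else None
        respiration = (teio.read_table(config.respiration_csv)
                       if config.respiration_csv else None)
    log.info("inputs ready (%.1f s)", time.perf_counter() - t0)

    report: dict = {"mode": config.mode, "species": config.species}

    limits = None
    if viability is not None:
        limits = detect_limits(viability, criterion=th.criterion)
        report["thermal_limits"] = {"lower": limits.lower, "upper": limits.upper,
                                    "criterion": th.criterion}
    range_ = config.thermal_range or (
        (limits.lower, limits.upper) if limits is not None
        else (SPECIES_PRESETS[config.species].lower_limit,
              SPECIES_PRESETS[config.species].upper_limit))
    report["thermal_range"] = list(range_)

    if len(features) == 0:
        warnings.warn("empty feature table: report will have zero rows", stacklevel=2)
    log.info("screening %d features over range %s", features["feature"].nunique(), range_)
    reports = classify_table(features, range_, M=th.m_features,
                             family_alpha=th.family_alpha, threshold=th.ftest_threshold)
    screen_df = reports_to_frame(reports)
    outputs["screen"] = teio.write_table(screen_df, outdir / "screen.csv")
    report["n_features"] = len(reports)
    report["n_temperature_dependent"] = int(
        sum(r.screen.temperature_dependent for r in reports if not r.untestable))

    cc = features[features["feature"] == "t_pm_s"]
    if len(cc) >= 2:
        fit = arrhenius_fit(cc["temperature"], cc["value"], range_=range_)
        report["cell_cycle_arrhenius"] = {
            "E_eV": fit.E, "r2_percent": fit.r2_percent, "n": fit.n_obs}

    if respiration is not None:
        dep = respiration_departure(respiration, range_, threshold=th.ftest_threshold)
        report["respiration_departure"] = {
            side: {"F": fit.F, "p_value": fit.p_value, "beta": fit.beta,
                   "changed": fit.changed}
            for side, fit in dep.items()}

    report_path = outdir / "report.json"
    report_path.write_text(json.dumps(report, indent=1, default=float), encoding="utf-8")
    outputs["report"] = report_path

    manifest = {
        "seed": config.seed,
        "config": json.loads(config.model_dump_json(exclude={"outdir"})),
        "outputs": {name: _sha256(path) for name, path in sorted(outputs.items())},
        "created": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1),
                                          encoding="utf-8")
    log.info("run complete in %.1f s -> %s", time.perf_counter() - t0, outdir)
    return report
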