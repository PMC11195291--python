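"""Experiment configuration schema, orchestration and test fixtures.

The configuration is a tree of the package's own dataclasses; it round-trips
losslessly through YAML or JSON, rejects unknown or missing fields with an
error naming the offending key, and hashes canonically so a manifest can
prove two runs used the same settings.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from logprf import io as lio
from logprf.fitting import (
    GridSearchSpec,
    RetentionRule,
    apply_filters,
    fit_dataset,
    results_to_frame,
)
from logprf.forward_model import PRFParams
from logprf.hemodynamics import HRFParams
from logprf.simulation import (
    NoiseSpec,
    SimGridSpec,
    SizeEccRelation,
    build_stimulus_pair,
    make_prf_grid,
    plot_recovery,
    recovery_analysis,
    simulate_dataset,
)
from logprf.stimulus import (
    FieldGrid,
    RunSpec,
    SweepSpec,
    WarpSpec,
    assemble_run,
    warp_movie,
)

__all__ = [
    "StimulusSettings",
    "ExperimentConfig",
    "ConfigError",
    "load_config",
    "save_config",
    "config_hash",
    "run_experiment",
    "make_fixtures",
]


class ConfigError(ValueError):
    """Invalid configuration; the message names the offending field."""


@dataclass(frozen=True)
class StimulusSettings:
    """Geometry and render/preprocess settings of the stimulus pair."""

    render_px: int = 540
    render_fps: float = 10.0
    rmax: float = 8.0
    k: float = 5.0
    bar_width: float = 2.0
    speed: float = 0.4
    target_px: int = 108
    target_frames: int = 366


@dataclass(frozen=True)
class ExperimentConfig:
    """All settings of one simulated pRF-mapping experiment."""

    stimulus: StimulusSettings = StimulusSettings()
    hrf: HRFParams = HRFParams.canonical()
    grid: GridSearchSpec = GridSearchSpec()
    retention: RetentionRule = RetentionRule()
    sim_grid: SimGridSpec = SimGridSpec()
    noise: NoiseSpec = NoiseSpec()
    rng_seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        return _build(cls, d, path="")


_NESTED = {
    "stimulus": StimulusSettings,
    "hrf": HRFParams,
    "grid": GridSearchSpec,
    "retention": RetentionRule,
    "sim_grid": SimGridSpec,
    "noise": NoiseSpec,
    "relation": SizeEccRelation,
}


def _build(cls, d: dict, path: str):
    if not isinstance(d, dict):
        raise ConfigError(f"expected a mapping at '{path or cls.__name__}'")
    names = {f.name for f in dataclasses.fields(cls)}
    for key in d:
        if key not in names:
            raise ConfigError(f"unknown config field '{path}{key}'")
    kwargs = {}
    for key, value in d.items():
        if key in _NESTED and isinstance(value, dict):
            kwargs[key] = _build(_NESTED[key], value, path=f"{path}{key}.")
        else:
            kwargs[key] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid config at '{path or 'root'}': {exc}") from exc


def save_config(config: ExperimentConfig, path: str | Path) -> Path:
    path = Path(path)
    d = config.to_dict()
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(d, sort_keys=True))
    else:
        path.write_text(json.dumps(d, indent=2, sort_keys=True))
    return path


def load_config(path: str | Path) -> ExperimentConfig:
    path = Path(path)
    text = path.read_text()
    d = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
    return ExperimentConfig.from_dict(d)


def config_hash(config: ExperimentConfig) -> str:
    canonical = json.dumps(config.to_dict(), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def run_experiment(config: ExperimentConfig, outdir: str | Path,
                   progress: bool = False) -> Path:
    """Run the full simulated experiment and write all artifacts.

    Produces the stimulus movie pair, simulated datasets, per-unit fit
    tables, a binned recovery report, a recovery figure, and a manifest
    recording the config hash, seeds, timings and artifact checksums.
    Deterministic: the same config yields byte-identical TSV outputs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "config_hash": config_hash(config),
        "rng_seed": config.rng_seed,
        "stages": {},
        "outputs": {},
    }

    def _stage(name):
        t0 = time.perf_counter()
        return lambda: manifest["stages"].__setitem__(
            name, round(time.perf_counter() - t0, 3))

    st = config.stimulus
    done = _stage("stimulus")
    fixed, log = build_stimulus_pair(
        render_px=st.render_px, render_fps=st.render_fps, rmax=st.rmax,
        k=st.k, rng_seed=config.rng_seed, target_px=st.target_px,
        target_frames=st.target_frames,
    )
    lio.save_movie(fixed, outdir / "stimulus_fixed.nii.gz")
    lio.save_movie(log, outdir / "stimulus_log.nii.gz")
    done()

    grid = make_prf_grid(config.sim_grid)
    fits_by_stim = {}
    truth = None
    for label, stim in (("fixed", fixed), ("log", log)):
        done = _stage(f"simulate_{label}")
        noise = dataclasses.replace(
            config.noise,
            rng_seed=config.noise.rng_seed + (0 if label == "fixed" else 1),
        )
        data, truth = simulate_dataset(grid, stim, config.hrf, noise)
        lio.save_timecourses(data, stim.frame_duration_s,
                             outdir / f"timecourses_{label}.nii.gz")
        done()
        done = _stage(f"fit_{label}")
        results = fit_dataset(data, stim, config.hrf, config.grid,
                              progress=progress)
        results = apply_filters(results, config.retention)
        frame = results_to_frame(results)
        lio.save_fits(frame, outdir / f"fits_{label}.tsv")
        fits_by_stim[label] = frame
        done()

    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False,
                 float_format="%.10g")
    report = recovery_analysis(fits_by_stim, truth)
    lio.save_fits(report, outdir / "recovery_report.tsv")
    plot_recovery(fits_by_stim, truth, str(outdir / "recovery.png"))

    for p in sorted(outdir.iterdir()):
        if p.suffix == ".tsv":
            manifest["outputs"][p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                     sort_keys=True))
    return outdir


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

def make_fixtures(seed: int = 0, n_units: int = 20) -> dict:
    """Small deterministic dataset for fast tests.

    A 64x64, 60-frame fixed/log stimulus pair (four 13 s sweeps between short
    blanks, bar speed scaled for a full traverse) and ``n_units`` synthetic
    units with known ground truth (centers within 6° eccentricity, sizes in
    [0.3, 2]°), as noiseless unit-peak predictions.
    """
    rmax = 8.0
    grid = FieldGrid.square(64, fov_deg=2 * rmax)
    rng = np.random.default_rng(seed)
    directions = rng.permutation([0.0, 90.0, 180.0, 270.0])
    sweeps = tuple(
        SweepSpec(direction=float(d), bar_width=2.0, speed=18.0 / 13.0,
                  duration=13.0)
        for d in directions
    )
    run = RunSpec(sweeps=sweeps, pre_blank_s=4.0, post_blank_s=4.0,
                  frame_rate_hz=1.0, rng_seed=seed)
    fixed = assemble_run(run, grid, rmax)
    log = warp_movie(fixed, WarpSpec(k=5.0, rmax=rmax))

    ecc = rng.uniform(0.0, 5.5, n_units)
    ang = rng.uniform(0.0, 2 * np.pi, n_units)
    sigma = rng.uniform(0.3, 2.0, n_units)
    prfs = [
        PRFParams(float(e * np.cos(a)), float(e * np.sin(a)), float(s))
        for e, a, s in zip(ecc, ang, sigma)
    ]
    hrf = HRFParams.canonical()
    data, truth = simulate_dataset(
        prfs, fixed, hrf, NoiseSpec(sd=0.0, n_reps=1, rng_seed=seed)
    )
    data_log, _ = simulate_dataset(
        prfs, log, hrf, NoiseSpec(sd=0.0, n_reps=1, rng_seed=seed)
    )
    return {
        "stim_fixed": fixed,
        "stim_log": log,
        "prfs": prfs,
        "truth": truth,
        "data_fixed": data,
        "data_log": data_log,
        "hrf": hrf,
        "seed": seed,
    }
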