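"""Run configuration: one place for every default the pipeline uses.

Every numeric default that the analysis depends on lives here (or in the
parameter dataclasses this module aggregates): factorial design size,
RT-model effects, envelope landmarks, spectral estimator settings
(Hanning 500 ms / 20 ms), regression window −500..1650 ms with Bonferroni
correction, and the source stage (6 mm grid, λ, 500 bootstrap resamples,
FDR α = 0.05, ROI rules ≥4 connected significant neighbors and
mean |t| ≥ 2.6).  Configs round-trip losslessly through YAML/JSON.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, is_dataclass
from pathlib import Path

import yaml

from .coupling import CouplingParams
from .design import RTGenParams
from .simulate import EnvelopeParams


@dataclass
class DesignParams:
    n_blocks: int = 8
    reps_per_condition: int = 10


@dataclass
class SimParams:
    n_sensors: int = 80
    fs_hz: float = 250.0
    tmin_ms: float = -1000.0
    tmax_ms: float = 3000.0
    noise_sd: float = 1.0
    save_epochs: str = "first"   # none | first | all


@dataclass
class SpectralParams:
    window_ms: float = 500.0
    step_ms: float = 20.0
    freq_min_hz: float = 2.0
    freq_max_hz: float = 40.0
    freq_step_hz: float = 2.0
    alpha_band: tuple[float, float] = (8.0, 12.0)
    beta_band: tuple[float, float] = (16.0, 25.0)
    baseline_ms: tuple[float, float] = (-500.0, 0.0)
    planar_neighbors: int = 6


@dataclass
class StatsParams:
    window_ms: tuple[float, float] = (-500.0, 1650.0)
    alpha: float = 0.05
    bonferroni_divisor: int | None = None   # None: number of grid time points


@dataclass
class SourceParams:
    grid_spacing_mm: float = 6.0
    mask_radius_mm: float = 80.0
    lam: float = 0.05
    n_boot: int = 500
    fdr_alpha: float = 0.05
    min_neighbors: int = 4
    t_mean_min: float = 2.6
    active_ms: tuple[float, float] = (600.0, 1100.0)
    baseline_ms: tuple[float, float] = (-500.0, 0.0)
    run_source_stage: bool = True


@dataclass
class RunConfig:
    seed: int = 0
    n_subjects: int = 12
    out_dir: str = "runs/default"
    design: DesignParams = field(default_factory=DesignParams)
    rt: RTGenParams = field(default_factory=RTGenParams)
    envelopes: EnvelopeParams = field(default_factory=EnvelopeParams)
    sim: SimParams = field(default_factory=SimParams)
    spectral: SpectralParams = field(default_factory=SpectralParams)
    stats: StatsParams = field(default_factory=StatsParams)
    source: SourceParams = field(default_factory=SourceParams)
    coupling: CouplingParams = field(default_factory=CouplingParams)


def _to_plain(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, (tuple, list)):
        return [_to_plain(v) for v in obj]
    return obj


def _from_plain(cls, data):
    # rebuild nested dataclasses and tuples from the defaults' shapes
    obj = cls()
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        default = getattr(obj, f.name)
        v = data[f.name]
        if is_dataclass(default) and not isinstance(default, type):
            v = _from_plain(type(default), v)
        elif isinstance(default, tuple) and isinstance(v, list):
            v = tuple(v)
        setattr(obj, f.name, v)
    return obj


def config_to_dict(config: RunConfig) -> dict:
    return _to_plain(config)


def config_from_dict(data: dict) -> RunConfig:
    return _from_plain(RunConfig, data)


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(config),
                                         sort_keys=False))


def load_config(path: str | Path) -> RunConfig:
    return config_from_dict(yaml.safe_load(Path(path).read_text()))


def validate_config(config: RunConfig) -> list[str]:
    """Return a list of violation messages (empty list: valid)."""
    v: list[str] = []
    c = config
    if c.n_subjects < 1:
        v.append("n_subjects must be >= 1")
    if c.design.n_blocks < 1 or c.design.reps_per_condition < 1:
        v.append("design counts must be >= 1")
    nyq = c.sim.fs_hz / 2.0
    for name, band in (("alpha", c.spectral.alpha_band),
                       ("beta", c.spectral.beta_band)):
        if band[1] > nyq:
            v.append(f"{name} band {band} exceeds Nyquist ({nyq:g} Hz)")
        if band[0] >= band[1]:
            v.append(f"{name} band {band} is not increasing")
    if c.spectral.freq_max_hz > nyq:
        v.append(f"frequency grid top {c.spectral.freq_max_hz:g} Hz exceeds "
                 f"Nyquist ({nyq:g} Hz)")
    epoch = (c.sim.tmin_ms, c.sim.tmax_ms)
    if c.spectral.window_ms > epoch[1] - epoch[0]:
        v.append("spectral window does not fit inside the epoch")
    if not (epoch[0] <= c.spectral.baseline_ms[0] < c.spectral.baseline_ms[1] <= epoch[1]):
        v.append("baseline window must lie inside the epoch")
    if not (epoch[0] <= c.stats.window_ms[0] < c.stats.window_ms[1] <= epoch[1]):
        v.append("stats window must lie inside the epoch")
    if not 0 < c.stats.alpha < 1:
        v.append("stats alpha must be in (0, 1)")
    if not 0 < c.source.fdr_alpha < 1:
        v.append("FDR alpha must be in (0, 1)")
    if c.source.lam < 0:
        v.append("regularization λ must be >= 0")
    if c.source.n_boot < 1:
        v.append("bootstrap resample count must be >= 1")
    if c.source.grid_spacing_mm <= 0 or c.source.mask_radius_mm <= 0:
        v.append("grid spacing and mask radius must be positive")
    if c.rt.support[0] >= c.rt.support[1]:
        v.append("RT support must be an increasing interval")
    if c.sim.n_sensors < 8 or c.sim.n_sensors % 2:
        v.append("n_sensors must be an even number >= 8")
    if c.sim.save_epochs not in ("none", "first", "all"):
        v.append("save_epochs must be one of none|first|all")
    return v
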