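"""Pipeline configuration.

Every numeric constant used anywhere in the pipeline lives here with its
default value, so a single YAML file (plus CLI overrides) fully determines a
run.  Unknown keys in a config file are rejected rather than ignored.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

__all__ = [
    "FilterConfig",
    "SegmentConfig",
    "EpochConfig",
    "ModelConfig",
    "MCMCSettings",
    "ReliabilityConfig",
    "PipelineConfig",
    "config_hash",
]


@dataclass
class FilterConfig:
    """Continuous-EEG filter stages (Butterworth throughout)."""

    highpass_hz: float = 0.2
    highpass_order: int = 2
    bandstop_hz: tuple[float, float] = (58.0, 62.0)  # 60 Hz line-noise stop band
    bandstop_order: int = 2
    lowpass_hz: float = 30.0
    lowpass_order: int = 6
    # offline filtering is zero-phase (forward-backward) by default, so that
    # component peak latencies are not biased by filter group delay; the
    # stated order is the overall magnitude-response order (half per pass)
    highpass_two_pass: bool = True
    bandstop_two_pass: bool = True
    lowpass_two_pass: bool = True


@dataclass
class SegmentConfig:
    """Bad-segment detection via cross-channel spectral correlation."""

    seg_len_s: float = 0.5
    z_thresh: float = 1.8
    spectrum_band_hz: tuple[float, float] = (1.0, 100.0)
    spectrum_kind: str = "amplitude"  # amplitude | power | log
    bad_channel_k: float = 5.0  # robust-SD multiple for noisy-channel candidates


@dataclass
class EpochConfig:
    """Response-locked epoching and component-window settings."""

    epoch_pre_ms: float = 500.0
    epoch_post_ms: float = 500.0
    baseline_ms: tuple[float, float] = (-500.0, -400.0)
    window_half_ms: float = 50.0
    peak_search_ms: tuple[float, float] = (0.0, 200.0)
    evoked_span_s: tuple[float, float] = (0.0, 1.5)  # stimulus-locked average span
    min_error_trials: int = 6
    fa_rate_exclude: float = 0.83
    fa_blocks_exclude: int = 10
    channel: str = "FCz"
    per_subject_windows: bool = False


@dataclass
class MCMCSettings:
    chains: int = 4
    warmup: int = 1000
    samples: int = 500
    seed: int = 0

    @classmethod
    def paper_settings(cls, seed: int = 0) -> "MCMCSettings":
        return cls(chains=8, warmup=8000, samples=1000, seed=seed)


@dataclass
class ModelConfig:
    """Regularized-horseshoe hierarchical regression hyperparameters."""

    p0: int = 9  # expected number of non-zero coefficients
    nu0: float = 20.0  # slab degrees of freedom
    s: float = 1.0  # slab scale
    nu_prior_shape: float = 2.0
    nu_prior_rate: float = 0.1  # Gamma rate parameterization (mean 20)
    restandardize_interactions: bool = False
    mcmc: MCMCSettings = field(default_factory=MCMCSettings)


@dataclass
class ReliabilityConfig:
    phi_threshold: float = 0.8
    s_grid: tuple[int, ...] = (5, 10, 15, 20, 25, 30, 40, 50)
    draw_wise: bool = True  # phi over posterior draws (vs plug-in at medians)


@dataclass
class PipelineConfig:
    """Top-level configuration: paths, stage constants, and the run seed."""

    raw_dir: str | None = None
    events_path: str | None = None
    traits_path: str | None = None
    out_dir: str = "crnpipe_run"
    seed: int = 0
    filters: FilterConfig = field(default_factory=FilterConfig)
    segments: SegmentConfig = field(default_factory=SegmentConfig)
    epochs: EpochConfig = field(default_factory=EpochConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    reliability: ReliabilityConfig = field(default_factory=ReliabilityConfig)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        return _asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        return _from_dict(cls, d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)


def _asdict(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _asdict(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, tuple):
        return list(obj)
    return obj


def _from_dict(cls: type, d: dict[str, Any]) -> Any:
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(d) - set(fields)
    if unknown:
        raise ValueError(f"unknown config keys for {cls.__name__}: {sorted(unknown)}")
    kwargs: dict[str, Any] = {}
    for name, value in d.items():
        ftype = fields[name].type
        default = fields[name].default_factory() if fields[name].default_factory is not dataclasses.MISSING else None  # type: ignore[misc]
        if dataclasses.is_dataclass(default):
            kwargs[name] = _from_dict(type(default), value)
        elif isinstance(value, list):
            kwargs[name] = tuple(value)
        else:
            kwargs[name] = value
        del ftype
    return cls(**kwargs)


def config_hash(config: PipelineConfig) -> str:
    """Stable short hash identifying a configuration (for output sidecars)."""
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
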