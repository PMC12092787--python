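"""Pipeline configuration: YAML schema, defaults, strict validation.

Defaults mirror the analysis the package reproduces: 8-mm FWHM smoothing,
3-mm resampling, MDL-selected model order, 20 ICASSO runs, FDR q = 0.05,
|Z| > 3 display threshold, age and TIV as group-test covariates, age as
the correlation covariate.  Unknown keys are rejected with a close-match
suggestion, and the fully resolved config is written to the run manifest.
"""

from __future__ import annotations

import difflib
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Any

import yaml

from .exceptions import ConfigError
from .synthetic_data import ClinicalLink, SyntheticConfig


@dataclass
class PathsConfig:
    volumes: str | None = None  # glob pattern for per-subject NIfTI files
    participants: str | None = None  # participants.tsv


@dataclass
class SimulateConfig:
    enabled: bool = False
    grid_shape: tuple[int, int, int] = (24, 28, 24)
    voxel_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    k_true: int = 4
    blobs_per_source: int = 3
    blob_sigma_mm: float = 8.0
    baseline: float = 0.25
    loading_mean: float = 1.0
    loading_sd: float = 0.25
    group_effect: tuple[float, ...] = (0.0, 0.0, 0.0, 1.5)
    noise_sd: float = 0.05
    n_patients: int = 20
    n_controls: int = 20
    clinical_link_source: int | None = 3
    clinical_link_column: str | None = "magnification"
    clinical_link_r: float | None = -0.6

    def to_synthetic(self, seed: int) -> SyntheticConfig:
        link = None
        if self.clinical_link_source is not None:
            link = ClinicalLink(
                source=self.clinical_link_source,
                column=self.clinical_link_column,
                r=self.clinical_link_r,
            )
        return SyntheticConfig(
            grid_shape=tuple(self.grid_shape),
            voxel_mm=tuple(self.voxel_mm),
            k_true=self.k_true,
            blobs_per_source=self.blobs_per_source,
            blob_sigma_mm=self.blob_sigma_mm,
            baseline=self.baseline,
            loading_mean=self.loading_mean,
            loading_sd=self.loading_sd,
            group_effect=tuple(self.group_effect),
            noise_sd=self.noise_sd,
            n_patients=self.n_patients,
            n_controls=self.n_controls,
            clinical_link=link,
            seed=seed,
        )


@dataclass
class PreprocessingConfig:
    resample_mm: float | None = 3.0  # None disables resampling
    fwhm_mm: float = 8.0
    mask_threshold: float = 0.1
    mask_require_variance: bool = True


@dataclass
class DecompositionConfig:
    k: int | str = "auto"  # integer or "auto" (MDL)
    n_runs: int = 20
    seed: int = 0
    mdl_decimation: int = 4
    max_k: int | None = None
    lrate: float | None = None
    block_size: int | None = None
    anneal: float = 0.9
    max_steps: int = 512
    tol: float = 1.0e-6

    def infomax_params(self) -> dict:
        return {
            "lrate": self.lrate,
            "block_size": self.block_size,
            "anneal": self.anneal,
            "max_steps": self.max_steps,
            "tol": self.tol,
        }


@dataclass
class StatsConfig:
    covariates: tuple[str, ...] = ("age", "tiv")
    fdr_q: float = 0.05
    z_threshold: float = 3.0
    connectivity: int = 26
    df_mode: str = "adjusted"


@dataclass
class CorrelationConfig:
    metrics: tuple[str, ...] = (
        "fm_years", "rumination", "magnification", "STAI", "CESD",
        "pain_intensity", "PCS", "PSP", "helplessness",
    )
    covariates: tuple[str, ...] = ("age",)
    group: str | None = None  # None = both groups pooled
    fdr_q: float | None = None  # optional BH across the grid


@dataclass
class PipelineConfig:
    paths: PathsConfig = field(default_factory=PathsConfig)
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    preprocessing: PreprocessingConfig = field(default_factory=PreprocessingConfig)
    decomposition: DecompositionConfig = field(default_factory=DecompositionConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    correlation: CorrelationConfig = field(default_factory=CorrelationConfig)

    def to_dict(self) -> dict:
        return asdict(self)


_SECTIONS = {
    "paths": PathsConfig,
    "simulate": SimulateConfig,
    "preprocessing": PreprocessingConfig,
    "decomposition": DecompositionConfig,
    "stats": StatsConfig,
    "correlation": CorrelationConfig,
}


def _known_keys(cls) -> list[str]:
    return [f.name for f in fields(cls)]


def _reject_unknown(key: str, known: list[str], where: str) -> None:
    suggestion = difflib.get_close_matches(key, known, n=1, cutoff=0.5)
    hint = f"; did you mean {suggestion[0]!r}?" if suggestion else ""
    raise ConfigError(f"unknown config key {key!r} in {where}{hint}")


def _listify(value: Any) -> Any:
    return tuple(value) if isinstance(value, list) else value


def config_from_dict(raw: dict | None) -> PipelineConfig:
    """Build a validated PipelineConfig from a (possibly partial) dict."""
    raw = raw or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    cfg = PipelineConfig()
    for section, value in raw.items():
        if section not in _SECTIONS:
            _reject_unknown(section, list(_SECTIONS), "config root")
        cls = _SECTIONS[section]
        known = _known_keys(cls)
        if not isinstance(value, dict):
            raise ConfigError(f"config section {section!r} must be a mapping")
        target = getattr(cfg, section)
        for key, v in value.items():
            if key not in known:
                _reject_unknown(key, known, f"section {section!r}")
            setattr(target, key, _listify(v))
    _validate(cfg)
    return cfg


def _validate(cfg: PipelineConfig) -> None:
    d = cfg.decomposition
    if isinstance(d.k, str) and d.k != "auto":
        raise ConfigError(f"decomposition.k must be an integer or 'auto', got {d.k!r}")
    if d.n_runs < 1:
        raise ConfigError("decomposition.n_runs must be >= 1")
    if cfg.preprocessing.fwhm_mm < 0:
        raise ConfigError("preprocessing.fwhm_mm must be >= 0")
    if cfg.preprocessing.resample_mm is not None and cfg.preprocessing.resample_mm <= 0:
        raise ConfigError("preprocessing.resample_mm must be positive")
    if not 0 < cfg.stats.fdr_q < 1:
        raise ConfigError("stats.fdr_q must be in (0, 1)")
    if cfg.stats.z_threshold <= 0:
        raise ConfigError("stats.z_threshold must be > 0")
    if cfg.stats.connectivity not in (6, 26):
        raise ConfigError("stats.connectivity must be 6 or 26")
    if cfg.correlation.group not in (None, "patient", "control"):
        raise ConfigError("correlation.group must be 'patient', 'control', or null")
    if not cfg.simulate.enabled and (
        cfg.paths.volumes is None or cfg.paths.participants is None
    ):
        raise ConfigError(
            "paths.volumes and paths.participants are required unless "
            "simulate.enabled is true"
        )


def load_config(path: str | Path) -> PipelineConfig:
    """Read and validate a YAML pipeline config."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return config_from_dict(raw)


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
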