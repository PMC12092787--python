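"""Synthetic grey-matter volumes with known latent structure.

The generator emulates the statistical model that source-based morphometry
assumes: each subject's smoothed grey-matter image is a linear mixture of a
small number of spatial sources,

    volume_i = baseline + sum_k loading[i, k] * source_k + noise,

clipped at zero to mimic nonnegative grey-matter maps.  Sources are sums of
Gaussian blobs with limited cross-source overlap; loadings are Gaussian with
an optional group-dependent mean shift (patients vs controls); one clinical
score can be generated so that its age-partialled correlation with a chosen
source's loadings approaches a configured target.  Everything is
deterministic given the config seed.

Ground truth (true sources, loadings, effects, clinical targets) is returned
and persisted alongside the data so that recovery metrics can be computed
without re-running generation.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exceptions import ValidationError
from .io_volumes import (
    CLINICAL_COLUMNS,
    VolumeSet,
    write_participants,
    write_volumes,
)

#: per-group (mean, sd) used to draw plausible clinical scores:
#: (patient, control); None marks scores undefined for controls
CLINICAL_NORMS: dict[str, tuple[tuple[float, float], tuple[float, float] | None]] = {
    "PCS": ((27.6, 12.5), (12.0, 10.9)),
    "helplessness": ((13.3, 5.7), (4.9, 4.9)),
    "magnification": ((5.3, 3.8), (2.6, 2.6)),
    "rumination": ((9.3, 4.6), (4.5, 4.2)),
    "PSP": ((56.1, 28.7), (17.6, 23.7)),
    "STAI": ((52.8, 20.0), (26.1, 10.7)),
    "CESD": ((30.6, 13.7), (11.0, 8.6)),
    "pain_intensity": ((7.2, 1.6), None),
    "fm_years": ((5.2, 5.0), None),
}


@dataclass
class ClinicalLink:
    """Tie one clinical column to one source's loadings.

    ``r`` is the target age-partialled correlation between the column and
    the loadings of source ``source`` (0-based), |r| < 1.
    """

    source: int
    column: str
    r: float

    def __post_init__(self) -> None:
        if not abs(self.r) < 1:
            raise ValidationError(f"target correlation |r| must be < 1, got {self.r}")
        if self.column not in CLINICAL_NORMS:
            raise ValidationError(
                f"unknown clinical column {self.column!r}; "
                f"available: {sorted(CLINICAL_NORMS)}"
            )


@dataclass
class SyntheticConfig:
    """Study-design parameters for the synthetic cohort.

    Defaults mirror the emulated study: 20 patients vs 20 controls, four
    spatial sources with a group shift on the last one, 3-mm voxels on a
    desk-scale 24x28x24 grid.
    """

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
    clinical_link: ClinicalLink | None = field(
        default_factory=lambda: ClinicalLink(source=3, column="magnification", r=-0.6)
    )
    seed: int = 0
    max_source_overlap: float = 0.2
    age_confounding: float = 0.3  # weight of standardized age in linked score

    def __post_init__(self) -> None:
        if self.k_true < 1:
            raise ValidationError("k_true must be >= 1")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.blob_sigma_mm <= 0:
            raise ValidationError("blob_sigma_mm must be > 0")
        if self.baseline < 0:
            raise ValidationError("baseline must be >= 0")
        if self.n_patients < 2 or self.n_controls < 2:
            raise ValidationError("at least 2 subjects per group required")
        if len(self.group_effect) != self.k_true:
            raise ValidationError(
                f"group_effect has {len(self.group_effect)} entries "
                f"for k_true={self.k_true}"
            )
        if self.clinical_link is not None and not (
            0 <= self.clinical_link.source < self.k_true
        ):
            raise ValidationError("clinical_link.source out of range")
        margin_vox = np.asarray(self.blob_sigma_mm) / np.asarray(self.voxel_mm)
        if np.any(2 * margin_vox >= np.asarray(self.grid_shape)):
            raise ValidationError("blobs do not fit inside the grid")

    @property
    def n_subjects(self) -> int:
        return self.n_patients + self.n_controls

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.grid_shape))


@dataclass
class SyntheticGroundTruth:
    """Latent quantities recorded for recovery testing."""

    true_sources: np.ndarray  # (k_true, n_voxels), Fortran voxel order
    true_loadings: np.ndarray  # (n_subjects, k_true), patients first
    true_group_effects: np.ndarray  # (k_true,), in loading-sd units
    clinical_link_source: int | None
    clinical_link_column: str | None
    clinical_link_r: float | None

    def save(self, path: str | os.PathLike) -> None:
        np.savez_compressed(
            path,
            true_sources=self.true_sources,
            true_loadings=self.true_loadings,
            true_group_effects=self.true_group_effects,
            clinical_link_source=-1
            if self.clinical_link_source is None
            else self.clinical_link_source,
            clinical_link_column=""
            if self.clinical_link_column is None
            else self.clinical_link_column,
            clinical_link_r=np.nan
            if self.clinical_link_r is None
            else self.clinical_link_r,
        )

    @classmethod
    def load(cls, path: str | os.PathLike) -> "SyntheticGroundTruth":
        with np.load(path, allow_pickle=False) as z:
            src = int(z["clinical_link_source"])
            col = str(z["clinical_link_column"])
            r = float(z["clinical_link_r"])
            return cls(
                true_sources=z["true_sources"],
                true_loadings=z["true_loadings"],
                true_group_effects=z["true_group_effects"],
                clinical_link_source=None if src < 0 else src,
                clinical_link_column=col or None,
                clinical_link_r=None if np.isnan(r) else r,
            )


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def _place_centres(cfg: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """Seeded blob centres (mm), rejection-sampled for cross-source separation.

    Centres of different sources must be at least ``3 * blob_sigma_mm``
    apart; if the grid is too small for that, the separation is relaxed by
    x0.9 until placement succeeds, which guarantees termination on small
    grids while keeping sources spatially distinct.
    """
    extent = np.asarray(cfg.grid_shape) * np.asarray(cfg.voxel_mm)
    margin = cfg.blob_sigma_mm
    lo, hi = margin, extent - margin
    separation = 3.0 * cfg.blob_sigma_mm
    while True:
        centres = np.full((cfg.k_true, cfg.blobs_per_source, 3), np.nan)
        ok = True
        for k in range(cfg.k_true):
            for b in range(cfg.blobs_per_source):
                placed = False
                for _ in range(2000):
                    c = rng.uniform(lo, hi)
                    others = centres[np.arange(cfg.k_true) != k].reshape(-1, 3)
                    others = others[~np.isnan(others[:, 0])]
                    if others.size == 0 or (
                        np.linalg.norm(others - c, axis=1) >= separation
                    ).all():
                        centres[k, b] = c
                        placed = True
                        break
                if not placed:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            return centres
        separation *= 0.9


def generate_sources(cfg: SyntheticConfig, rng: np.random.Generator | None = None) -> np.ndarray:
    """Build ``(k_true, n_voxels)`` spatial sources as unit-peak Gaussian blob sums.

    Voxels are enumerated in the package's fixed Fortran order.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    centres = _place_centres(cfg, rng)
    # world coordinate of each voxel centre, per axis
    axes = [
        (np.arange(n) + 0.5) * v
        for n, v in zip(cfg.grid_shape, cfg.voxel_mm)
    ]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    sources = np.empty((cfg.k_true, cfg.n_voxels))
    two_s2 = 2.0 * cfg.blob_sigma_mm**2
    for k in range(cfg.k_true):
        vol = np.zeros(cfg.grid_shape)
        for c in centres[k]:
            d2 = (xx - c[0]) ** 2 + (yy - c[1]) ** 2 + (zz - c[2]) ** 2
            vol += np.exp(-d2 / two_s2)
        vol /= vol.max()
        sources[k] = vol.ravel(order="F")
    return sources


def source_overlap(sources: np.ndarray, support_level: float = 0.1) -> np.ndarray:
    """Pairwise overlap fractions: |supp_i & supp_j| / min(|supp_i|, |supp_j|)."""
    supp = sources > support_level
    k = sources.shape[0]
    out = np.zeros((k, k))
    sizes = supp.sum(axis=1)
    for i in range(k):
        for j in range(i + 1, k):
            out[i, j] = out[j, i] = supp[i][supp[j]].sum() / max(
                1, min(sizes[i], sizes[j])
            )
    return out


def generate_loadings(cfg: SyntheticConfig, rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw ``(n_subjects, k_true)`` loadings, patients first.

    Controls ~ Normal(loading_mean, loading_sd); patient loadings for source
    k are shifted by ``group_effect[k] * loading_sd``.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n = cfg.n_subjects
    loadings = rng.normal(cfg.loading_mean, cfg.loading_sd, size=(n, cfg.k_true))
    shift = np.asarray(cfg.group_effect) * cfg.loading_sd
    loadings[: cfg.n_patients] += shift[None, :]
    return loadings


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def _clinical_scores(
    cfg: SyntheticConfig,
    loadings: np.ndarray,
    ages: np.ndarray,
    rng: np.random.Generator,
) -> pd.DataFrame:
    n_p, n_c = cfg.n_patients, cfg.n_controls
    cols: dict[str, np.ndarray] = {}
    for name, (pat, ctl) in CLINICAL_NORMS.items():
        vals = np.full(cfg.n_subjects, np.nan)
        vals[:n_p] = rng.normal(pat[0], pat[1], n_p)
        if ctl is not None:
            vals[n_p:] = rng.normal(ctl[0], ctl[1], n_c)
        cols[name] = vals
    link = cfg.clinical_link
    if link is not None:
        pat, ctl = CLINICAL_NORMS[link.column]
        if ctl is None:
            mean, sd = pat
        else:  # pooled scale across both groups
            mean = (n_p * pat[0] + n_c * ctl[0]) / cfg.n_subjects
            sd = np.sqrt((n_p * pat[1] ** 2 + n_c * ctl[1] ** 2) / cfg.n_subjects)
        z = _standardize(loadings[:, link.source])
        e = rng.standard_normal(cfg.n_subjects)
        gamma = cfg.age_confounding
        raw = link.r * z + np.sqrt(1 - link.r**2) * e + gamma * _standardize(ages)
        raw /= np.sqrt(1 + gamma**2)
        vals = mean + sd * raw
        if ctl is None:
            vals[n_p:] = np.nan
        cols[link.column] = vals
    return pd.DataFrame(cols)


def synthesize_dataset(
    cfg: SyntheticConfig,
) -> tuple[VolumeSet, pd.DataFrame, SyntheticGroundTruth]:
    """Generate volumes, a participants table, and the ground truth.

    Ages ~ Uniform(25, 60); TIV ~ Normal(1400, 120) ml.  Subject ids are
    ``sub-p01..`` (patients) then ``sub-c01..`` (controls), matching the
    table order.
    """
    rng = np.random.default_rng(cfg.seed)
    sources = generate_sources(cfg, rng)
    loadings = generate_loadings(cfg, rng)
    ages = rng.uniform(25, 60, cfg.n_subjects)
    tiv = rng.normal(1400, 120, cfg.n_subjects)

    X = cfg.baseline + loadings @ sources
    if cfg.noise_sd > 0:
        X = X + rng.normal(0, cfg.noise_sd, size=X.shape)
    X = np.clip(X, 0, None)
    data = X.reshape((cfg.n_subjects, *cfg.grid_shape), order="F")

    clinical = _clinical_scores(cfg, loadings, ages, rng)

    width_p = max(2, len(str(cfg.n_patients)))
    width_c = max(2, len(str(cfg.n_controls)))
    ids = [f"sub-p{i + 1:0{width_p}d}" for i in range(cfg.n_patients)] + [
        f"sub-c{i + 1:0{width_c}d}" for i in range(cfg.n_controls)
    ]
    table = pd.DataFrame(
        {
            "participant_id": ids,
            "group": ["patient"] * cfg.n_patients + ["control"] * cfg.n_controls,
            "age": ages,
            "tiv": tiv,
        }
    )
    table = pd.concat([table, clinical], axis=1)

    affine = np.diag([*cfg.voxel_mm, 1.0])
    vs = VolumeSet(ids, data, affine)
    link = cfg.clinical_link
    gt = SyntheticGroundTruth(
        true_sources=sources,
        true_loadings=loadings,
        true_group_effects=np.asarray(cfg.group_effect, dtype=float),
        clinical_link_source=None if link is None else link.source,
        clinical_link_column=None if link is None else link.column,
        clinical_link_r=None if link is None else link.r,
    )
    return vs, table, gt


def write_dataset(
    cfg: SyntheticConfig, out_dir: str | os.PathLike
) -> tuple[VolumeSet, pd.DataFrame, SyntheticGroundTruth]:
    """Generate and persist a dataset: NIfTI volumes, participants.tsv,
    ground_truth.npz, and the resolved config (YAML)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    vs, table, gt = synthesize_dataset(cfg)
    write_volumes(vs, out_dir)
    write_participants(table, out_dir / "participants.tsv")
    gt.save(out_dir / "ground_truth.npz")
    cfg_dict = asdict(cfg)
    with open(out_dir / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg_dict, fh, sort_keys=False)
    return vs, table, gt
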