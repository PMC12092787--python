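"""End-to-end pipeline: simulate -> preprocess -> decompose -> stats -> correlate.

Each stage records its inputs, outputs and seeds in a JSON manifest with
content hashes; rerunning with the same config and master seed reproduces
all outputs (ICA outputs are deterministic given the seed and BLAS).  On a
stage failure the files written so far are renamed with a ``.partial``
suffix and the stage name is reported.
"""

from __future__ import annotations

import glob
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .correlation import correlate_all, extract_roi_series, residualized_pairs
from .decomposition import DecompositionResult, decompose
from .exceptions import ConfigError, SbmError
from .group_stats import (
    analyze_components,
    clusters_to_frame,
    label_clusters,
    threshold_components,
)
from .io_volumes import (
    BrainMask,
    MeasureMatrix,
    build_mask,
    load_volumes,
    read_participants,
    resample_volume,
    smooth_volumes,
    vectorize,
    write_component_maps,
    write_mask,
)
from .synthetic_data import write_dataset

log = logging.getLogger("sbmorph")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class StageFailure(SbmError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def save_measure_matrix(mm: MeasureMatrix, path: Path) -> None:
    np.savez_compressed(
        path,
        values=mm.values,
        mask_grid=mm.mask.grid,
        subject_ids=np.asarray(mm.subject_ids),
        affine=mm.affine,
    )


def load_measure_matrix(path: str | Path) -> MeasureMatrix:
    with np.load(path, allow_pickle=False) as z:
        return MeasureMatrix(
            values=z["values"],
            mask=BrainMask(z["mask_grid"]),
            subject_ids=[str(s) for s in z["subject_ids"]],
            affine=z["affine"],
        )


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path, seed: int | None = None) -> dict:
    """Run all enabled stages; returns the manifest dict.

    ``seed`` overrides the decomposition master seed (and seeds the
    simulation stage when enabled).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    master_seed = cfg.decomposition.seed if seed is None else int(seed)
    manifest: dict = {
        "package": "sbmorph",
        "version": __version__,
        "master_seed": master_seed,
        "config": cfg.to_dict(),
        "stages": [],
        "outputs": {},
    }
    written: list[Path] = []
    current_stage = "setup"

    def record(name: str, path: Path) -> None:
        written.append(path)
        manifest["outputs"][name] = {
            "path": str(path.relative_to(out)) if path.is_relative_to(out) else str(path),
            "sha256": _sha256(path),
        }

    def stage_done(name: str, t0: float, **info) -> None:
        manifest["stages"].append(
            {"name": name, "seconds": round(time.time() - t0, 3), **info}
        )

    try:
        # ------------------------------------------------------------- simulate
        if cfg.simulate.enabled:
            current_stage = "simulate"
            t0 = time.time()
            data_dir = out / "data"
            scfg = cfg.simulate.to_synthetic(seed=master_seed)
            vs, table, _ = write_dataset(scfg, data_dir)
            for p in sorted(data_dir.iterdir()):
                record(f"data/{p.name}", p)
            stage_done("simulate", t0, n_subjects=vs.n_subjects, seed=master_seed)
            log.info("simulate: %d subjects on grid %s", vs.n_subjects, vs.grid_shape)
        else:
            current_stage = "load"
            t0 = time.time()
            paths = sorted(glob.glob(cfg.paths.volumes))
            if not paths:
                raise ConfigError(f"no volumes match {cfg.paths.volumes!r}")
            vs, table = load_volumes(paths, cfg.paths.participants)
            stage_done("load", t0, n_subjects=vs.n_subjects)

        # ----------------------------------------------------------- preprocess
        current_stage = "preprocess"
        t0 = time.time()
        pp = cfg.preprocessing
        if pp.resample_mm is not None and not np.allclose(
            vs.voxel_size, pp.resample_mm
        ):
            vs = resample_volume(vs, pp.resample_mm)
            log.info("resampled to %s mm, grid %s", pp.resample_mm, vs.grid_shape)
        if pp.fwhm_mm > 0:
            vs = smooth_volumes(vs, pp.fwhm_mm)
        mask = build_mask(vs, pp.mask_threshold, pp.mask_require_variance)
        mm = vectorize(vs, mask)
        save_measure_matrix(mm, out / "measure.npz")
        record("measure", out / "measure.npz")
        write_mask(mask, vs.affine, out / "mask.nii.gz")
        record("mask", out / "mask.nii.gz")
        stage_done("preprocess", t0, n_voxels=mask.n_voxels, fwhm_mm=pp.fwhm_mm)
        log.info("measure matrix: %d x %d", mm.n_subjects, mm.n_voxels)

        # ------------------------------------------------------------ decompose
        current_stage = "decompose"
        t0 = time.time()
        dc = cfg.decomposition
        result: DecompositionResult = decompose(
            mm,
            k=dc.k,
            n_runs=dc.n_runs,
            seed=master_seed,
            max_k=dc.max_k,
            mdl_decimation=dc.mdl_decimation,
            infomax_params=dc.infomax_params(),
        )
        write_component_maps(result.sources_z, mask, vs.affine, out / "components.nii.gz")
        record("components", out / "components.nii.gz")
        mixing_df = pd.DataFrame(
            result.mixing,
            columns=[f"component_{j + 1}" for j in range(result.k)],
        )
        mixing_df.insert(0, "participant_id", mm.subject_ids)
        mixing_df.to_csv(out / "mixing.tsv", sep="\t", index=False)
        record("mixing", out / "mixing.tsv")
        pd.DataFrame(
            {
                "component": np.arange(1, result.k + 1),
                "iq": result.stability_iq,
            }
        ).to_csv(out / "stability.tsv", sep="\t", index=False)
        record("stability", out / "stability.tsv")
        info = {"k": result.k, "n_runs": dc.n_runs,
                "run_seeds": [r.seed for r in result.runs],
                "converged": [bool(r.converged) for r in result.runs]}
        if result.order_estimate is not None:
            est = result.order_estimate
            pd.DataFrame(
                {
                    "k": np.arange(1, est.criterion_values.size + 1),
                    "mdl": est.criterion_values,
                }
            ).to_csv(out / "mdl.tsv", sep="\t", index=False)
            record("mdl", out / "mdl.tsv")
            info["mdl_k_selected"] = est.k_selected
        stage_done("decompose", t0, **info)
        log.info("decomposition: k=%d, Iq=%s", result.k,
                 np.round(result.stability_iq, 3).tolist())

        # ---------------------------------------------------------------- stats
        current_stage = "stats"
        t0 = time.time()
        st = cfg.stats
        cov_cols = [c for c in st.covariates]
        covariates = table[cov_cols].to_numpy(dtype=float) if cov_cols else None
        comp_stats = analyze_components(
            result.mixing,
            table["group"].to_numpy(),
            covariates,
            q=st.fdr_q,
            df_mode=st.df_mode,
        )
        comp_stats.to_csv(out / "component_stats.tsv", sep="\t", index=False)
        record("component_stats", out / "component_stats.tsv")
        sig = comp_stats.loc[comp_stats["significant"], "component"].tolist()
        keep_rows = [c - 1 for c in sig] if sig else []
        clusters = threshold_components(
            result.sources_z[keep_rows] if keep_rows else result.sources_z[:0],
            mask,
            vs.affine,
            z_threshold=st.z_threshold,
            connectivity=st.connectivity,
        )
        # threshold_components numbers rows 1..len(keep_rows); restore ids
        for c in clusters:
            c.component = sig[c.component - 1]
        clusters = label_clusters(clusters, comp_stats)
        clusters_to_frame(clusters).to_csv(out / "clusters.tsv", sep="\t", index=False)
        record("clusters", out / "clusters.tsv")
        if clusters:
            np.savez_compressed(
                out / "cluster_voxels.npz",
                **{
                    f"cluster_{i}": c.voxel_index
                    for i, c in enumerate(clusters)
                },
            )
            record("cluster_voxels", out / "cluster_voxels.npz")
        stage_done("stats", t0, significant_components=sig, n_clusters=len(clusters))
        log.info("stats: significant components %s, %d clusters", sig, len(clusters))

        # ------------------------------------------------------------ correlate
        current_stage = "correlate"
        t0 = time.time()
        cr = cfg.correlation
        metrics = [m for m in cr.metrics if m in table.columns]
        if clusters and metrics:
            rois = [extract_roi_series(mm, c) for c in clusters]
            corr = correlate_all(
                rois, table, metrics,
                covariates=list(cr.covariates), group=cr.group, fdr_q=cr.fdr_q,
            )
            corr.to_csv(out / "correlations.tsv", sep="\t", index=False)
            record("correlations", out / "correlations.tsv")
            scatter_dir = out / "scatter"
            scatter_dir.mkdir(exist_ok=True)
            for roi in rois:
                for m in metrics:
                    pairs = residualized_pairs(roi, table, m, list(cr.covariates))
                    p = scatter_dir / f"{roi.roi_id}_{m}.tsv"
                    pairs.to_csv(p, sep="\t", index=False)
                    record(f"scatter/{p.name}", p)
            n_corr = len(corr)
        else:
            n_corr = 0
        stage_done("correlate", t0, n_results=n_corr)

    except BaseException as exc:
        for p in written:
            if p.exists():
                p.rename(p.with_name(p.name + ".partial"))
        if isinstance(exc, SbmError):
            raise StageFailure(current_stage, exc) from exc
        raise

    manifest_path = out / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
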