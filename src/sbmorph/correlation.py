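"""ROI extraction and age-partialled correlations with clinical metrics.

Per-subject grey-matter values are averaged over each significant
cluster's voxels, residualized on the covariates (age by default), and
correlated with clinical scores that are residualized the same way.  The
partial correlation is the Pearson correlation of the two residual
series, with p-values from t = r sqrt((n - 2 - n_cov) / (1 - r^2)).

Missing clinical entries (scores undefined for controls, e.g. pain
intensity) are dropped pairwise; the effective n is recorded per result.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ValidationError
from .group_stats import Cluster, regress_out_covariates
from .io_volumes import MeasureMatrix


@dataclass
class ROISeries:
    """Per-subject mean grey-matter values within one cluster."""

    roi_id: str
    values: np.ndarray  # (n_subjects,)
    subject_ids: list[str]


@dataclass
class PartialCorrelationResult:
    roi_id: str
    metric: str
    r: float
    p: float
    n_effective: int
    covariates: tuple[str, ...]


def extract_roi_series(mm: MeasureMatrix, cluster: Cluster) -> ROISeries:
    """Mean measure-matrix value over the cluster's voxels, per subject.

    The cluster's flat voxel indices must all lie inside the measure
    matrix's mask.
    """
    if cluster.voxel_index.size == 0:
        raise ValidationError("empty cluster")
    pos = np.searchsorted(mm.mask.linear_index, cluster.voxel_index)
    inside = (pos < mm.mask.linear_index.size) & (
        mm.mask.linear_index[np.clip(pos, 0, mm.mask.linear_index.size - 1)]
        == cluster.voxel_index
    )
    if not inside.all():
        raise ValidationError("cluster contains voxels outside the mask")
    roi_id = f"C{cluster.component}_{cluster.sign}_{cluster.size}vox"
    return ROISeries(
        roi_id=roi_id,
        values=mm.values[:, pos].mean(axis=1),
        subject_ids=list(mm.subject_ids),
    )


def partial_correlation(
    x: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
    roi_id: str = "x",
    metric: str = "y",
    covariate_names: tuple[str, ...] = (),
) -> PartialCorrelationResult:
    """Partial correlation of x and y given covariates.

    Both series are residualized on ``[1, covariates]`` by OLS; r is the
    Pearson correlation of the residuals.  With an empty covariate set this
    is the plain Pearson correlation (identical p-value formula with
    n_cov = 0).  Rows with a missing value in x, y, or any covariate are
    dropped pairwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("x and y must have the same length")
    C = None
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
    keep = np.isfinite(x) & np.isfinite(y)
    if C is not None:
        keep &= np.isfinite(C).all(axis=1)
    n_cov = 0 if C is None else C.shape[1]
    n = int(keep.sum())
    if n <= n_cov + 2:
        raise ValidationError(
            f"need more than {n_cov + 2} complete observations, have {n}"
        )
    xr = regress_out_covariates(x[keep], None if C is None else C[keep])
    yr = regress_out_covariates(y[keep], None if C is None else C[keep])
    sx, sy = xr.std(), yr.std()
    # residual variance at float round-off means x or y lies in the
    # covariate span (e.g. a covariate equal to x)
    if sx <= 1e-10 * max(x[keep].std(), 1.0) or sy <= 1e-10 * max(
        y[keep].std(), 1.0
    ):
        raise ValidationError("degenerate after residualization: zero variance")
    r = float((xr @ yr) / (n * sx * sy))
    r = float(np.clip(r, -1.0, 1.0))
    df = n - 2 - n_cov
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), df))
    return PartialCorrelationResult(
        roi_id=roi_id, metric=metric, r=r, p=p, n_effective=n,
        covariates=covariate_names,
    )


def correlate_all(
    rois: list[ROISeries],
    participants: pd.DataFrame,
    metrics: list[str],
    covariates: list[str] = ("age",),
    group: str | None = None,
    fdr_q: float | None = None,
) -> pd.DataFrame:
    """Partial correlations for every (ROI, clinical metric) pair.

    ``group`` restricts the analysis to one group ('patient'/'control');
    by default both groups are pooled and metrics undefined for controls
    restrict themselves via pairwise missing-data handling.  BH adjustment
    across the grid is optional (off by default; the correlations are
    exploratory).
    """
    covariates = list(covariates)
    missing = [m for m in metrics if m not in participants.columns]
    if missing:
        available = [
            c for c in participants.columns
            if c not in ("participant_id", "group")
        ]
        raise ValidationError(
            f"unknown metric(s) {missing}; available columns: {available}"
        )
    for c in covariates:
        if c not in participants.columns:
            raise ValidationError(f"unknown covariate {c!r}")

    table = participants
    row_keep = np.ones(len(table), dtype=bool)
    if group is not None:
        if group not in ("patient", "control"):
            raise ValidationError("group must be 'patient' or 'control'")
        row_keep = (table["group"] == group).to_numpy()

    C = table[covariates].to_numpy(dtype=float) if covariates else None
    results = []
    for roi in rois:
        if list(table["participant_id"]) != roi.subject_ids:
            raise ValidationError(
                f"ROI {roi.roi_id}: subject order does not match participants table"
            )
        x = np.where(row_keep, roi.values, np.nan)
        for m in metrics:
            y = np.where(row_keep, table[m].to_numpy(dtype=float), np.nan)
            results.append(
                partial_correlation(
                    x, y,
                    covariates=None if C is None else C,
                    roi_id=roi.roi_id, metric=m,
                    covariate_names=tuple(covariates),
                )
            )
    df = pd.DataFrame(
        [
            {
                "roi_id": r.roi_id,
                "metric": r.metric,
                "r": r.r,
                "p": r.p,
                "n_effective": r.n_effective,
            }
            for r in results
        ]
    )
    if fdr_q is not None:
        from .group_stats import fdr_adjust

        p_adj, reject = fdr_adjust(df["p"].to_numpy(), q=fdr_q)
        df["p_fdr"] = p_adj
        df["significant"] = reject
    return df


def residualized_pairs(
    roi: ROISeries,
    participants: pd.DataFrame,
    metric: str,
    covariates: list[str] = ("age",),
) -> pd.DataFrame:
    """Scatter-plot data: residualized ROI values vs residualized metric.

    Returns a DataFrame (participant_id, x_resid, y_resid) over complete
    cases, mirroring the content of partial-correlation scatter panels.
    """
    covariates = list(covariates)
    x = np.asarray(roi.values, dtype=float)
    y = participants[metric].to_numpy(dtype=float)
    C = participants[covariates].to_numpy(dtype=float) if covariates else None
    keep = np.isfinite(x) & np.isfinite(y)
    if C is not None:
        keep &= np.isfinite(C).all(axis=1)
    xr = regress_out_covariates(x[keep], None if C is None else C[keep])
    yr = regress_out_covariates(y[keep], None if C is None else C[keep])
    return pd.DataFrame(
        {
            "participant_id": np.asarray(roi.subject_ids)[keep],
            "x_resid": xr,
            "y_resid": yr,
        }
    )
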