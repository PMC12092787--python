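"""Group inference on loading coefficients and spatial thresholding.

Each column of the mixing matrix holds one component's loading
coefficients across subjects.  Group differences (patients vs controls)
are tested with a covariate-adjusted two-sample t-test, corrected for
multiple comparisons with Benjamini-Hochberg FDR.  Significant components'
Z-scored source maps are thresholded at |Z| > 3 into signed, 26-connected
clusters, and the direction of the grey-matter effect in each cluster is
read off the sign rule: a positive loading difference on a positive map
region means greater tissue volume in patients, and every sign flip
inverts the label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

from .exceptions import ValidationError
from .io_volumes import BrainMask, map_to_volume

GREATER = "greater-in-patients"
LOWER = "lower-in-patients"


# ---------------------------------------------------------------------------
# covariate adjustment
# ---------------------------------------------------------------------------


def _design(covariates: np.ndarray | None, n: int) -> np.ndarray:
    if covariates is None:
        return np.ones((n, 1))
    C = np.asarray(covariates, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    if C.shape[0] != n:
        raise ValidationError(f"covariates have {C.shape[0]} rows for {n} values")
    return np.column_stack([np.ones(n), C])


def regress_out_covariates(
    values: np.ndarray, covariates: np.ndarray | None
) -> np.ndarray:
    """OLS residuals of ``values`` on ``[1, covariates]``.

    Residuals are orthogonal to the intercept and every covariate column.
    Collinear covariates (including zero-variance columns, collinear with
    the intercept) raise a rank error.
    """
    y = np.asarray(values, dtype=float)
    X = _design(covariates, y.shape[0])
    if y.shape[0] <= X.shape[1]:
        raise ValidationError(
            f"need more than {X.shape[1]} observations to adjust for "
            f"{X.shape[1] - 1} covariate(s)"
        )
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValidationError(
            "collinear covariates: design matrix (intercept + "
            f"{X.shape[1] - 1} column(s)) has rank {rank}"
        )
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


# ---------------------------------------------------------------------------
# loading-coefficient group test
# ---------------------------------------------------------------------------


def component_group_test(
    loadings: np.ndarray,
    groups: np.ndarray,
    covariates: np.ndarray | None = None,
    df_mode: str = "adjusted",
) -> tuple[float, float]:
    """Covariate-adjusted two-sample t-test on one mixing-matrix column.

    Both the loadings and the patient indicator are residualized on the
    covariates (Frisch-Waugh), so the statistic equals the partial t of the
    group term in an OLS of loading on [1, group, covariates].  Sign
    convention: t > 0 iff the adjusted patient mean exceeds the control
    mean.  ``df_mode='adjusted'`` uses df = n1 + n2 - 2 - n_covariates;
    ``'naive'`` keeps df = n1 + n2 - 2 (the conventional two-sample value).

    Without covariates this reduces exactly to the pooled-variance
    two-sample t-test.
    """
    y = np.asarray(loadings, dtype=float)
    g = np.asarray(groups)
    if g.dtype.kind in "US O":
        g = (g == "patient").astype(float)
    g = g.astype(float)
    n1, n0 = int(g.sum()), int((1 - g).sum())
    if n1 < 2 or n0 < 2:
        raise ValidationError("both groups need at least 2 subjects")
    if df_mode not in ("adjusted", "naive"):
        raise ValidationError(f"df_mode must be 'adjusted' or 'naive', got {df_mode}")

    n_cov = 0
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        n_cov = 1 if C.ndim == 1 else C.shape[1]
        y = regress_out_covariates(y, C)
        g_res = regress_out_covariates(g, C)
    else:
        g_res = g - g.mean()

    n = y.shape[0]
    sgg = float(g_res @ g_res)
    if sgg <= 0:
        raise ValidationError("group indicator collinear with covariates")
    beta = float(g_res @ y) / sgg
    resid = y - y.mean() - beta * g_res if covariates is None else None
    if covariates is None:
        rss = float(resid @ resid)
    else:
        fit = y - beta * g_res  # y already residualized (mean 0 wrt design)
        rss = float(fit @ fit)
    df = n - 2 - n_cov
    if rss <= 0:
        raise ValidationError("zero pooled variance: loadings perfectly separated")
    se = np.sqrt(rss / df / sgg)
    t = beta / se
    p_df = df if df_mode == "adjusted" else n - 2
    p = 2.0 * stats.t.sf(abs(t), p_df)
    return float(t), float(p)


def fdr_adjust(pvals, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjustment.

    Returns ``(adjusted_pvals, reject_flags)``; a hypothesis is rejected
    iff its adjusted p-value is below ``q``.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy(), np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValidationError("p-values must lie in [0, 1]")
    _, p_adj, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, p_adj < q


def analyze_components(
    mixing: np.ndarray,
    groups: np.ndarray,
    covariates: np.ndarray | None = None,
    q: float = 0.05,
    df_mode: str = "adjusted",
) -> pd.DataFrame:
    """Per-component group tests with FDR correction.

    Returns a DataFrame with columns ``component`` (1-based), ``t``, ``p``,
    ``p_fdr``, ``significant``, ``mean_patient``, ``mean_control`` (means of
    covariate-adjusted loadings).
    """
    A = np.asarray(mixing, dtype=float)
    g = np.asarray(groups)
    is_patient = g == "patient" if g.dtype.kind in "US O" else g.astype(bool)
    rows = []
    for j in range(A.shape[1]):
        t, p = component_group_test(A[:, j], groups, covariates, df_mode=df_mode)
        adj = (
            regress_out_covariates(A[:, j], covariates)
            if covariates is not None
            else A[:, j]
        )
        rows.append(
            {
                "component": j + 1,
                "t": t,
                "p": p,
                "mean_patient": float(adj[is_patient].mean()),
                "mean_control": float(adj[~is_patient].mean()),
            }
        )
    df = pd.DataFrame(rows)
    p_fdr, reject = fdr_adjust(df["p"].to_numpy(), q=q)
    df["p_fdr"] = p_fdr
    df["significant"] = reject
    return df[
        ["component", "t", "p", "p_fdr", "significant", "mean_patient", "mean_control"]
    ]


# ---------------------------------------------------------------------------
# spatial thresholding
# ---------------------------------------------------------------------------


@dataclass
class Cluster:
    """A signed, supra-threshold connected component of a Z map."""

    component: int  # 1-based component index
    sign: str  # "positive" | "negative"
    size: int
    peak_z: float
    peak_ijk: tuple[int, int, int]
    peak_mm: tuple[float, float, float]
    voxel_index: np.ndarray  # flat Fortran-order indices on the full grid
    direction: str | None = None
    label: str | None = None


_CONNECTIVITY = {26: np.ones((3, 3, 3), dtype=bool), 6: ndimage.generate_binary_structure(3, 1)}


def _extract_sign_clusters(
    vol: np.ndarray, comp: int, sign: str, threshold: float, structure: np.ndarray,
    affine: np.ndarray,
) -> list[Cluster]:
    supra = vol > threshold if sign == "positive" else vol < -threshold
    labelled, n = ndimage.label(supra, structure=structure)
    out = []
    for lab in range(1, n + 1):
        idx = np.argwhere(labelled == lab)
        zvals = vol[tuple(idx.T)]
        mags = np.abs(zvals)
        best = np.lexsort((idx[:, 2], idx[:, 1], idx[:, 0], -mags))[0]
        peak_ijk = tuple(int(v) for v in idx[best])
        peak_mm = tuple(
            float(v) for v in (affine @ np.array([*peak_ijk, 1.0]))[:3]
        )
        flat = np.ravel_multi_index(idx.T, vol.shape, order="F")
        out.append(
            Cluster(
                component=comp,
                sign=sign,
                size=len(idx),
                peak_z=float(zvals[best]),
                peak_ijk=peak_ijk,
                peak_mm=peak_mm,
                voxel_index=np.sort(flat),
            )
        )
    return out


def threshold_components(
    sources_z: np.ndarray,
    mask: BrainMask,
    affine: np.ndarray,
    z_threshold: float = 3.0,
    connectivity: int = 26,
) -> list[Cluster]:
    """Split each Z map into signed supra-threshold clusters.

    Voxels with |Z| > ``z_threshold`` are grouped into ``connectivity``-
    connected components separately for each sign.  Clusters are sorted by
    size (descending), then peak |Z| (descending), then lexicographic peak
    voxel index.  An empty result is valid.
    """
    if z_threshold <= 0:
        raise ValidationError("z_threshold must be > 0")
    if connectivity not in _CONNECTIVITY:
        raise ValidationError(f"connectivity must be one of {sorted(_CONNECTIVITY)}")
    structure = _CONNECTIVITY[connectivity]
    Z = np.asarray(sources_z, dtype=float)
    if Z.ndim == 1:
        Z = Z[None, :]
    clusters: list[Cluster] = []
    for j in range(Z.shape[0]):
        vol = map_to_volume(Z[j], mask)
        for sign in ("positive", "negative"):
            clusters.extend(
                _extract_sign_clusters(vol, j + 1, sign, z_threshold, structure, affine)
            )
    clusters.sort(
        key=lambda c: (-c.size, -abs(c.peak_z), c.peak_ijk)
    )
    return clusters


def interpret_direction(t_sign: float, voxel_sign: float) -> str:
    """Sign rule for reading a cluster's grey-matter effect.

    Higher patient loadings (t > 0) on a positive map region mean greater
    tissue volume in patients; each sign flip of either factor inverts the
    label.  Zero signs are ambiguous and rejected.
    """
    if t_sign == 0 or voxel_sign == 0:
        raise ValidationError("ambiguous direction: zero sign")
    return GREATER if t_sign * voxel_sign > 0 else LOWER


def label_clusters(
    clusters: list[Cluster], component_stats: pd.DataFrame
) -> list[Cluster]:
    """Attach direction labels using each cluster's component t statistic."""
    t_by_comp = dict(
        zip(component_stats["component"], component_stats["t"])
    )
    for c in clusters:
        t = t_by_comp.get(c.component)
        if t is not None and t != 0:
            c.direction = interpret_direction(np.sign(t), 1.0 if c.sign == "positive" else -1.0)
    return clusters


def anatomical_labels(
    clusters: list[Cluster],
    label_grid: np.ndarray,
    lookup: dict[int, str],
) -> list[Cluster]:
    """Attach anatomical names from a user-supplied integer label volume.

    ``label_grid`` must be on the analysis grid (resample label images with
    nearest-neighbour interpolation beforehand); each cluster is named after
    the label at its peak voxel.  No atlas is bundled with the package.
    """
    label_grid = np.asarray(label_grid)
    for c in clusters:
        if label_grid.shape != ():
            value = int(label_grid[c.peak_ijk])
            c.label = lookup.get(value)
    return clusters


def clusters_to_frame(clusters: list[Cluster]) -> pd.DataFrame:
    """Tabular cluster summary (one row per cluster, voxel lists omitted)."""
    return pd.DataFrame(
        [
            {
                "component": c.component,
                "sign": c.sign,
                "size": c.size,
                "peak_z": c.peak_z,
                "x_mm": c.peak_mm[0],
                "y_mm": c.peak_mm[1],
                "z_mm": c.peak_mm[2],
                "direction": c.direction if c.direction is not None else "n/a",
                "label": c.label if c.label is not None else "n/a",
            }
            for c in clusters
        ],
        columns=[
            "component", "sign", "size", "peak_z",
            "x_mm", "y_mm", "z_mm", "direction", "label",
        ],
    )


# ---------------------------------------------------------------------------
# summary-statistics t-test (demographics tables)
# ---------------------------------------------------------------------------


def ttest_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, int, float]:
    """Pooled-variance two-sample t-test from group summary statistics.

    Returns ``(t, df, p)`` with df = n1 + n2 - 2 and a two-tailed p.  Two
    identical degenerate groups (both sds zero, equal means) give
    t = 0, p = 1 rather than an error.
    """
    if sd1 < 0 or sd2 < 0:
        raise ValidationError("standard deviations must be >= 0")
    if n1 < 2 or n2 < 2:
        raise ValidationError("each group needs n >= 2")
    df = n1 + n2 - 2
    if sd1 == 0 and sd2 == 0:
        if mean1 == mean2:
            return 0.0, df, 1.0
        return np.inf if mean1 > mean2 else -np.inf, df, 0.0
    t, p = stats.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=True
    )
    return float(t), df, float(p)
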