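"""ICA decomposition of the measure matrix with stability selection.

The measure matrix X (subjects x voxels) is treated as a linear mixture
X = A S of spatially independent sources.  The pipeline is the standard
source-based-morphometry stack:

1. model-order selection with the Minimum Description Length criterion on
   the subject-space covariance eigen-spectrum (:func:`estimate_order_mdl`);
2. row-mean centering and PCA whitening to ``k`` dimensions
   (:func:`pca_reduce`);
3. Infomax ICA — natural-gradient maximum-likelihood with a logistic
   nonlinearity — on the whitened data (:func:`infomax_unmix`);
4. ICASSO stability selection: many Infomax runs from random starts,
   agglomerative clustering of the pooled source estimates by absolute
   correlation, one centrotype per cluster with a cluster-quality index Iq
   (:func:`run_icasso`);
5. least-squares back-reconstruction of the subject loadings
   (:func:`back_reconstruct`) and Z-scoring of the source maps with a
   positive-skewness sign convention (:func:`zscore_and_sign_fix`).

ICA is identifiable only up to permutation, sign and scale; recovery
evaluation therefore matches components by maximum absolute correlation
(:func:`match_sources`, Hungarian assignment) before comparing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import squareform
from scipy.special import expit
from scipy.stats import skew

from .exceptions import (
    ConvergenceError,
    DegenerateComponentError,
    ValidationError,
)
from .io_volumes import MeasureMatrix

# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class OrderEstimate:
    """MDL model-order selection result.

    ``criterion_values[i]`` is MDL(k=i+1); ``k_selected`` is its argmin.
    """

    k_selected: int
    criterion_values: np.ndarray
    eigenvalues: np.ndarray


@dataclass
class Whitening:
    """PCA reduction of the row-centered measure matrix to k dimensions."""

    whitened: np.ndarray  # (k, n_voxels), rows have identity covariance
    dewhitening: np.ndarray  # (n_subjects, k)
    eigenvalues: np.ndarray  # full subject-space spectrum, descending
    row_means: np.ndarray  # per-subject means removed before PCA
    k: int

    @property
    def retained_variance(self) -> float:
        ev = np.clip(self.eigenvalues, 0, None)
        return float(ev[: self.k].sum() / ev.sum())


@dataclass
class IcaRun:
    """A single Infomax run in whitened space."""

    unmixing: np.ndarray  # (k, k)
    sources: np.ndarray  # (k, n_voxels)
    converged: bool
    n_steps: int
    seed: int


@dataclass
class DecompositionResult:
    """Final SBM decomposition: loadings, Z-scored source maps, stability.

    ``mixing @ sources_z`` reconstructs the row-centered measure matrix up
    to the variance discarded by the PCA reduction (source scale/offset is
    folded into ``mixing`` / ``source_means``).
    """

    k: int
    mixing: np.ndarray  # (n_subjects, k) loading coefficients
    sources_z: np.ndarray  # (k, n_voxels), mean 0 / sd 1, skewness >= 0
    stability_iq: np.ndarray  # (k,) cluster-quality indices in [-1, 1]
    runs: list[IcaRun]
    whitening: Whitening
    source_means: np.ndarray = field(default=None)  # pre-Z-score row means
    source_sds: np.ndarray = field(default=None)  # pre-Z-score row sds
    order_estimate: OrderEstimate | None = None


# ---------------------------------------------------------------------------
# model order (MDL)
# ---------------------------------------------------------------------------


def _subject_eigenspectrum(
    X: np.ndarray, decimation: int = 1
) -> tuple[np.ndarray, int]:
    """Eigenvalues (descending) of the subject-space covariance of
    row-centered X, with optional voxel decimation; returns (spectrum, N_eff)."""
    Xs = X[:, ::decimation] if decimation > 1 else X
    Xc = Xs - Xs.mean(axis=1, keepdims=True)
    n_eff = Xs.shape[1]
    cov = Xc @ Xc.T / n_eff
    ev = np.linalg.eigvalsh(cov)[::-1]
    return ev, n_eff


def estimate_order_mdl(
    mm: MeasureMatrix | np.ndarray,
    max_k: int | None = None,
    decimation: int = 4,
) -> OrderEstimate:
    """Select the number of ICA components with the MDL criterion.

    In-mask voxels are treated as N_eff observations of an n_subjects-
    dimensional signal.  With eigenvalues l_1 >= ... >= l_n of the
    subject-space covariance,

        MDL(k) = -N_eff (n - k) log( gm(l_{k+1..n}) / am(l_{k+1..n}) )
                 + 1/2 k (2n - k) log(N_eff),

    where gm/am are geometric and arithmetic means of the trailing
    eigenvalues; the selected order is the argmin over k = 1..max_k.

    Smoothed voxels are spatially correlated, violating the i.i.d.-samples
    assumption and inflating N_eff, so every ``decimation``-th voxel is used
    by default (factor 4).
    """
    X = mm.values if isinstance(mm, MeasureMatrix) else np.asarray(mm, dtype=float)
    n = X.shape[0]
    if max_k is None:
        max_k = n - 1
    if not 1 <= max_k <= n - 1:
        raise ValidationError(f"max_k must be in [1, {n - 1}], got {max_k}")
    if decimation < 1:
        raise ValidationError("decimation must be >= 1")

    ev, n_eff = _subject_eigenspectrum(X, decimation)
    floor = max(ev.max(), 0.0) * 1e-12
    if (ev <= floor).any():
        warnings.warn(
            "rank-deficient subject covariance; eigenvalue floor applied",
            RuntimeWarning,
        )
        ev = np.maximum(ev, max(floor, np.finfo(float).tiny))

    crit = np.empty(max_k)
    log_n_eff = np.log(n_eff)
    for k in range(1, max_k + 1):
        tail = ev[k:]
        m = n - k
        if m == 0:
            ratio = 0.0
        else:
            ratio = np.mean(np.log(tail)) - np.log(np.mean(tail))
        crit[k - 1] = -n_eff * m * ratio + 0.5 * k * (2 * n - k) * log_n_eff
    k_selected = int(np.argmin(crit)) + 1
    return OrderEstimate(k_selected=k_selected, criterion_values=crit, eigenvalues=ev)


# ---------------------------------------------------------------------------
# PCA whitening
# ---------------------------------------------------------------------------


def center_measure_matrix(X: np.ndarray) -> np.ndarray:
    """Remove per-subject (row) means and the mean image across subjects.

    Double centering: the column-mean removal makes the subject-space rank
    at most n - 1 (so k = n - 1 retains everything), and the row-mean
    removal gives every source row zero mean, which keeps the
    loadings x sources product consistent with the Z-scored maps.
    """
    Xc = X - X.mean(axis=1, keepdims=True)
    Xc -= Xc.mean(axis=0, keepdims=True)
    return Xc


def pca_reduce(mm: MeasureMatrix | np.ndarray, k: int) -> Whitening:
    """Center the measure matrix and whiten to k dimensions.

    Rows of the returned ``whitened`` matrix have identity covariance
    (scaled by 1/N over voxels).  ``dewhitening @ whitened`` restores the
    rank-k approximation of the centered data; with k = n - 1 the
    reconstruction is lossless.
    """
    X = mm.values if isinstance(mm, MeasureMatrix) else np.asarray(mm, dtype=float)
    n, n_vox = X.shape
    if not 1 <= k <= n - 1:
        raise ValidationError(f"k must be in [1, {n - 1}], got {k}")
    row_means = X.mean(axis=1)
    Xc = center_measure_matrix(X)
    cov = Xc @ Xc.T / n_vox
    ev, vec = np.linalg.eigh(cov)
    ev, vec = ev[::-1], vec[:, ::-1]
    if ev[k - 1] <= max(ev[0], 0.0) * 1e-12:
        raise ValidationError(f"k={k} exceeds the numerical rank of the data")
    d = ev[:k]
    E = vec[:, :k]
    whitened = (E / np.sqrt(d)).T @ Xc
    dewhitening = E * np.sqrt(d)
    return Whitening(
        whitened=whitened,
        dewhitening=dewhitening,
        eigenvalues=ev,
        row_means=row_means,
        k=k,
    )


# ---------------------------------------------------------------------------
# Infomax ICA
# ---------------------------------------------------------------------------


def _random_orthonormal(k: int, rng: np.random.Generator) -> np.ndarray:
    q, r = np.linalg.qr(rng.standard_normal((k, k)))
    return q * np.sign(np.diag(r))


def infomax_unmix(
    whitened: np.ndarray,
    seed: int = 0,
    lrate: float | None = None,
    block_size: int | None = None,
    anneal: float = 0.9,
    anneal_angle_deg: float = 60.0,
    max_steps: int = 512,
    tol: float = 1e-6,
    max_restarts: int = 3,
) -> IcaRun:
    """Bell-Sejnowski Infomax ICA on whitened data.

    Natural-gradient updates with the logistic nonlinearity
    g(u) = 1/(1 + e^-u) over shuffled voxel blocks:

        W <- W + lrate * ( I + (1 - 2 g(u)) u^T / B ) W,

    where B is the block size (the outer product is averaged over the
    block).  The learning rate anneals by ``anneal`` whenever the update
    direction turns by more than ``anneal_angle_deg`` between sweeps;
    iteration stops when the relative weight change drops below ``tol``.
    On divergence (|W| > 1e8) the run restarts with a halved learning rate,
    at most ``max_restarts`` times.

    Gaussian sources are a documented non-identifiable case: the run may
    converge but the recovered components are arbitrary rotations.
    """
    data = np.asarray(whitened, dtype=float)
    if not np.isfinite(data).all():
        raise ValidationError("whitened data must be finite")
    k, n = data.shape
    if lrate is None:
        lrate = 0.015 / np.log(k) if k > 1 else 0.015
    if block_size is None:
        block_size = max(8, int(np.floor(np.sqrt(n / 3.0))))
    block_size = min(block_size, n)
    cos_limit = np.cos(np.deg2rad(anneal_angle_deg))

    ident = np.eye(k)
    for restart in range(max_restarts + 1):
        rng = np.random.default_rng(seed + 104729 * restart)
        W = _random_orthonormal(k, rng)
        rate = lrate / (2.0**restart)
        prev_delta = None
        converged = False
        diverged = False
        step = 0
        while step < max_steps:
            step += 1
            perm = rng.permutation(n)
            W_old = W.copy()
            for start in range(0, n - block_size + 1, block_size):
                x = data[:, perm[start : start + block_size]]
                u = W @ x
                y = expit(u)
                W = W + rate * (ident + ((1.0 - 2.0 * y) @ u.T) / block_size) @ W
                if not np.isfinite(W).all() or np.abs(W).max() > 1e8:
                    diverged = True
                    break
            if diverged:
                break
            delta = W - W_old
            change = np.linalg.norm(delta) / max(np.linalg.norm(W_old), 1e-300)
            if prev_delta is not None:
                denom = np.linalg.norm(delta) * np.linalg.norm(prev_delta)
                if denom > 0 and np.vdot(delta, prev_delta) / denom < cos_limit:
                    rate *= anneal
            prev_delta = delta
            if change < tol:
                converged = True
                break
        if not diverged:
            return IcaRun(
                unmixing=W,
                sources=W @ data,
                converged=converged,
                n_steps=step,
                seed=seed,
            )
    raise ConvergenceError(
        f"Infomax diverged after {max_restarts} restarts (seed {seed})"
    )


def amari_index(P: np.ndarray) -> float:
    """Amari separation error of a permutation-like matrix P = W_est @ A_true.

    Zero iff P is a scaled permutation; normalized to [0, 1]-ish by
    2 k (k - 1).
    """
    P = np.abs(np.asarray(P, dtype=float))
    k = P.shape[0]
    if k < 2:
        return 0.0
    row = (P / P.max(axis=1, keepdims=True)).sum(axis=1) - 1.0
    col = (P / P.max(axis=0, keepdims=True)).sum(axis=0) - 1.0
    return float((row.sum() + col.sum()) / (2.0 * k * (k - 1)))


# ---------------------------------------------------------------------------
# back-reconstruction and standardization
# ---------------------------------------------------------------------------


def back_reconstruct(mm: MeasureMatrix | np.ndarray, sources: np.ndarray) -> np.ndarray:
    """Least-squares loadings A minimizing ||X_centered - A S||_F.

    X is centered with :func:`center_measure_matrix` before fitting;
    A = X_c S^+ via lstsq.
    """
    X = mm.values if isinstance(mm, MeasureMatrix) else np.asarray(mm, dtype=float)
    S = np.asarray(sources, dtype=float)
    if X.shape[1] != S.shape[1]:
        raise ValidationError(
            f"measure matrix has {X.shape[1]} voxels, sources have {S.shape[1]}"
        )
    Xc = center_measure_matrix(X)
    coef, _, rank, _ = np.linalg.lstsq(S.T, Xc.T, rcond=None)
    if rank < S.shape[0]:
        warnings.warn(
            "rank-deficient source matrix; pseudoinverse solution used",
            RuntimeWarning,
        )
    return coef.T


def zscore_and_sign_fix(
    sources: np.ndarray, mixing: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Z-score each source row and enforce the positive-skewness sign rule.

    Rows are standardized to mean 0 / sd 1 over the mask; the per-row scale
    is folded into the mixing columns so the joint product (after
    de-standardization) is unchanged.  Rows with negative skewness are
    flipped together with their mixing column — this makes "predominantly
    positive spatial map" an operational, deterministic convention.

    Returns ``(sources_z, mixing_adjusted, row_means, row_sds)``; the means
    and sds refer to the input rows (pre-flip).
    """
    S = np.asarray(sources, dtype=float)
    A = np.asarray(mixing, dtype=float)
    if A.shape[1] != S.shape[0]:
        raise ValidationError("mixing columns must match source rows")
    means = S.mean(axis=1)
    sds = S.std(axis=1)
    if np.any(sds == 0):
        bad = np.flatnonzero(sds == 0).tolist()
        raise DegenerateComponentError(f"degenerate component(s) {bad}: zero variance")
    Sz = (S - means[:, None]) / sds[:, None]
    Az = A * sds[None, :]
    flip = skew(Sz, axis=1) < 0
    Sz[flip] *= -1.0
    Az[:, flip] *= -1.0
    return Sz, Az, means, sds


# ---------------------------------------------------------------------------
# ICASSO
# ---------------------------------------------------------------------------


def _cluster_pooled_sources(
    pooled: np.ndarray, k: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Average-linkage clustering of pooled source estimates by |corr|.

    Returns (labels, iq per cluster, centrotype row index per cluster),
    clusters ordered by descending Iq (ties: smallest member index).
    """
    sim = np.abs(np.corrcoef(pooled))
    np.fill_diagonal(sim, 1.0)
    dist = np.clip(1.0 - sim, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="average")
    labels = fcluster(Z, t=k, criterion="maxclust") - 1

    iq = np.empty(k)
    centro = np.empty(k, dtype=int)
    for c in range(k):
        members = np.flatnonzero(labels == c)
        outside = np.flatnonzero(labels != c)
        block = sim[np.ix_(members, members)]
        if len(members) > 1:
            intra = (block.sum() - len(members)) / (len(members) * (len(members) - 1))
        else:
            intra = 1.0
        extra = sim[np.ix_(members, outside)].mean() if outside.size else 0.0
        iq[c] = intra - extra
        centro[c] = members[np.argmax(block.sum(axis=1))]
    order = np.lexsort((centro, -iq))
    return labels, iq[order], centro[order]


def run_icasso(
    mm: MeasureMatrix | np.ndarray,
    k: int,
    n_runs: int = 20,
    seed: int = 0,
    infomax_params: dict | None = None,
    order_estimate: OrderEstimate | None = None,
) -> DecompositionResult:
    """ICASSO stability-selected Infomax decomposition.

    ``n_runs`` Infomax runs from distinct random initializations (seeds
    ``seed + run``) on identically whitened data; the pooled k*n_runs source
    estimates are clustered by absolute correlation (average linkage) into k
    clusters.  Each cluster's quality index

        Iq = mean intra-cluster similarity - mean similarity to outside

    is near 1 for stable components.  The cluster centrotype (the estimate
    with maximal total intra-cluster similarity) becomes the component; the
    loadings are recovered by least-squares back-reconstruction onto the
    Z-scored, sign-fixed source maps.
    """
    if n_runs < 1:
        raise ValidationError("n_runs must be >= 1")
    params = dict(infomax_params or {})
    wh = pca_reduce(mm, k)
    runs = [
        infomax_unmix(wh.whitened, seed=seed + i, **params) for i in range(n_runs)
    ]
    pooled = np.vstack([r.sources for r in runs])

    if n_runs == 1:
        S = runs[0].sources
        iq = np.ones(k)
    else:
        labels, iq, centro = _cluster_pooled_sources(pooled, k)
        counts = np.bincount(labels, minlength=k)
        if (counts < n_runs / 2).any():
            warnings.warn(
                "unstable component: a cluster has fewer members than n_runs/2",
                RuntimeWarning,
            )
        S = pooled[centro]

    A_raw = back_reconstruct(mm, S)
    Sz, _, means, sds = zscore_and_sign_fix(S, A_raw)
    # final loadings are the least-squares fit onto the standardized maps
    A = back_reconstruct(mm, Sz)
    return DecompositionResult(
        k=k,
        mixing=A,
        sources_z=Sz,
        stability_iq=iq,
        runs=runs,
        whitening=wh,
        source_means=means,
        source_sds=sds,
        order_estimate=order_estimate,
    )


def decompose(
    mm: MeasureMatrix,
    k: int | str = "auto",
    n_runs: int = 20,
    seed: int = 0,
    max_k: int | None = None,
    mdl_decimation: int = 4,
    infomax_params: dict | None = None,
) -> DecompositionResult:
    """Full decomposition: MDL order selection (``k='auto'``) then ICASSO."""
    est = None
    if isinstance(k, str):
        if k != "auto":
            raise ValidationError(f"k must be an integer or 'auto', got {k!r}")
        est = estimate_order_mdl(mm, max_k=max_k, decimation=mdl_decimation)
        k = est.k_selected
    return run_icasso(
        mm, int(k), n_runs=n_runs, seed=seed, infomax_params=infomax_params,
        order_estimate=est,
    )


# ---------------------------------------------------------------------------
# recovery evaluation
# ---------------------------------------------------------------------------


def match_sources(
    true_sources: np.ndarray, est_sources: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Match estimated to true sources by maximum absolute correlation.

    Hungarian assignment on the |Pearson correlation| matrix; returns
    ``(true_idx, est_idx, matched_abs_corr)``.
    """
    kt = true_sources.shape[0]
    ke = est_sources.shape[0]
    corr = np.corrcoef(true_sources, est_sources)[:kt, kt:]
    cost = -np.abs(corr)
    rows, cols = linear_sum_assignment(cost)
    return rows, cols, np.abs(corr[rows, cols])
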