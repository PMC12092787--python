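"""Reproducible desk-scale benchmarks of the full pipeline.

Every function here regenerates its inputs from a seed and runs the
package's own estimators, so the reported numbers are always computed
fresh.  They back both the validation suite and ``scripts/acceptance.py``:

* :func:`demographics_table_tests` — pooled two-sample t-tests recomputed
  from the published cohort summary statistics (means/SDs at n = 20/20);
* :func:`source_recovery_benchmark` — ground-truth source recovery and MDL
  order selection across seeded replicates of the study-scale design;
* :func:`null_calibration_benchmark` — family-wise rate of spurious
  FDR-significant components under a global-null design;
* :func:`oracle_deviations` — numerical agreement of the statistical
  primitives with brute-force reference computations;
* :func:`direction_rule_accuracy` — exhaustive check of the sign rule.
"""

from __future__ import annotations

import numpy as np

from .correlation import partial_correlation
from .decomposition import (
    center_measure_matrix,
    estimate_order_mdl,
    match_sources,
    run_icasso,
)
from .group_stats import (
    GREATER,
    LOWER,
    analyze_components,
    fdr_adjust,
    interpret_direction,
    ttest_from_summary,
)
from .io_volumes import build_mask, vectorize
from .synthetic_data import SyntheticConfig, synthesize_dataset

#: published cohort rows reproduced from summary statistics:
#: (patient mean, sd), (control mean, sd), both n = 20
TABLE1_ROWS = {
    "age": ((46.4, 12.5), (42.1, 12.5)),
    "PCS": ((27.6, 12.5), (12.0, 10.9)),
    "magnification": ((5.3, 3.8), (2.6, 2.6)),
    "rumination": ((9.3, 4.6), (4.5, 4.2)),
}


def demographics_table_tests() -> dict[str, dict[str, float]]:
    """Pooled two-sample t-tests from the cohort's printed means/SDs."""
    out = {}
    for name, ((m1, s1), (m2, s2)) in TABLE1_ROWS.items():
        t, df, p = ttest_from_summary(m1, s1, 20, m2, s2, 20)
        out[name] = {"t": t, "df": df, "p": p}
    return out


def _study_scale_config(seed: int) -> SyntheticConfig:
    """The study-scale synthetic design: 20/20 subjects, 4 sources, one of
    them shifted by 1.5 loading-sd in patients, 24x28x24 grid at 3 mm."""
    return SyntheticConfig(
        k_true=4,
        group_effect=(0.0, 0.0, 0.0, 1.5),
        noise_sd=0.05,
        n_patients=20,
        n_controls=20,
        seed=seed,
    )


def source_recovery_benchmark(
    n_seeds: int = 20, n_runs: int = 5, base_seed: int = 1
) -> dict:
    """Recovery of ground-truth sources and of the model order.

    For each master seed: generate the study-scale dataset, select the
    order by MDL, decompose at the true order with ICASSO, and score the
    Hungarian-matched mean |correlation| between true and estimated source
    maps.  Returns per-seed values plus the across-seed mean correlation
    and the fraction of seeds where MDL selects the true order (4).
    """
    corrs, mdl_hits = [], 0
    for i in range(n_seeds):
        seed = base_seed * 1000 + i
        cfg = _study_scale_config(seed)
        vs, _, gt = synthesize_dataset(cfg)
        mm = vectorize(vs, build_mask(vs))
        est = estimate_order_mdl(mm, max_k=10)
        mdl_hits += est.k_selected == cfg.k_true
        res = run_icasso(mm, cfg.k_true, n_runs=n_runs, seed=seed)
        _, _, matched = match_sources(
            gt.true_sources[:, mm.mask.linear_index], res.sources_z
        )
        corrs.append(float(matched.mean()))
    return {
        "mean_abs_corr": float(np.mean(corrs)),
        "min_abs_corr": float(np.min(corrs)),
        "per_seed_corr": corrs,
        "mdl_correct_rate": mdl_hits / n_seeds,
        "n_seeds": n_seeds,
    }


def null_calibration_benchmark(
    n_replicates: int = 500, base_seed: int = 1
) -> dict:
    """Family-wise false-positive rate under the global null.

    Each replicate: a 16x16x16 design with four sources, no group effect
    and no clinical link, decomposed at k = 4 (single Infomax run — the
    stability repetition does not change the null distribution of the
    loading t-tests) and tested with age/TIV-adjusted loading t-tests plus
    BH at q = 0.05.  Reports the fraction of replicates with at least one
    significant component.
    """
    any_sig = 0
    for i in range(n_replicates):
        seed = base_seed * 10000 + i
        cfg = SyntheticConfig(
            grid_shape=(16, 16, 16),
            blob_sigma_mm=4.5,
            k_true=4,
            group_effect=(0.0, 0.0, 0.0, 0.0),
            clinical_link=None,
            seed=seed,
        )
        vs, table, _ = synthesize_dataset(cfg)
        mm = vectorize(vs, build_mask(vs))
        res = run_icasso(mm, 4, n_runs=1, seed=seed)
        C = table[["age", "tiv"]].to_numpy(dtype=float)
        stats = analyze_components(res.mixing, table["group"].to_numpy(), C, q=0.05)
        any_sig += bool(stats["significant"].any())
    return {
        "any_significant_rate": any_sig / n_replicates,
        "n_replicates": n_replicates,
    }


def oracle_deviations(seed: int = 1) -> dict:
    """Numerical agreement of the primitives with brute-force references.

    Returns maximum absolute deviations for: partial correlation vs
    residualize-then-Pearson, BH adjustment vs the hand step-up on the
    4-element example, back-reconstruction residual vs the discarded-PCA
    bound, and Z-map standardization.
    """
    rng = np.random.default_rng(seed)

    # partial correlation vs explicit residual Pearson
    x, y, c = rng.standard_normal((3, 30))
    X = np.column_stack([np.ones(30), c])
    rx = x - X @ np.linalg.solve(X.T @ X, X.T @ x)
    ry = y - X @ np.linalg.solve(X.T @ X, X.T @ y)
    r_ref = float((rx @ ry) / np.sqrt((rx @ rx) * (ry @ ry)))
    r_got = partial_correlation(x, y, c).r
    partial_dev = abs(r_got - r_ref)

    # BH step-up vs the hand-computed 4-element example
    adj, _ = fdr_adjust([0.01, 0.02, 0.03, 0.04])
    bh_dev = float(np.max(np.abs(adj - np.array([0.04, 0.04, 0.04, 0.04]))))

    # decomposition invariants on one study-scale dataset
    cfg = _study_scale_config(seed)
    vs, _, _ = synthesize_dataset(cfg)
    mm = vectorize(vs, build_mask(vs))
    res = run_icasso(mm, 4, n_runs=2, seed=seed)
    Xc = center_measure_matrix(mm.values)
    rel_resid = (
        np.linalg.norm(Xc - res.mixing @ res.sources_z) ** 2
        / np.linalg.norm(Xc) ** 2
    )
    discarded = 1.0 - res.whitening.retained_variance
    recon_margin = float(rel_resid - discarded)  # <= ~0 up to round-off

    zmean_dev = float(np.abs(res.sources_z.mean(axis=1)).max())
    zsd_dev = float(np.abs(res.sources_z.std(axis=1) - 1.0).max())

    return {
        "partial_corr_dev": float(partial_dev),
        "bh_adjust_dev": bh_dev,
        "reconstruction_margin": recon_margin,
        "zscore_mean_dev": zmean_dev,
        "zscore_sd_dev": zsd_dev,
    }


def direction_rule_accuracy() -> float:
    """Fraction of the four (t, Z) sign combinations labelled correctly."""
    expected = {
        (1, 1): GREATER,
        (1, -1): LOWER,
        (-1, 1): LOWER,
        (-1, -1): GREATER,
    }
    hits = sum(
        interpret_direction(t, z) == lab for (t, z), lab in expected.items()
    )
    return hits / len(expected)
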