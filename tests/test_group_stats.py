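"""Covariate adjustment, loading t-tests, FDR, thresholding, direction rule."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import sbmorph as sm
from sbmorph.exceptions import ValidationError
from sbmorph.group_stats import GREATER, LOWER, clusters_to_frame


class TestRegressOut:
    def test_residuals_orthogonal_to_covariates(self):
        rng = np.random.default_rng(0)
        age = rng.uniform(25, 60, 40)
        y = 3.0 * age + rng.standard_normal(40)
        resid = sm.regress_out_covariates(y, age)
        r = np.corrcoef(resid, age)[0, 1]
        assert abs(r) < 1e-10

    def test_zero_variance_covariate_rejected(self):
        y = np.arange(10.0)
        with pytest.raises(ValidationError, match="collinear"):
            sm.regress_out_covariates(y, np.full(10, 2.0))

    def test_matches_normal_equations_oracle(self):
        """n=5 hand example: residuals equal the brute-force normal-equation fit."""
        y = np.array([2.0, 4.1, 5.9, 8.2, 9.8])
        C = np.array([[1.0, 0.5], [2.0, 0.1], [3.0, 0.9], [4.0, 0.4], [5.0, 0.7]])
        X = np.column_stack([np.ones(5), C])
        beta = np.linalg.solve(X.T @ X, X.T @ y)  # normal equations, independent route
        expected = y - X @ beta
        got = sm.regress_out_covariates(y, C)
        np.testing.assert_allclose(got, expected, atol=1e-12)


class TestComponentGroupTest:
    def test_identical_groups_give_null(self):
        vals = np.tile(np.arange(10.0), 2)
        groups = np.array(["patient"] * 10 + ["control"] * 10)
        t, p = sm.component_group_test(vals, groups)
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_closed_form_pooled_t_without_covariates(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(20) + 0.8
        y = rng.standard_normal(20)
        groups = np.array(["patient"] * 20 + ["control"] * 20)
        t, p = sm.component_group_test(np.concatenate([x, y]), groups)
        t_ref, df_ref, p_ref = sm.ttest_from_summary(
            x.mean(), x.std(ddof=1), 20, y.mean(), y.std(ddof=1), 20
        )
        assert abs(t - t_ref) < 1e-10
        assert abs(p - p_ref) < 1e-10

    def test_sign_convention_patient_minus_control(self):
        groups = np.array(["patient"] * 5 + ["control"] * 5)
        high_patients = np.array([3.0, 3.1, 2.9, 3.2, 3.0, 1.0, 1.1, 0.9, 1.2, 1.0])
        t, _ = sm.component_group_test(high_patients, groups)
        assert t > 0

    def test_power_under_two_sd_shift(self):
        """Patient shift of 2 loading-sd at n=20/20: rejection rate >= 0.99."""
        rejected, n_seeds = 0, 500
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            vals = np.concatenate(
                [rng.normal(2.0, 1.0, 20), rng.normal(0.0, 1.0, 20)]
            )
            groups = np.array(["patient"] * 20 + ["control"] * 20)
            _, p = sm.component_group_test(vals, groups)
            rejected += p < 0.05
        assert rejected / n_seeds >= 0.99

    def test_covariate_adjustment_removes_confounded_effect(self):
        rng = np.random.default_rng(3)
        groups = np.array(["patient"] * 20 + ["control"] * 20)
        age = np.concatenate([rng.uniform(45, 60, 20), rng.uniform(25, 40, 20)])
        vals = 0.1 * age + rng.normal(0, 0.1, 40)  # pure age effect
        t_raw, p_raw = sm.component_group_test(vals, groups)
        t_adj, p_adj = sm.component_group_test(vals, groups, covariates=age)
        assert p_raw < 0.01
        assert abs(t_adj) < abs(t_raw)

    def test_subject_permutation_invariance(self):
        rng = np.random.default_rng(4)
        vals = rng.standard_normal(40)
        groups = np.array(["patient"] * 20 + ["control"] * 20)
        cov = rng.uniform(25, 60, 40)
        t1, p1 = sm.component_group_test(vals, groups, cov)
        perm = rng.permutation(40)
        t2, p2 = sm.component_group_test(vals[perm], groups[perm], cov[perm])
        assert t1 == pytest.approx(t2, abs=1e-10)
        assert p1 == pytest.approx(p2, abs=1e-10)


class TestFdr:
    def test_single_pvalue_unchanged(self):
        adj, rej = sm.fdr_adjust([0.03], q=0.05)
        assert adj[0] == pytest.approx(0.03)
        assert rej[0]

    def test_hand_computed_step_up_example(self):
        """BH on [0.01, 0.02, 0.03, 0.04]: adj_i = min_j>=i p_j m / j = 0.04."""
        adj, rej = sm.fdr_adjust([0.01, 0.02, 0.03, 0.04], q=0.05)
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.04], atol=1e-12)
        assert rej.all()

    def test_out_of_range_pvalue_rejected(self):
        with pytest.raises(ValidationError):
            sm.fdr_adjust([0.5, 1.2])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=12))
    def test_adjusted_values_monotone_in_sorted_order(self, pvals):
        adj, _ = sm.fdr_adjust(pvals)
        order = np.argsort(pvals, kind="stable")
        assert (np.diff(adj[order]) >= -1e-12).all()
        assert (adj >= np.asarray(pvals) - 1e-12).all()


class TestThreshold:
    def _mask(self, shape=(4, 4, 4)):
        return sm.BrainMask(np.ones(shape, dtype=bool))

    def test_zero_map_has_no_clusters(self):
        mask = self._mask()
        out = sm.threshold_components(np.zeros((1, 64)), mask, np.eye(4))
        assert out == []

    def test_single_blob_found_by_flood_fill_oracle(self):
        """A 5-voxel Z=4 blob yields one positive cluster of size 5."""
        mask = self._mask()
        vol = np.zeros((4, 4, 4))
        blob = [(1, 1, 1), (2, 1, 1), (1, 2, 1), (1, 1, 2), (2, 2, 2)]
        for ijk in blob:
            vol[ijk] = 4.0
        flat = vol.ravel(order="F")
        clusters = sm.threshold_components(flat[None, :], mask, np.eye(4), 3.0)
        assert len(clusters) == 1
        c = clusters[0]
        assert c.sign == "positive" and c.size == 5
        # oracle: exhaustive flood fill over 26-neighbourhoods
        seen, stack, comp = set(), [blob[0]], set()
        blob_set = set(blob)
        while stack:
            v = stack.pop()
            if v in seen:
                continue
            seen.add(v)
            comp.add(v)
            for dx in (-1, 0, 1):
                for dy in (-1, 0, 1):
                    for dz in (-1, 0, 1):
                        w = (v[0] + dx, v[1] + dy, v[2] + dz)
                        if w in blob_set and w not in seen:
                            stack.append(w)
        assert len(comp) == c.size == 5

    def test_signs_split_into_separate_clusters(self):
        mask = self._mask()
        vol = np.zeros((4, 4, 4))
        vol[0, 0, 0] = 5.0
        vol[3, 3, 3] = -5.0
        clusters = sm.threshold_components(vol.ravel(order="F")[None], mask, np.eye(4))
        assert {c.sign for c in clusters} == {"positive", "negative"}

    def test_peak_world_coordinates_use_affine(self):
        mask = self._mask()
        vol = np.zeros((4, 4, 4))
        vol[2, 1, 3] = 4.5
        affine = np.diag([3.0, 3.0, 3.0, 1.0])
        affine[:3, 3] = [-10.0, -20.0, -30.0]
        (c,) = sm.threshold_components(vol.ravel(order="F")[None], mask, affine)
        assert c.peak_mm == (2 * 3.0 - 10.0, 1 * 3.0 - 20.0, 3 * 3.0 - 30.0)

    def test_default_threshold_is_three(self):
        import inspect

        sig = inspect.signature(sm.threshold_components)
        assert sig.parameters["z_threshold"].default == 3.0


class TestDirectionRule:
    @pytest.mark.parametrize(
        "t_sign, z_sign, expected",
        [
            (1, 1, GREATER),   # higher patient loadings, positive map
            (1, -1, LOWER),    # higher patient loadings, negative map
            (-1, 1, LOWER),    # lower patient loadings, positive map
            (-1, -1, GREATER), # double negative
        ],
    )
    def test_all_sign_combinations(self, t_sign, z_sign, expected):
        assert sm.interpret_direction(t_sign, z_sign) == expected

    def test_zero_sign_ambiguous(self):
        with pytest.raises(ValidationError, match="ambiguous"):
            sm.interpret_direction(0, 1)


class TestSummaryTtest:
    def test_age_row_reproduces_printed_pvalue(self):
        t, df, p = sm.ttest_from_summary(46.4, 12.5, 20, 42.1, 12.5, 20)
        assert df == 38
        assert round(p, 2) == 0.28

    def test_catastrophizing_rows_respect_printed_bounds(self):
        _, _, p_pcs = sm.ttest_from_summary(27.6, 12.5, 20, 12.0, 10.9, 20)
        _, _, p_mag = sm.ttest_from_summary(5.3, 3.8, 20, 2.6, 2.6, 20)
        _, _, p_rum = sm.ttest_from_summary(9.3, 4.6, 20, 4.5, 4.2, 20)
        assert p_pcs < 0.001
        assert p_mag < 0.02
        assert p_rum < 0.002

    def test_degenerate_equal_groups(self):
        t, df, p = sm.ttest_from_summary(5.0, 0.0, 10, 5.0, 0.0, 10)
        assert (t, p) == (0.0, 1.0)


class TestAnalyzeComponents:
    def test_fdr_and_flags_consistent(self, decomposition, dataset):
        vs, table, gt = dataset
        C = table[["age", "tiv"]].to_numpy(dtype=float)
        df = sm.analyze_components(
            decomposition.mixing, table["group"].to_numpy(), C
        )
        assert (df["p_fdr"] >= df["p"] - 1e-15).all()
        assert (df["significant"] == (df["p_fdr"] < 0.05)).all()

    def test_shifted_source_detected(self, decomposition, dataset, measure):
        """The group-shifted source is the one significant component, and its
        direction matches the sign rule."""
        vs, table, gt = dataset
        C = table[["age", "tiv"]].to_numpy(dtype=float)
        df = sm.analyze_components(
            decomposition.mixing, table["group"].to_numpy(), C
        )
        ti, ei, _ = sm.match_sources(
            gt.true_sources[:, measure.mask.linear_index], decomposition.sources_z
        )
        shifted_est = int(ei[list(ti).index(3)])  # estimated idx of true source 4
        sig = df.loc[df["significant"], "component"].tolist()
        assert sig == [shifted_est + 1]
        assert df.loc[df["component"] == shifted_est + 1, "t"].abs().iloc[0] > 4

    def test_cluster_frame_schema(self, decomposition, measure, dataset):
        clusters = sm.threshold_components(
            decomposition.sources_z, measure.mask, measure.affine, 3.0
        )
        frame = clusters_to_frame(clusters)
        assert list(frame.columns) == [
            "component", "sign", "size", "peak_z",
            "x_mm", "y_mm", "z_mm", "direction", "label",
        ]
        assert (frame["size"] >= 1).all()
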