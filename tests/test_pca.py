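"""PCA decomposition, marker selection and differential-correlation classes."""

import numpy as np
import pytest

from immunosig import pca as P
from immunosig.panels import FeatureMatrix, standardize
from immunosig.pca import (
    CorrelationMatrix,
    compare_signatures,
    correlation_heatmap,
    group_signature_analysis,
    marker_component_correlations,
    select_markers,
    variance_explained,
)
from immunosig.synthetic import simulate_correlation_pair


def _std(X, labels=None, names=None):
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    fm = FeatureMatrix(
        "SPL", "pca_variables",
        list(names) if names else [f"v{j}" for j in range(p)],
        [f"M{i}" for i in range(n)], X,
        np.asarray(labels if labels is not None else np.zeros(n), dtype=int),
        np.array(["F"] * n, dtype=object),
    )
    return standardize(fm)


def _pearson_two_pass(x, y):
    """Textbook two-pass Pearson correlation."""
    mx, my = sum(x) / len(x), sum(y) / len(y)
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / (sxx * syy) ** 0.5


class TestPCA:
    def test_eigenvalues_match_dense_eigendecomposition(self):
        rng = np.random.default_rng(0)
        std = _std(rng.normal(size=(12, 8)))
        res = P.pca(std)
        C = np.cov(std.values, rowvar=False)
        oracle = np.sort(np.linalg.eigvalsh(C))[::-1][: res.n_components]
        np.testing.assert_allclose(res.eigenvalues, oracle, atol=1e-8)

    def test_matches_sklearn_pca_oracle(self):
        from sklearn.decomposition import PCA as SkPCA

        rng = np.random.default_rng(42)
        std = _std(rng.normal(size=(25, 7)))
        res = P.pca(std)
        sk = SkPCA().fit(std.values)
        np.testing.assert_allclose(res.eigenvalues, sk.explained_variance_, atol=1e-10)
        np.testing.assert_allclose(res.variance_fraction,
                                   sk.explained_variance_ratio_, atol=1e-10)
        # loadings agree up to the per-component sign convention
        for k in range(res.n_components):
            a, b = res.loadings[:, k], sk.components_[k]
            assert min(np.abs(a - b).max(), np.abs(a + b).max()) < 1e-9

    def test_loadings_orthonormal_and_descending(self):
        rng = np.random.default_rng(1)
        res = P.pca(_std(rng.normal(size=(15, 6))))
        np.testing.assert_allclose(res.loadings.T @ res.loadings,
                                   np.eye(res.n_components), atol=1e-9)
        assert np.all(np.diff(res.eigenvalues) <= 1e-12)

    def test_variance_fractions_sum_to_one(self):
        rng = np.random.default_rng(2)
        res = P.pca(_std(rng.normal(size=(10, 5))))
        assert res.variance_fraction.sum() == pytest.approx(1.0, abs=1e-9)

    def test_full_reconstruction(self):
        rng = np.random.default_rng(3)
        std = _std(rng.normal(size=(20, 7)))
        res = P.pca(std)
        np.testing.assert_allclose(res.scores @ res.loadings.T, std.values, atol=1e-8)

    def test_two_perfectly_correlated_variables_are_rank_one(self):
        x = np.random.default_rng(4).normal(size=10)
        with pytest.warns(UserWarning, match="rank"):
            res = P.pca(_std(np.column_stack([x, 2 * x + 1])))
        assert res.variance_fraction[0] == pytest.approx(1.0, abs=1e-12)

    def test_sign_convention_largest_loading_positive(self):
        rng = np.random.default_rng(5)
        res = P.pca(_std(rng.normal(size=(30, 6))))
        for k in range(res.n_components):
            col = res.loadings[:, k]
            assert col[np.abs(col).argmax()] > 0

    def test_rank_deficiency_warns_when_variables_exceed_samples(self):
        rng = np.random.default_rng(6)
        with pytest.warns(UserWarning, match="rank deficiency"):
            res = P.pca(_std(rng.normal(size=(11, 30))))
        assert res.n_components <= 10

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            # bypass standardize's own minimum by constructing directly
            std = _std(np.random.default_rng(7).normal(size=(4, 3)))
            std.values = std.values[:2]
            P.pca(std)

    def test_variance_fraction_invariant_under_column_permutation(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(14, 6)) @ rng.normal(size=(6, 6))
        res1 = P.pca(_std(X))
        res2 = P.pca(_std(X[:, ::-1]))
        np.testing.assert_allclose(res1.variance_fraction, res2.variance_fraction,
                                   atol=1e-10)


class TestVarianceExplained:
    def test_all_components_give_one(self):
        res = P.pca(_std(np.random.default_rng(9).normal(size=(12, 5))))
        assert variance_explained(res, res.n_components) == pytest.approx(1.0)

    def test_rank_two_data_k2_gives_one(self):
        rng = np.random.default_rng(10)
        f = rng.normal(size=(20, 2))
        X = f @ rng.normal(size=(2, 6))
        with pytest.warns(UserWarning):
            res = P.pca(_std(X))
        assert variance_explained(res, 2) == pytest.approx(1.0, abs=1e-9)

    def test_planted_spectrum_recovered(self):
        """Cumulative fraction of 4-factor data matches the planted spectrum."""
        rng = np.random.default_rng(11)
        n, p = 4000, 10
        sd = np.array([4.0, 3.0, 2.0, 1.0])
        F = rng.normal(size=(n, 4)) * sd
        W = np.linalg.qr(rng.normal(size=(p, 4)))[0]
        X = F @ W.T + rng.normal(0, 0.3, size=(n, p))
        # expected cumulative variance over total (incl. isotropic noise)
        total = (sd**2).sum() + 0.3**2 * p
        planted = ((sd**2) + 0.3**2).cumsum()[-1] / total
        fm = FeatureMatrix("SPL", "pca_variables", [f"v{j}" for j in range(p)],
                           [f"M{i}" for i in range(n)], X,
                           np.zeros(n, dtype=int), np.array(["F"] * n, dtype=object))
        res = P.pca(standardize_raw(fm))
        assert variance_explained(res, 4) == pytest.approx(planted, abs=0.02)

    def test_k_out_of_range(self):
        res = P.pca(_std(np.random.default_rng(12).normal(size=(8, 4))))
        with pytest.raises(ValueError):
            variance_explained(res, res.n_components + 1)


def standardize_raw(fm):
    """Center only (no variance rescaling is needed: test uses raw covariance scale)."""
    from immunosig.panels import StandardizedMatrix

    X = fm.values
    means = X.mean(axis=0)
    return StandardizedMatrix(
        tissue=fm.tissue, variable_set=fm.variable_set, variables=fm.variables,
        rows=fm.rows, values=X - means, labels=fm.labels, sex=fm.sex,
        means=means, sds=np.ones(X.shape[1]),
    )


class TestMarkerCorrelations:
    def test_closed_form_identity(self):
        rng = np.random.default_rng(13)
        std = _std(rng.normal(size=(25, 6)))
        res = P.pca(std)
        r = marker_component_correlations(res, std)
        np.testing.assert_allclose(r, res.loadings * np.sqrt(res.eigenvalues),
                                   atol=1e-9)
        assert np.nanmax(np.abs(r)) <= 1.0 + 1e-12

    def test_variable_equal_to_pc1_score_has_unit_correlation(self):
        rng = np.random.default_rng(14)
        base = rng.normal(size=(30, 4))
        res0 = P.pca(_std(base))
        X = np.column_stack([base, res0.scores[:, 0]])
        std = _std(X)
        with pytest.warns(UserWarning, match="rank"):  # collinear by design
            res = P.pca(std)
        r = marker_component_correlations(res, std)
        assert abs(r[4, 0]) == pytest.approx(1.0, abs=1e-9)
        sel = select_markers(r, std.variables, scope="first_component")
        assert "v4" in sel.markers


class TestSelectMarkers:
    def test_planted_block_fully_selected(self):
        """Three variables sharing a factor (pairwise r≈0.95) all pass |r|>0.8."""
        rng = np.random.default_rng(15)
        n = 200
        f = rng.normal(size=n)
        noise_sd = np.sqrt(1 / 0.95 - 1)  # gives pairwise r ≈ 0.95
        block = np.column_stack([f + rng.normal(0, noise_sd, n) for _ in range(3)])
        indep = rng.normal(size=(n, 12))
        std = _std(np.hstack([block, indep]))
        res = P.pca(std)
        r = marker_component_correlations(res, std)
        sel = select_markers(r, std.variables, scope="first_component", threshold=0.8)
        assert {"v0", "v1", "v2"} <= set(sel.markers)
        assert all(abs(rv) > 0.8 for _, _, rv in sel.selected)

    def test_impossible_threshold_gives_empty_selection_with_warning(self):
        rng = np.random.default_rng(16)
        std = _std(rng.normal(size=(20, 5)))
        res = P.pca(std)
        r = marker_component_correlations(res, std)
        with pytest.warns(UserWarning, match="no marker"):
            sel = select_markers(r, std.variables, threshold=1.0)
        assert sel.selected == []

    def test_first_four_scope_widens_selection(self):
        rng = np.random.default_rng(17)
        std = _std(rng.normal(size=(10, 8)))
        res = P.pca(std)
        r = marker_component_correlations(res, std)
        s1 = select_markers(r, std.variables, scope="first_component", threshold=0.5)
        s4 = select_markers(r, std.variables, scope="first_four", threshold=0.5)
        assert set(s1.markers) <= set(s4.markers)


class TestCorrelationHeatmap:
    def test_unit_diagonal(self):
        rng = np.random.default_rng(18)
        h = correlation_heatmap(rng.normal(size=(10, 5)), list("abcde"))
        np.testing.assert_allclose(np.diag(h.r), 1.0)
        np.testing.assert_allclose(h.r, h.r.T, atol=1e-12)

    def test_constructed_anticorrelated_pair(self):
        rng = np.random.default_rng(19)
        x = rng.normal(size=50)
        h = correlation_heatmap(np.column_stack([x, -x + rng.normal(0, 1e-3, 50)]),
                                ["a", "b"])
        assert h.r[0, 1] < -0.99

    def test_matches_two_pass_pearson_oracle(self):
        rng = np.random.default_rng(20)
        X = rng.normal(size=(10, 5))
        h = correlation_heatmap(X, list("abcde"))
        for i in range(5):
            for j in range(i + 1, 5):
                assert h.r[i, j] == pytest.approx(
                    _pearson_two_pass(X[:, i], X[:, j]), abs=1e-12)

    def test_constant_marker_flagged_undefined(self):
        X = np.column_stack([np.ones(10), np.random.default_rng(21).normal(size=10)])
        h = correlation_heatmap(X, ["const", "x"])
        assert np.isnan(h.r[0, 1])


class TestCompareSignatures:
    def _table(self, rc, ri):
        c = CorrelationMatrix(["a", "b"], np.array([[1.0, rc], [rc, 1.0]]))
        i = CorrelationMatrix(["a", "b"], np.array([[1.0, ri], [ri, 1.0]]))
        return compare_signatures(c, i)

    @pytest.mark.parametrize("rc, ri, expected", [
        (0.9, -0.9, "inverted"),
        (-0.6, 0.3, "inverted"),
        (0.9, 0.05, "lost"),
        (-0.7, 0.1, "lost"),
        (0.05, 0.9, "gained"),
        (0.1, 0.1, "neutral"),
        (-0.15, 0.18, "neutral"),
        (0.9, 0.85, "retained"),
        (0.4, 0.1, "retained"),  # not strong enough in control to count as lost
    ])
    def test_classification_bands(self, rc, ri, expected):
        assert self._table(rc, ri).rows[0][3] == expected

    def test_antisymmetry_under_group_swap(self):
        rng = np.random.default_rng(22)
        swap = {"lost": "gained", "gained": "lost"}
        for _ in range(200):
            rc, ri = rng.uniform(-1, 1, 2)
            fwd = self._table(rc, ri).rows[0][3]
            rev = self._table(ri, rc).rows[0][3]
            assert rev == swap.get(fwd, fwd)

    def test_marker_set_mismatch(self):
        c = CorrelationMatrix(["a", "b"], np.eye(2))
        i = CorrelationMatrix(["a", "c"], np.eye(2))
        with pytest.raises(ValueError):
            compare_signatures(c, i)

    def test_planted_sign_flip_detected(self):
        ctrl, imm = simulate_correlation_pair(0.7, -0.7, 100, seed=23)
        table = compare_signatures(correlation_heatmap(ctrl, ["a", "b"]),
                                   correlation_heatmap(imm, ["a", "b"]))
        assert table.rows[0][3] == "inverted"


class TestGroupWorkflow:
    def test_group_pca_overlaps_global_on_single_factor_data(self):
        """With one common factor the global PC1 markers reappear per group."""
        rng = np.random.default_rng(24)
        n = 60
        f = rng.normal(size=n)
        X = np.column_stack([f + rng.normal(0, 0.3, n) for _ in range(4)]
                            + [rng.normal(size=n) for _ in range(4)])
        labels = np.repeat([0, 1], n // 2)
        std_all = _std(X, labels)
        res = P.pca(std_all)
        r = marker_component_correlations(res, std_all)
        global_sel = set(select_markers(r, std_all.variables).markers)
        per_group = set()
        for g in (0, 1):
            stdg = _std(X[labels == g])
            resg = P.pca(stdg)
            rg = marker_component_correlations(resg, stdg)
            per_group |= set(select_markers(rg, stdg.variables).markers)
        assert global_sel and global_sel <= per_group

    def test_full_signature_workflow_runs(self, default_cohort):
        import warnings
        from immunosig.panels import build_feature_matrix, standardize

        fm = build_feature_matrix(default_cohort, "SPL", "pca_variables")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            std_c = standardize(fm.subset(fm.labels == 0))
            std_i = standardize(fm.subset(fm.labels == 1))
            sel_c, sel_i, heat_c, heat_i, table = group_signature_analysis(std_c, std_i)
        assert sel_c.group == "control"
        if sel_c.markers:
            assert heat_c.variables == sel_c.markers
            assert len(table.rows) == len(sel_c.markers) * (len(sel_c.markers) - 1) // 2
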