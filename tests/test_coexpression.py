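import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from regumine.coexpression import (
    CorrelationResult,
    bin_density_diagnostic,
    coexpression_pipeline,
    correlation_with_pvalues,
    critical_pcc,
    filter_low_expression,
    normalize_transform,
    remove_pc1,
    spatial_quantile_normalize,
    tmm_factors,
)


def _counts(matrix, genes=None, samples=None):
    matrix = np.asarray(matrix)
    genes = genes or [f"g{i}" for i in range(matrix.shape[0])]
    samples = samples or [f"s{j}" for j in range(matrix.shape[1])]
    return pd.DataFrame(matrix, index=genes, columns=samples)


class TestFilter:
    def test_boundary_gene_kept_at_exactly_half(self):
        counts = _counts([[5, 5, 0, 0], [9, 9, 9, 9]])
        kept = filter_low_expression(counts, min_count=5, min_fraction=0.5)
        assert "g0" in kept.index

    def test_gene_below_min_count_everywhere_removed(self):
        counts = _counts([[4, 4, 4, 4], [9, 9, 9, 9]])
        kept = filter_low_expression(counts)
        assert list(kept.index) == ["g1"]

    def test_all_zero_gene_removed_and_empty_result_errors(self):
        counts = _counts([[0, 0, 0, 0], [9, 9, 9, 9]])
        assert "g0" not in filter_low_expression(counts).index
        with pytest.raises(ValueError):
            filter_low_expression(_counts([[0, 0], [1, 1]]))


def _reference_tmm(counts, trim_m=0.30, trim_a=0.05):
    """Independent step-by-step TMM computation used as oracle."""
    mat = counts.to_numpy(float)
    lib = mat.sum(axis=0)
    uq = np.array([np.quantile(c[c > 0] / n, 0.75) for c, n in zip(mat.T, lib)])
    ref = int(np.argmin(np.abs(uq - uq.mean())))
    logf = []
    for j in range(mat.shape[1]):
        if j == ref:
            logf.append(0.0)
            continue
        yk, yr = mat[:, j], mat[:, ref]
        keep = (yk > 0) & (yr > 0)
        pk, pr = yk[keep] / lib[j], yr[keep] / lib[ref]
        m = np.log2(pk / pr)
        a = 0.5 * np.log2(pk * pr)
        w = 1.0 / (
            (lib[j] - yk[keep]) / (lib[j] * yk[keep])
            + (lib[ref] - yr[keep]) / (lib[ref] * yr[keep])
        )
        n = len(m)
        lo_m = math.floor(n * trim_m) + 1
        hi_m = n + 1 - lo_m
        lo_a = math.floor(n * trim_a) + 1
        hi_a = n + 1 - lo_a
        rm = scipy.stats.rankdata(m)
        ra = scipy.stats.rankdata(a)
        sel = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
        logf.append(float((w[sel] * m[sel]).sum() / w[sel].sum()))
    logf = np.array(logf) - np.mean(logf)
    return 2.0 ** logf


class TestTMM:
    def test_identical_columns_give_unit_factors(self):
        counts = _counts(np.tile([[10], [200], [35], [7]], (1, 4)))
        assert np.allclose(tmm_factors(counts), 1.0)

    def test_pure_depth_change_gives_unit_factors(self):
        col = np.array([10, 200, 35, 7, 90])
        counts = _counts(np.column_stack([col, 3 * col, col]))
        assert np.allclose(tmm_factors(counts), 1.0)

    def test_contaminant_gene_matches_independent_reference(self):
        rng = np.random.default_rng(0)
        base = rng.poisson(100, size=(40, 4)).astype(float)
        base[0, 2] = 20_000  # one dominant contaminant in sample 2
        counts = _counts(base)
        got = tmm_factors(counts).to_numpy()
        expected = _reference_tmm(counts)
        assert np.allclose(got, expected, rtol=1e-10)

    def test_zero_total_sample_rejected(self):
        with pytest.raises(ValueError):
            tmm_factors(_counts([[0, 5], [0, 5]]))


class TestTransform:
    def test_zero_count_maps_to_zero(self):
        counts = _counts([[0, 0], [10, 10]])
        y = normalize_transform(counts, pd.Series([1.0, 1.0], index=counts.columns))
        assert np.allclose(y.loc["g0"], 0.0)

    def test_unit_value_closed_form(self):
        # one gene at CPM exactly 1: y = log2(1 + sqrt(2))
        counts = _counts([[1], [999_999]])
        y = normalize_transform(counts, pd.Series([1.0], index=counts.columns))
        assert y.loc["g0"].iloc[0] == pytest.approx(math.log2(1 + math.sqrt(2)))

    def test_large_values_approach_log2_of_twice_x(self):
        counts = _counts([[500_000], [500_000]])
        y = normalize_transform(counts, pd.Series([1.0], index=counts.columns))
        x = 500_000.0
        assert y.iloc[0, 0] == pytest.approx(math.log2(2 * x), abs=1e-6)


class TestRemovePC1:
    def test_rank_one_matrix_fully_annihilated(self):
        u = np.array([1.0, -2.0, 0.5, 3.0])
        v = np.array([0.3, -1.0, 2.0, 0.7, -0.5])
        x = pd.DataFrame(np.outer(u, v))
        resid = remove_pc1(x)
        centered = resid.to_numpy() - resid.to_numpy().mean(axis=1, keepdims=True)
        assert np.allclose(centered, 0.0, atol=1e-10)

    def test_injected_dominant_factor_removed(self):
        rng = np.random.default_rng(1)
        factor = rng.normal(size=30)
        loadings = rng.normal(size=50) * 3
        x = pd.DataFrame(np.outer(loadings, factor) + rng.normal(scale=0.1, size=(50, 30)))
        resid = remove_pc1(x)
        cors = [np.corrcoef(row, factor)[0, 1] for row in resid.to_numpy()]
        assert np.median(np.abs(cors)) < 0.1

    def test_total_variance_strictly_decreases(self):
        rng = np.random.default_rng(2)
        x = pd.DataFrame(rng.normal(size=(20, 10)))
        resid = remove_pc1(x)
        var = lambda m: ((m.to_numpy() - m.to_numpy().mean(1, keepdims=True)) ** 2).sum()
        assert var(resid) < var(x)

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValueError):
            remove_pc1(pd.DataFrame(np.ones((5, 6))))


class TestCorrelation:
    def test_small_sample_matches_scipy_pearsonr(self):
        rng = np.random.default_rng(3)
        x = pd.DataFrame(rng.normal(size=(3, 5)))
        result = correlation_with_pvalues(x)
        r_ref, p_ref = scipy.stats.pearsonr(x.iloc[0], x.iloc[1])
        assert result.pcc.iloc[0, 1] == pytest.approx(r_ref)
        assert result.pvalues.iloc[0, 1] == pytest.approx(p_ref)

    def test_diagonal_and_antidiagonal_identities(self):
        x = pd.DataFrame([[1.0, 2, 3, 4], [-1.0, -2, -3, -4]])
        result = correlation_with_pvalues(x)
        assert result.pcc.iloc[0, 0] == pytest.approx(1.0)
        assert result.pvalues.iloc[0, 0] == 0.0
        assert result.pcc.iloc[0, 1] == pytest.approx(-1.0)

    def test_zero_variance_gene_flagged_not_dropped(self):
        x = pd.DataFrame([[1.0, 1, 1, 1], [1.0, 2, 3, 4]])
        result = correlation_with_pvalues(x)
        assert np.isnan(result.pcc.iloc[0, 1])
        assert result.pcc.shape == (2, 2)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            correlation_with_pvalues(pd.DataFrame(np.eye(3)))


class TestCriticalPcc:
    def test_reproduces_published_threshold_at_n22(self):
        assert round(critical_pcc(22, 0.05), 2) == 0.43

    def test_without_component_adjustment_gives_plain_student_value(self):
        assert round(critical_pcc(22, 0.05, n_components_removed=0), 2) == 0.42

    def test_strictly_decreasing_in_sample_count(self):
        values = [critical_pcc(n) for n in range(6, 40)]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_small_n_matches_t_quantile_oracle(self):
        t_star = scipy.stats.t.ppf(0.975, 4 - 2)
        expected = t_star / math.sqrt(t_star**2 + 2)
        assert critical_pcc(4, 0.05, n_components_removed=0) == pytest.approx(expected)

    def test_alpha_near_one_drives_threshold_to_zero(self):
        assert critical_pcc(22, 0.999) < 0.01


def _corr_from_matrix(m, mean_expression=None):
    m = np.asarray(m, float)
    genes = [f"g{i}" for i in range(m.shape[0])]
    me = (
        pd.Series(mean_expression, index=genes)
        if mean_expression is not None
        else pd.Series(np.arange(m.shape[0], dtype=float), index=genes)
    )
    return CorrelationResult(
        pcc=pd.DataFrame(m, index=genes, columns=genes),
        pvalues=pd.DataFrame(np.zeros_like(m), index=genes, columns=genes),
        n_samples=24,
        mean_expression=me,
    )


class TestSpqn:
    def test_noop_on_bin_homogeneous_matrix(self):
        n = 60
        m = np.full((n, n), 0.2)
        np.fill_diagonal(m, 1.0)
        corr = _corr_from_matrix(m)
        out = spatial_quantile_normalize(corr, ngrp=6, size_grp=20, ref_grp=5)
        assert np.abs(out.pcc.to_numpy() - m).max() <= 0.01

    def test_compressed_low_bins_equalized_to_reference(self):
        rng = np.random.default_rng(4)
        n = 120
        base = np.clip(rng.normal(0, 0.3, size=(n, n)), -0.95, 0.95)
        base = (base + base.T) / 2
        scale = np.linspace(0.3, 1.0, n)  # low-expression rows compressed
        m = base * np.sqrt(np.outer(scale, scale))
        np.fill_diagonal(m, 1.0)
        corr = _corr_from_matrix(m)

        def bin_iqr(mat, lo, hi):
            block = mat[lo:hi, lo:hi][~np.eye(hi - lo, dtype=bool)]
            return np.subtract(*np.percentile(block, [75, 25]))

        ref_before = bin_iqr(m, 90, 120)
        low_before = bin_iqr(m, 0, 30)
        assert abs(low_before / ref_before - 1) > 0.5
        out = spatial_quantile_normalize(corr, ngrp=4, size_grp=40, ref_grp=3)
        mo = out.pcc.to_numpy()
        low_after = bin_iqr(mo, 0, 30)
        ref_after = bin_iqr(mo, 90, 120)
        assert abs(low_after / ref_after - 1) < 0.2

    def test_rank_preservation_within_cells(self):
        rng = np.random.default_rng(5)
        n = 40
        m = np.clip(rng.normal(0, 0.4, size=(n, n)), -0.9, 0.9)
        m = (m + m.T) / 2
        np.fill_diagonal(m, 1.0)
        corr = _corr_from_matrix(m)
        out = spatial_quantile_normalize(corr, ngrp=4, size_grp=20, ref_grp=3)
        # off-diagonal cell (0, 3): ordering must be preserved by the monotone map
        before = m[0:10, 30:40].ravel()
        after = out.pcc.to_numpy()[0:10, 30:40].ravel()
        assert (np.argsort(before) == np.argsort(after)).all()

    def test_output_symmetric_with_unit_diagonal(self):
        rng = np.random.default_rng(6)
        m = np.clip(rng.normal(0, 0.4, size=(50, 50)), -0.9, 0.9)
        m = (m + m.T) / 2
        np.fill_diagonal(m, 1.0)
        out = spatial_quantile_normalize(_corr_from_matrix(m), ngrp=5, ref_grp=4)
        mo = out.pcc.to_numpy()
        assert np.allclose(mo, mo.T, atol=1e-12)
        assert np.allclose(np.diag(mo), 1.0)

    def test_invalid_parameters_rejected(self):
        corr = _corr_from_matrix(np.eye(20))
        with pytest.raises(ValueError):
            spatial_quantile_normalize(corr, ngrp=5, size_grp=50, ref_grp=4)
        with pytest.raises(ValueError):
            spatial_quantile_normalize(corr, ngrp=5, ref_grp=7)


class TestBinDiagnostic:
    def test_bin_sizes_partition_genes(self):
        corr = _corr_from_matrix(np.eye(47))
        diag = bin_density_diagnostic(corr, n_bins=10)
        assert diag["n_genes"].sum() == 47

    def test_independent_data_has_near_zero_medians(self):
        rng = np.random.default_rng(7)
        x = pd.DataFrame(rng.normal(size=(200, 60)))
        corr = correlation_with_pvalues(x)
        diag = bin_density_diagnostic(corr, n_bins=10)
        assert np.abs(diag["median"]).max() < 0.05

    def test_mean_linked_confounder_raises_high_bins(self):
        rng = np.random.default_rng(8)
        factor = rng.normal(size=40)
        loadings = np.linspace(0, 1.5, 100)
        x = pd.DataFrame(
            np.outer(loadings, factor)
            + rng.normal(scale=1.0, size=(100, 40))
            + np.linspace(0, 10, 100)[:, None]  # mean increases with loading
        )
        corr = correlation_with_pvalues(x)
        diag = bin_density_diagnostic(corr, n_bins=5)
        assert diag["median"].iloc[-1] > diag["median"].iloc[0] + 0.2


class TestFullStack:
    def test_deterministic_and_well_formed(self, scenario):
        corr1, _ = coexpression_pipeline(scenario.counts)
        corr2, _ = coexpression_pipeline(scenario.counts)
        pd.testing.assert_frame_equal(corr1.pcc, corr2.pcc)
        m = corr1.pcc.to_numpy()
        assert np.allclose(m, m.T, atol=1e-12)
        assert np.allclose(np.diag(m), 1.0)
        assert ((corr1.pvalues.to_numpy() >= 0) & (corr1.pvalues.to_numpy() <= 1)).all()

    def test_confounder_bias_reduced_in_every_bin(self, scenario):
        _, diagnostics = coexpression_pipeline(scenario.counts)
        before = np.abs(diagnostics["normalized"]["median"].to_numpy())
        after = np.abs(diagnostics["spqn"]["median"].to_numpy())
        assert (after < before).all()
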