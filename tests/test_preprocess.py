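import numpy as np
import pytest

from omicsense import CountMatrix
from omicsense.preprocess import (
    arcsinh_values,
    downsample_counts,
    jittered_arcsinh,
    jittered_arcsinh_values,
    log_normalize,
    qc_filter,
    regress_and_scale,
)


def _rna_matrix(counts, barcodes=None, names=None):
    counts = np.asarray(counts)
    if barcodes is None:
        barcodes = [f"B{i:04d}" for i in range(counts.shape[0])]
    if names is None:
        names = [f"G{j}" for j in range(counts.shape[1])]
    return CountMatrix(counts, barcodes, names, "rna")


class TestLogNormalize:
    def test_closed_form(self):
        # count 1 of cell total 100 at scale 10,000 -> ln(1 + 100)
        m = _rna_matrix([[1, 99]])
        norm = log_normalize(m)
        assert norm.values[0, 0] == pytest.approx(np.log(101), abs=1e-12)

    def test_zero_count_maps_to_zero(self):
        norm = log_normalize(_rna_matrix([[0, 5]]))
        assert norm.values[0, 0] == 0.0

    def test_proportional_cells_identical(self):
        norm = log_normalize(_rna_matrix([[2, 4, 6], [20, 40, 60]]))
        np.testing.assert_allclose(norm.values[0], norm.values[1], atol=1e-12)

    def test_prelog_sums_equal_scale_factor(self, rng):
        counts = rng.integers(0, 50, size=(30, 20))
        counts[:, 0] += 1  # no zero-total cells
        m = _rna_matrix(counts)
        norm = log_normalize(m, scale_factor=10_000)
        prelog = np.expm1(norm.values)
        np.testing.assert_allclose(prelog.sum(axis=1), 10_000, rtol=1e-12)

    def test_zero_total_cells_dropped_with_warning(self):
        m = _rna_matrix([[1, 1], [0, 0]])
        with pytest.warns(UserWarning, match="zero total"):
            norm = log_normalize(m)
        assert norm.values.shape == (1, 2)
        assert norm.barcodes == ["B0000"]

    def test_bad_scale_factor(self):
        with pytest.raises(ValueError, match="scale_factor"):
            log_normalize(_rna_matrix([[1]]), scale_factor=0)


class TestArcsinh:
    def test_closed_form_without_jitter(self):
        np.testing.assert_allclose(arcsinh_values(5), np.arcsinh(1.0), atol=1e-12)
        assert arcsinh_values(0) == 0.0

    def test_monotone_in_counts(self):
        vals = arcsinh_values(np.arange(100))
        assert np.all(np.diff(vals) > 0)

    def test_jitter_bounded(self, rng):
        counts = rng.integers(0, 100, size=(20, 5))
        vals = jittered_arcsinh_values(counts, seed=1)
        assert np.all(vals >= arcsinh_values(counts))
        assert np.all(vals < arcsinh_values(counts + 1))

    def test_seed_reproducibility(self):
        counts = np.arange(12).reshape(3, 4)
        a = jittered_arcsinh_values(counts, seed=7)
        b = jittered_arcsinh_values(counts, seed=7)
        np.testing.assert_array_equal(a, b)
        c = jittered_arcsinh_values(counts, seed=8)
        assert not np.array_equal(a, c)

    def test_matrix_wrapper_tags(self):
        m = _rna_matrix([[1, 2], [3, 4]])
        norm = jittered_arcsinh(m, seed=3)
        assert norm.transform_tag == "jittered_arcsinh"
        assert norm.seed == 3
        np.testing.assert_array_equal(
            norm.values, jittered_arcsinh_values(m.counts, seed=3)
        )


class TestQCFilter:
    def _cell(self, n_genes_detected, total=None, mito=0, n_genes=250):
        row = np.zeros(n_genes, dtype=int)
        row[:n_genes_detected] = 1
        if total is not None:
            row[0] += total - row.sum()
        row[-1] = mito
        return row

    def _matrix(self, rows):
        rows = np.asarray(rows)
        names = [f"G{j}" for j in range(rows.shape[1] - 1)] + ["MT-1"]
        return CountMatrix(rows, [f"B{i}" for i in range(rows.shape[0])], names, "rna")

    def test_low_gene_cell_dropped_by_inclusion(self):
        m = self._matrix([self._cell(150), self._cell(220)])
        kept, report = qc_filter(m, "wta_inclusion", mito_features=["MT-1"])
        assert kept.n_barcodes == 1
        assert report.drops_per_rule["min_genes"] == 1

    def test_high_mito_dropped_by_inclusion(self):
        good = self._cell(220)
        bad = self._cell(220, mito=1000)  # mito >> 20% of total
        m = self._matrix([good, bad])
        kept, report = qc_filter(m, "wta_inclusion", mito_features=["MT-1"])
        assert kept.n_barcodes == 1
        assert report.drops_per_rule["mito_fraction"] == 1

    def test_high_umi_dropped_by_doublet_removal(self):
        m = self._matrix([self._cell(200, total=16_000), self._cell(200, total=5_000)])
        kept, report = qc_filter(m, "wta_doublet_removal", mito_features=["MT-1"])
        assert kept.n_barcodes == 1
        assert report.drops_per_rule["max_umis"] == 1

    def test_high_gene_count_dropped_by_doublet_removal(self):
        rows = np.ones((1, 3500), dtype=int)
        m = CountMatrix(rows, ["B0"], [f"G{j}" for j in range(3500)], "rna")
        kept, report = qc_filter(m, "wta_doublet_removal")
        assert kept.n_barcodes == 0
        assert report.drops_per_rule["max_genes"] == 1

    def test_ruleset_none_is_identity(self, tiny_multimodal):
        kept, report = qc_filter(tiny_multimodal, "none")
        assert kept is tiny_multimodal
        assert report.n_dropped == 0

    def test_unknown_ruleset(self, tiny_multimodal):
        with pytest.raises(ValueError, match="unknown ruleset"):
            qc_filter(tiny_multimodal, "bogus")

    def test_unknown_mito_feature(self, tiny_multimodal):
        with pytest.raises(ValueError, match="mito"):
            qc_filter(tiny_multimodal, "wta_inclusion", mito_features=["MT-NOPE"])

    def test_drop_accounting(self, rng):
        counts = rng.integers(0, 3, size=(50, 300))
        m = CountMatrix(counts, [f"B{i}" for i in range(50)], [f"G{j}" for j in range(300)], "rna")
        kept, report = qc_filter(m, "wta_inclusion")
        assert report.n_input - report.n_kept == report.n_dropped
        assert report.n_dropped <= sum(report.drops_per_rule.values())  # overlap allowed


class TestRegressAndScale:
    def test_orthogonal_covariate_equals_zscore(self, rng):
        values = rng.normal(size=(100, 4))
        values -= values.mean(axis=0)
        cov = rng.normal(size=100)
        cov -= cov.mean()
        cov -= values @ np.linalg.lstsq(values, cov, rcond=None)[0]  # orthogonalize
        norm = _norm(values)
        scaled = regress_and_scale(norm, cov)
        expected = (values - values.mean(axis=0)) / values.std(axis=0)
        np.testing.assert_allclose(scaled.values, expected, atol=1e-8)

    def test_perfectly_linear_feature_scales_to_zero(self):
        cov = np.arange(50, dtype=float)
        values = np.column_stack([2.0 * cov + 1.0])
        scaled = regress_and_scale(_norm(values), cov)
        np.testing.assert_allclose(scaled.values, 0.0, atol=1e-8)

    def test_mean_zero_sd_one(self, rng):
        values = rng.normal(size=(200, 6)) + rng.normal(size=200)[:, None]
        cov = rng.normal(size=200)
        scaled = regress_and_scale(_norm(values), cov)
        assert np.all(np.abs(scaled.values.mean(axis=0)) < 1e-8)
        sd = scaled.values.std(axis=0)
        assert np.all((np.abs(sd - 1) < 1e-8) | (sd == 0))

    def test_constant_feature_zeroed(self):
        values = np.column_stack([np.full(30, 5.0), np.arange(30, dtype=float)])
        scaled = regress_and_scale(_norm(values), np.random.default_rng(0).normal(size=30))
        np.testing.assert_array_equal(scaled.values[:, 0], 0.0)

    def test_clipping(self, rng):
        values = rng.normal(size=(100, 2))
        values[0, 0] = 1e6  # extreme outlier
        scaled = regress_and_scale(_norm(values), rng.normal(size=100), clip=3.0)
        assert scaled.values.max() <= 3.0
        assert scaled.values.min() >= -3.0

    def test_length_mismatch(self, rng):
        with pytest.raises(ValueError, match="covariate length"):
            regress_and_scale(_norm(rng.normal(size=(10, 2))), np.ones(5))


def _norm(values):
    from omicsense.preprocess import NormalizedMatrix

    return NormalizedMatrix(
        values=np.asarray(values, dtype=float),
        barcodes=[f"B{i}" for i in range(len(values))],
        feature_names=[f"F{j}" for j in range(np.asarray(values).shape[1])],
        transform_tag="lognorm10k",
    )


class TestDownsample:
    def test_fraction_one_identity(self, tiny_multimodal):
        out = downsample_counts(tiny_multimodal, 1.0, seed=0)
        np.testing.assert_array_equal(out.counts, tiny_multimodal.counts)

    def test_never_exceeds_input(self, rng):
        counts = rng.integers(0, 100, size=(20, 10))
        m = CountMatrix(counts, [f"B{i}" for i in range(20)], [f"F{j}" for j in range(10)], "rna")
        out = downsample_counts(m, 0.3, seed=1)
        assert np.all(out.counts <= counts)
        assert out.total_molecules() <= m.total_molecules()

    def test_binomial_moments(self):
        m = CountMatrix([[10_000]], ["B0"], ["F0"], "rna")
        draws = np.array(
            [downsample_counts(m, 0.2, seed=s).counts[0, 0] for s in range(50)]
        )
        sd = np.sqrt(10_000 * 0.2 * 0.8)  # = 40
        assert abs(draws.mean() - 2000) < 3 * sd / np.sqrt(50)

    def test_composition_of_thins(self):
        m = CountMatrix(np.full((200, 1), 1000), [f"B{i}" for i in range(200)], ["F0"], "rna")
        two_step = downsample_counts(downsample_counts(m, 0.5, seed=1), 0.4, seed=2)
        one_step = downsample_counts(m, 0.2, seed=3)
        a, b = two_step.counts.ravel(), one_step.counts.ravel()
        # same distribution Binomial(1000, 0.2): compare mean and variance
        assert abs(a.mean() - b.mean()) < 4 * np.sqrt(2 * 160 / 200)
        assert abs(a.var() - b.var()) < 0.5 * 160

    @pytest.mark.parametrize("fraction", [0.0, -0.1, 1.5])
    def test_invalid_fraction(self, tiny_multimodal, fraction):
        with pytest.raises(ValueError, match="fraction"):
            downsample_counts(tiny_multimodal, fraction)

    def test_deterministic_under_seed(self, tiny_multimodal):
        a = downsample_counts(tiny_multimodal, 0.5, seed=5)
        b = downsample_counts(tiny_multimodal, 0.5, seed=5)
        np.testing.assert_array_equal(a.counts, b.counts)
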