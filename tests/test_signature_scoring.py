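import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.cluster.hierarchy import cophenet

from acb.io_formats import ExpressionMatrix, SensitivityVector, SignatureSet, Units
from acb.signature_scoring import (
    gene_gene_corr,
    hclust_complete,
    pca_on_signature,
    reduce_signature,
    responder_fraction,
    score_samples,
    zscore_genes,
)
from acb.synthetic_data import SyntheticConfig, generate_panel
from conftest import fisher_z_interval


def _matrix(arr, samples=None, genes=None):
    arr = np.asarray(arr, dtype=float)
    samples = samples or [f"s{i}" for i in range(arr.shape[0])]
    genes = genes or [f"g{i}" for i in range(arr.shape[1])]
    return ExpressionMatrix(pd.DataFrame(arr, index=samples, columns=genes),
                            units=Units.normalized_protein)


class TestScoreSamples:
    def test_mean_of_two_genes(self, tiny_matrix):
        sv = score_samples(tiny_matrix, SignatureSet("s", ("gA", "gB")))
        assert sv.score.loc["s1"] == pytest.approx(1.5)
        assert sv.score.loc["s3"] == pytest.approx(7.5)

    def test_missing_gene_is_an_error(self, tiny_matrix):
        with pytest.raises(KeyError, match="gZ"):
            score_samples(tiny_matrix, SignatureSet("s", ("gA", "gZ")))

    def test_linearity_in_the_matrix(self, panel31):
        sig = panel31.truth_signature()
        a = panel31.expression
        b = ExpressionMatrix(a.values * 2 + 1, units=Units.normalized_protein)
        avg = ExpressionMatrix((a.values + b.values) / 2, units=Units.normalized_protein)
        lhs = score_samples(avg, sig).score
        rhs = (score_samples(a, sig).score + score_samples(b, sig).score) / 2
        pd.testing.assert_series_equal(lhs, rhs)

    def test_panel_score_matches_planted_correlation(self, panel31):
        sv = score_samples(panel31.expression, panel31.truth_signature())
        r = stats.pearsonr(sv.score, np.log(panel31.sensitivity.values))[0]
        lo, hi = fisher_z_interval(0.86, n=31)
        assert lo < r < hi


class TestZscoreGenes:
    def test_simple_column(self):
        z = zscore_genes(_matrix([[1.0], [2.0], [3.0]]))
        assert z.iloc[:, 0].to_numpy() == pytest.approx([-1.0, 0.0, 1.0])

    def test_idempotent_and_permutation_equivariant(self, tiny_matrix):
        z = zscore_genes(tiny_matrix)
        z2 = zscore_genes(ExpressionMatrix(z, units=Units.normalized_protein))
        assert np.abs(z2.to_numpy() - z.to_numpy()).max() < 1e-10
        perm = ["s3", "s1", "s4", "s2"]
        zp = zscore_genes(ExpressionMatrix(tiny_matrix.values.loc[perm],
                                           units=Units.log2tpm1))
        pd.testing.assert_frame_equal(zp, z.loc[perm])

    def test_constant_gene_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            zscore_genes(_matrix([[1.0, 2.0], [1.0, 3.0], [1.0, 4.0]]))


def brute_force_complete_cophenetic(points: np.ndarray) -> np.ndarray:
    """O(n^3) complete-linkage agglomeration; returns the cophenetic matrix."""
    n = len(points)
    d = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(-1))
    clusters = [frozenset([i]) for i in range(n)]
    coph = np.zeros((n, n))
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            h = max(d[i, j] for i in clusters[a] for j in clusters[b])
            if best is None or h < best[0]:
                best = (h, a, b)
        h, a, b = best
        for i in clusters[a]:
            for j in clusters[b]:
                coph[i, j] = coph[j, i] = h
        merged = clusters[a] | clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)] + [merged]
    return coph


class TestHclustComplete:
    def test_three_points_on_a_line(self):
        m = _matrix(np.array([[0.0], [1.0], [10.0]]), samples=["a", "b", "c"])
        res = hclust_complete(m, axis="samples")
        assert res.heights[0] == pytest.approx(1.0)   # {a, b} first
        assert res.heights[-1] == pytest.approx(10.0)  # complete: max distance

    def test_identical_items_merge_at_zero(self):
        m = _matrix(np.array([[1.0, 2.0], [1.0, 2.0], [5.0, 5.0]]))
        res = hclust_complete(m, axis="samples")
        assert res.heights[0] == pytest.approx(0.0)

    def test_monotone_heights(self, panel31):
        sig = panel31.truth_signature()
        res = hclust_complete(panel31.expression.subset_features(sig.genes), axis="genes")
        assert np.all(np.diff(res.heights) >= -1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        pts = rng.standard_normal((n, 3))
        m = _matrix(pts, samples=[f"i{k:02d}" for k in range(n)])
        res = hclust_complete(m, axis="samples")
        coph_impl = np.zeros((n, n))
        iu = np.triu_indices(n, 1)
        coph_impl[iu] = cophenet(res.merges)
        coph_impl += coph_impl.T
        coph_ref = brute_force_complete_cophenetic(pts)
        assert np.abs(coph_impl - coph_ref).max() < 1e-10


class TestGeneGeneCorr:
    def test_unit_diagonal_and_symmetry(self, panel31):
        corr = gene_gene_corr(panel31.expression, panel31.truth_signature())
        assert np.allclose(np.diag(corr), 1.0)
        assert np.allclose(corr, corr.T)

    def test_duplicated_gene_gives_unit_offdiagonal(self):
        col = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        m = _matrix(np.column_stack([col, col, -col]), genes=["a", "b", "c"])
        corr = gene_gene_corr(m, SignatureSet("s", ("a", "b", "c")))
        assert corr.loc["a", "b"] == pytest.approx(1.0)
        assert corr.loc["a", "c"] == pytest.approx(-1.0)

    def test_planted_block_correlation_level(self):
        bundle = generate_panel(SyntheticConfig(n_samples=500, n_genes=100,
                                                within_block_r=0.7, seed=4))
        corr = gene_gene_corr(bundle.expression, bundle.truth_signature()).to_numpy()
        off = corr[~np.eye(corr.shape[0], dtype=bool)]
        assert 0.6 < off.mean() < 0.8


class TestPCA:
    def test_collinear_data_is_one_dimensional(self):
        t = np.linspace(-2, 2, 30)
        data = np.outer(t, [1.0, 2.0, -1.0])
        m = _matrix(data, genes=["a", "b", "c"])
        table, explained = pca_on_signature({"x": m}, SignatureSet("s", ("a", "b", "c")))
        assert explained[0] == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(explained) <= 1e-12)

    def test_isotropic_data_splits_variance(self):
        rng = np.random.default_rng(0)
        m = _matrix(rng.standard_normal((5000, 4)), genes=list("abcd"))
        _, explained = pca_on_signature({"x": m}, SignatureSet("s", tuple("abcd")))
        assert explained[0] / explained[1] < 1.05 / 0.95

    def test_cohort_order_invariance(self, panel31):
        sig = panel31.truth_signature()
        other = generate_panel(SyntheticConfig(n_samples=12, seed=9))
        b = ExpressionMatrix(
            other.expression.values.rename(index=lambda s: f"B_{s}"),
            units=Units.log2tpm1)
        t1, _ = pca_on_signature({"A": panel31.expression, "B": b}, sig)
        t2, _ = pca_on_signature({"B": b, "A": panel31.expression}, sig)
        a1 = t1[t1.cohort == "A"][["PC1", "PC2"]]
        a2 = t2[t2.cohort == "A"][["PC1", "PC2"]]
        pd.testing.assert_frame_equal(a1, a2)

    def test_single_sample_rejected(self):
        m = _matrix(np.ones((1, 2)), genes=["a", "b"])
        with pytest.raises(ValueError):
            pca_on_signature({"x": m}, SignatureSet("s", ("a", "b")))


class TestReduceSignature:
    @staticmethod
    def _panel_with_decoys(seed, n_samples=400, n_truth=4, n_decoys=2):
        # within_block_r = 0.5 so each real gene carries a marginal
        # contribution to the score correlation well above sampling noise
        bundle = generate_panel(SyntheticConfig(n_samples=n_samples, n_genes=200,
                                                within_block_r=0.5, seed=seed))
        genes = bundle.truth[:n_truth] + [f"GENE{j:05d}" for j in range(n_decoys)]
        return bundle, SignatureSet("mixed", tuple(genes)), set(genes[n_truth:])

    def test_pure_noise_gene_removed_first(self):
        rng = np.random.default_rng(0)
        n = 50
        base = rng.standard_normal(n)
        data = np.column_stack([base + 0.01 * rng.standard_normal(n) for _ in range(3)]
                               + [rng.standard_normal(n) * 3])
        m = _matrix(data, genes=["a", "b", "c", "noise"])
        s = SensitivityVector(pd.Series(base, index=m.sample_ids), metric="ln_ec50")
        _, trace = reduce_signature(SignatureSet("s", ("a", "b", "c", "noise")), m, s,
                                    transform="identity")
        assert trace and trace[0][0] == "noise"

    def test_trace_is_non_decreasing(self):
        bundle, sig, _ = self._panel_with_decoys(seed=1)
        _, trace = reduce_signature(sig, bundle.expression, bundle.sensitivity)
        rs = [r for _, r in trace]
        assert all(b >= a for a, b in zip(rs, rs[1:]))

    def test_decoys_and_only_decoys_removed(self):
        """Backward elimination strips planted decoys in >= 90% of seeds."""
        successes = 0
        for seed in range(20):
            bundle, sig, decoys = self._panel_with_decoys(seed)
            reduced, trace = reduce_signature(sig, bundle.expression, bundle.sensitivity)
            if {g for g, _ in trace} == decoys:
                successes += 1
        assert successes >= 18


class TestResponderFraction:
    def test_boundary_references(self):
        scores = pd.Series([2.0, 3.0, 4.0], index=["t1", "t2", "t3"])
        entities = pd.Series(["LUAD"] * 3, index=scores.index)
        assert responder_fraction(scores, entities, 1.0)["responder_fraction"].iloc[0] == 0.0
        assert responder_fraction(scores, entities, 9.0)["responder_fraction"].iloc[0] == 1.0

    def test_ties_count_as_responders(self):
        scores = pd.Series([2.0, 2.0, 4.0, 6.0], index=list("abcd"))
        entities = pd.Series(["X"] * 4, index=scores.index)
        out = responder_fraction(scores, entities, 2.0)
        assert out.loc["X", "responder_fraction"] == pytest.approx(0.5)

    def test_low_quantile_reference_gives_sub_percent_fraction(self):
        # 576 scores at exact normal plotting-position quantiles
        mu, sd, n = 5.0, 0.8, 576
        q = stats.norm.ppf((np.arange(n) + 0.5) / n)
        scores = pd.Series(mu + sd * q, index=[f"t{i}" for i in range(n)])
        entities = pd.Series(["LUAD"] * n, index=scores.index)
        reference = mu + sd * stats.norm.ppf(0.008)  # the 0.8th percentile
        out = responder_fraction(scores, entities, reference)
        assert out.loc["LUAD", "responder_fraction"] < 0.01

    def test_multiple_entities_grouped(self):
        scores = pd.Series([1.0, 2.0, 10.0, 11.0], index=list("abcd"))
        entities = pd.Series(["low", "low", "high", "high"], index=scores.index)
        out = responder_fraction(scores, entities, 5.0)
        assert out.loc["low", "responder_fraction"] == 1.0
        assert out.loc["high", "responder_fraction"] == 0.0
        assert out.loc["low", "n"] == 2
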