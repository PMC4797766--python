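import numpy as np
import pandas as pd
import pytest

from refstab import (
    CqMatrix,
    bestkeeper,
    delta_ct_stability,
    genorm,
    normfinder_stability,
    run_all,
)
from refstab.stability import _genorm_m, _normfinder_sigma2


def _cq(arr, genes=None):
    arr = np.asarray(arr, dtype=float)
    genes = genes or [chr(ord("A") + j) for j in range(arr.shape[1])]
    return CqMatrix(pd.DataFrame(
        arr, index=[f"s{i}" for i in range(arr.shape[0])], columns=genes))


def _random(n, g, seed, lo=20.0, hi=32.0):
    rng = np.random.default_rng(seed)
    return _cq(rng.uniform(lo, hi, size=(n, g)))


class TestDeltaCt:
    def test_constant_offset_pair_has_zero_pair_sd(self):
        m = _cq([[20.0, 23.0], [21.0, 24.0], [22.5, 25.5]])
        res = delta_ct_stability(m)
        assert res.values["A"] == pytest.approx(0.0, abs=1e-12)
        assert res.values["B"] == pytest.approx(0.0, abs=1e-12)

    def test_hand_worked_three_gene_scores(self, small_matrix):
        res = delta_ct_stability(small_matrix)
        np.testing.assert_allclose(
            res.values[["A", "B", "C"]], [0.028868, 0.028868, 0.057735],
            atol=1e-6)
        assert list(res.ranks[["A", "B", "C"]]) == [1, 1, 3]

    def test_missing_cells_rejected(self):
        vals = pd.DataFrame({"A": [20.0, np.nan], "B": [25.0, 26.0]})
        with pytest.raises(ValueError, match="missing"):
            delta_ct_stability(CqMatrix(vals))


class TestGenorm:
    def test_constant_offset_pair_survives_to_final_pair(self):
        rng = np.random.default_rng(2)
        base = rng.uniform(20, 30, size=12)
        noise = rng.normal(0, 0.4, size=(12, 2))
        arr = np.column_stack([base, base + 3.0, 25 + noise[:, 0],
                               28 + noise[:, 1]])
        res, _ = genorm(_cq(arr))
        final = set(res.values.index[res.ranks == 1])
        assert final == {"A", "B"}
        assert res.values["A"] == res.values["B"]

    def test_initial_m_equals_delta_ct_scores(self, small_matrix):
        arr = small_matrix.values.to_numpy()
        log_q = np.log2(2.0) * (arr.min(axis=0, keepdims=True) - arr)
        np.testing.assert_allclose(
            _genorm_m(log_q),
            delta_ct_stability(small_matrix).values.to_numpy(), atol=1e-12)

    def test_final_pair_share_rank_one_next_rank_three(self, random_matrix):
        res, _ = genorm(random_matrix)
        ranks = sorted(res.ranks)
        assert ranks[:3] == [1, 1, 3]
        assert res.exclusion_trace is not None
        assert len(res.exclusion_trace) == random_matrix.n_genes - 2

    def test_v_series_covers_2_to_gminus1(self, random_matrix):
        _, vs = genorm(random_matrix)
        assert [n for n, _ in vs.entries] == list(
            range(2, random_matrix.n_genes))
        assert all(v >= 0 for _, v in vs.entries)

    def test_two_genes_rejected(self):
        with pytest.raises(ValueError, match=">=3 genes"):
            genorm(_cq([[20.0, 25.0], [21.0, 26.0]]))


class TestNormfinder:
    def test_pure_sample_effects_give_zero_stability(self):
        rng = np.random.default_rng(0)
        mu = np.array([22.0, 25.0, 28.0, 30.0])
        delta = rng.normal(0, 1.0, size=10)
        m = _cq(mu[None, :] + delta[:, None])
        res = normfinder_stability(m)
        np.testing.assert_allclose(res.values, 0.0, atol=1e-10)

    def test_recovers_planted_noisy_gene(self):
        rng = np.random.default_rng(123)
        sigma = np.array([0.5] + [0.1] * 7)
        y = rng.normal(0, 1, (1000, 1)) + rng.normal(0, 1, (1000, 8)) * sigma
        m = _cq(24.0 + y)  # sign flip irrelevant to the estimator
        res = normfinder_stability(m)
        assert res.values.iloc[0] == pytest.approx(0.5, rel=0.10)
        assert res.ranks.iloc[0] == 8

    def test_moment_estimator_floor_at_zero(self):
        rng = np.random.default_rng(5)
        y = rng.normal(0, 1, (6, 1)) + rng.normal(0, 0.01, (6, 4))
        assert (_normfinder_sigma2(y) >= 0).all()

    def test_groups_need_two_samples_each(self):
        m = _random(5, 4, seed=1)
        with pytest.raises(ValueError, match="<2 samples"):
            normfinder_stability(m, groups=["a", "a", "a", "a", "b"])

    def test_grouped_estimate_close_to_pooled_when_groups_identical(self):
        m = _random(40, 5, seed=3)
        pooled = normfinder_stability(m).values
        grouped = normfinder_stability(
            m, groups=["x"] * 20 + ["y"] * 20).values
        np.testing.assert_allclose(grouped, pooled, rtol=0.1)


class TestBestkeeper:
    def test_constant_gene_ranks_first(self):
        m = _cq([[25.0, 20.0], [25.0, 22.0], [25.0, 24.0], [25.0, 21.0]])
        res, corr = bestkeeper(m)
        assert res.values["A"] == 0.0
        assert res.ranks["A"] == 1
        assert np.isnan(corr["A"])

    def test_sd_and_mad_hand_values(self):
        col = CqMatrix(pd.DataFrame({"g": [20.0, 21.0, 22.0],
                                     "h": [25.0, 25.0, 25.0],
                                     "k": [30.0, 30.5, 31.0]}))
        sd, _ = bestkeeper(col, dispersion="sd")
        mad, _ = bestkeeper(col, dispersion="mad")
        assert sd.values["g"] == pytest.approx(1.0)
        assert mad.values["g"] == pytest.approx(2.0 / 3.0)

    def test_index_correlation_reported_not_ranked(self, random_matrix):
        res, corr = bestkeeper(random_matrix)
        assert set(corr.index) == set(res.values.index)
        assert ((corr.abs() <= 1) | corr.isna()).all()


class TestCrossAlgorithmProperties:
    @pytest.mark.parametrize("seed", range(5))
    def test_sample_shift_invariance_except_bestkeeper(self, seed):
        m = _random(15, 6, seed)
        shifted_vals = m.values.copy()
        shifted_vals.iloc[4] += 1.7  # one sample gets more RNA input
        s = CqMatrix(shifted_vals)
        for fn in (delta_ct_stability, normfinder_stability):
            np.testing.assert_allclose(fn(m).values, fn(s).values, atol=1e-9)
        np.testing.assert_allclose(genorm(m)[0].values,
                                   genorm(s)[0].values, atol=1e-9)
        bk_m, _ = bestkeeper(m)
        bk_s, _ = bestkeeper(s)
        assert not np.allclose(bk_m.values, bk_s.values, atol=1e-6)

    @pytest.mark.parametrize("seed", range(5))
    def test_permutation_invariance_of_values(self, seed):
        m = _random(10, 5, seed)
        rng = np.random.default_rng(seed + 100)
        perm_genes = list(rng.permutation(m.gene_ids))
        perm_samples = list(rng.permutation(m.sample_ids))
        p = CqMatrix(m.values.loc[perm_samples, perm_genes])
        for fn in (delta_ct_stability, normfinder_stability):
            a, b = fn(m).values, fn(p).values
            np.testing.assert_allclose(a[m.gene_ids], b[m.gene_ids],
                                       atol=1e-10)
        ga, gb = genorm(m)[0].values, genorm(p)[0].values
        np.testing.assert_allclose(ga[m.gene_ids], gb[m.gene_ids], atol=1e-10)

    def test_values_increase_with_iid_noise_level(self):
        rng = np.random.default_rng(9)
        base = rng.uniform(22, 30, size=8)
        means = {}
        for sigma in (0.1, 0.4, 0.8):
            arr = base[None, :] + np.random.default_rng(42).normal(
                0, sigma, size=(200, 8))
            m = _cq(arr)
            res, _ = run_all(m)
            means[sigma] = {k: r.values.mean() for k, r in res.items()}
        for algo in ("delta_ct", "genorm", "normfinder", "bestkeeper"):
            seq = [means[s][algo] for s in (0.1, 0.4, 0.8)]
            assert seq[0] < seq[1] < seq[2], algo


def test_run_all_returns_requested_methods(random_matrix):
    res, vs = run_all(random_matrix, methods=["delta_ct", "bestkeeper"])
    assert set(res) == {"delta_ct", "bestkeeper"}
    assert vs is None
    res, vs = run_all(random_matrix)
    assert set(res) == {"delta_ct", "bestkeeper", "normfinder", "genorm"}
    assert vs is not None
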