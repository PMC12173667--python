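"""Co-abundance network: preprocessing, TOM, module detection, eigengenes."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from topform import network as nw
from topform.types import NetworkConfig
from conftest import make_quant_matrix


def zscore_rows(X):
    return (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, ddof=1, keepdims=True)


def planted_blocks(rng, sizes, n_samples, noise=0.5, n_noise_rows=0):
    rows, truth = [], []
    for m, size in enumerate(sizes):
        f = rng.normal(0, 1, n_samples)
        rows.append(f[None, :] + rng.normal(0, noise, (size, n_samples)))
        truth += [m + 1] * size
    if n_noise_rows:
        rows.append(rng.normal(0, 1, (n_noise_rows, n_samples)))
        truth += [0] * n_noise_rows
    X = np.vstack(rows)
    return pd.DataFrame(zscore_rows(X)), truth


class TestPreprocess:
    def test_complete_matrix_zero_pmi_slope_is_plain_zscore(self):
        rng = np.random.default_rng(0)
        Y = rng.normal(0, 1, (20, 60))
        qm = make_quant_matrix(Y, extra={"pmi_hours": np.zeros(60)})
        cfg = NetworkConfig(min_samples_observed=10)
        z = nw.preprocess_for_network(qm, cfg)
        assert np.allclose(z.to_numpy(), zscore_rows(Y), atol=1e-9)

    def test_low_rank_matrix_recovered_through_missingness(self):
        rng = np.random.default_rng(1)
        U = rng.normal(0, 1, (40, 2))
        V = rng.normal(0, 1, (2, 30))
        M = U @ V
        holes = rng.random(M.shape) < 0.1
        Md = M.copy()
        Md[holes] = np.nan
        imputed = nw.svd_impute(Md, rank=2, tol=1e-9, max_iter=500)
        assert np.abs(imputed[holes] - M[holes]).max() < 1e-3

    def test_pmi_residualization_orthogonalizes_rows(self):
        rng = np.random.default_rng(2)
        n = 80
        pmi = rng.gamma(2.25, 3.07, n)
        Y = 0.3 * pmi[None, :] + rng.normal(0, 1, (50, n))
        qm = make_quant_matrix(Y, extra={"pmi_hours": pmi})
        cfg = NetworkConfig(min_samples_observed=10)
        z = nw.preprocess_for_network(qm, cfg)
        for row in z.to_numpy():
            assert abs(np.corrcoef(row, pmi)[0, 1]) < 0.05

    def test_completeness_filter_drops_sparse_rows(self):
        rng = np.random.default_rng(3)
        Y = rng.normal(0, 1, (5, 60))
        Y[0, 15:] = np.nan
        qm = make_quant_matrix(Y, extra={"pmi_hours": rng.gamma(2, 3, 60)})
        cfg = NetworkConfig(min_samples_observed=31)
        z = nw.preprocess_for_network(qm, cfg)
        assert z.shape[0] == 4

    def test_excessive_impute_rank_rejected(self):
        with pytest.raises(ValueError):
            nw.svd_impute(np.full((4, 5), np.nan), rank=4)


class TestTopologicalOverlap:
    def test_matches_brute_force_triple_loop(self):
        rng = np.random.default_rng(4)
        A = np.abs(np.corrcoef(rng.normal(0, 1, (5, 20)))) ** 6
        np.fill_diagonal(A, 0.0)
        tom = nw.topological_overlap(A)
        for i in range(5):
            for j in range(5):
                if i == j:
                    expected = 1.0
                else:
                    shared = sum(
                        A[i, u] * A[u, j] for u in range(5) if u not in (i, j)
                    )
                    kmin = min(A[i].sum(), A[j].sum())
                    expected = (shared + A[i, j]) / (kmin + 1.0 - A[i, j])
                assert tom[i, j] == pytest.approx(expected, abs=1e-12)

    def test_symmetric_and_in_unit_interval(self):
        rng = np.random.default_rng(5)
        Z = rng.normal(0, 1, (30, 25))
        A = nw.adjacency_matrix(zscore_rows(Z))
        tom = nw.topological_overlap(A)
        assert np.allclose(tom, tom.T, atol=1e-12)
        assert tom.min() >= 0.0 and tom.max() <= 1.0 + 1e-12


class TestModuleDetection:
    def test_two_planted_blocks_recovered(self):
        rng = np.random.default_rng(6)
        z, truth = planted_blocks(rng, [30, 30], 60)
        labels = nw.detect_modules(z)
        assert adjusted_rand_score(truth, labels) >= 0.95

    def test_noise_matrix_mostly_unassigned(self):
        fractions = []
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            z = pd.DataFrame(zscore_rows(rng.normal(0, 1, (200, 60))))
            labels = nw.detect_modules(z)
            fractions.append((labels == 0).mean())
        assert np.mean([f >= 0.9 for f in fractions]) >= 0.9

    def test_fewer_rows_than_min_module_size_all_unassigned(self):
        rng = np.random.default_rng(7)
        z = pd.DataFrame(zscore_rows(rng.normal(0, 1, (3, 30))))
        labels = nw.detect_modules(z)
        assert (labels == 0).all()

    def test_module_count_non_increasing_in_merge_height(self):
        rng = np.random.default_rng(8)
        z, _ = planted_blocks(rng, [15, 15, 15, 15], 50, noise=0.8)
        counts = []
        for h in (0.05, 0.15, 0.4, 0.8):
            cfg = NetworkConfig(merge_height=h)
            labels = nw.detect_modules(z, cfg)
            counts.append(labels[labels != 0].nunique())
        assert all(b <= a for a, b in zip(counts, counts[1:]))


class TestEigengenes:
    def test_identical_rows_module_returns_member_profile(self):
        rng = np.random.default_rng(9)
        row = rng.normal(0, 1, 40)
        zrow = (row - row.mean()) / row.std(ddof=1)
        z = pd.DataFrame(np.tile(zrow, (6, 1)))
        me = nw.module_eigengenes(z, pd.Series([1] * 6, index=z.index))
        assert np.allclose(me[1].to_numpy(), zrow, atol=1e-9)

    def test_unit_variance_and_positive_orientation(self):
        rng = np.random.default_rng(10)
        z, truth = planted_blocks(rng, [20, 20], 50)
        labels = pd.Series(truth, index=z.index)
        me = nw.module_eigengenes(z, labels)
        for mod in me.columns:
            assert me[mod].std(ddof=1) == pytest.approx(1.0, abs=1e-9)
            members = z.loc[labels == mod].to_numpy()
            cors = [np.corrcoef(me[mod], r)[0, 1] for r in members]
            assert np.mean(cors) > 0

    def test_latent_factor_recovered(self):
        rng = np.random.default_rng(11)
        f = rng.normal(0, 1, 60)
        X = f[None, :] + rng.normal(0, 0.5, (25, 60))
        z = pd.DataFrame(zscore_rows(X))
        me = nw.module_eigengenes(z, pd.Series([1] * 25, index=z.index))
        assert abs(np.corrcoef(me[1], f)[0, 1]) >= 0.95

    def test_sample_permutation_equivariance(self):
        rng = np.random.default_rng(12)
        z, truth = planted_blocks(rng, [15, 15], 40)
        labels = pd.Series(truth, index=z.index)
        me = nw.module_eigengenes(z, labels)
        perm = rng.permutation(z.shape[1])
        zp = z.iloc[:, perm]
        mep = nw.module_eigengenes(zp, labels)
        for mod in me.columns:
            a = me[mod].to_numpy()[perm]
            b = mep[mod].to_numpy()
            assert np.allclose(a, b, atol=1e-8) or np.allclose(a, -b, atol=1e-8)


class TestModuleTraitCorrelation:
    def test_eigengene_equal_to_trait_gives_unit_correlation(self):
        rng = np.random.default_rng(13)
        trait = rng.normal(0, 1, 50)
        cohort = pd.DataFrame(
            {"sample_id": [f"S{i}" for i in range(50)], "tr": trait}
        ).set_index("sample_id", drop=False)
        eg = pd.DataFrame({1: trait}, index=cohort.index)
        out = nw.module_trait_correlation(eg, cohort, ["tr"])
        assert out["r"].iloc[0] == pytest.approx(1.0)
        assert out["p"].iloc[0] < 1e-20

    def test_planted_correlation_within_sampling_band(self):
        rng = np.random.default_rng(14)
        n = 103
        trait = rng.normal(0, 1, n)
        eg_vec = 0.6 * trait + np.sqrt(1 - 0.36) * rng.normal(0, 1, n)
        cohort = pd.DataFrame(
            {"sample_id": [f"S{i}" for i in range(n)], "tr": trait}
        ).set_index("sample_id", drop=False)
        eg = pd.DataFrame({1: eg_vec}, index=cohort.index)
        out = nw.module_trait_correlation(eg, cohort, ["tr"])
        assert 0.45 <= out["r"].iloc[0] <= 0.72

    def test_null_modules_yield_few_adjusted_discoveries(self):
        counts = []
        for seed in range(5):
            rng = np.random.default_rng(200 + seed)
            n = 60
            cohort = pd.DataFrame({"sample_id": [f"S{i}" for i in range(n)]})
            for t in range(10):
                cohort[f"t{t}"] = rng.normal(0, 1, n)
            cohort = cohort.set_index("sample_id", drop=False)
            eg = pd.DataFrame(
                {m: rng.normal(0, 1, n) for m in range(20)}, index=cohort.index
            )
            out = nw.module_trait_correlation(
                eg, cohort, [f"t{t}" for t in range(10)]
            )
            counts.append((out["p_adj"] < 0.05).sum())
        assert np.mean(counts) <= 1.0

    def test_constant_trait_recorded(self):
        cohort = pd.DataFrame(
            {"sample_id": ["a", "b", "c"], "tr": [1.0, 1.0, 1.0]}
        ).set_index("sample_id", drop=False)
        eg = pd.DataFrame({1: [0.1, 0.2, 0.3]}, index=cohort.index)
        out = nw.module_trait_correlation(eg, cohort, ["tr"])
        assert out["reason"].iloc[0] == "constant_trait"
        assert np.isnan(out["r"].iloc[0])
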