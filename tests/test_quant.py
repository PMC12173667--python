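"""Alignment, clustering, match-between-runs and matrix construction."""

import itertools

import numpy as np
import pandas as pd
import pytest

from topform import quant, synth
from topform.types import AlignConfig


def prsm(sample, pform, gene="G1", mass=1000.0, rt=30.0, evalue=1e-5, intensity=1e6):
    return dict(
        sample_id=sample, scan=1, accession=f"ACC_{gene}", tier="canonical",
        gene=gene, proteoform=pform, start=1, end=len(pform), mass_da=mass,
        rt_min=rt, evalue=evalue, intensity=intensity, is_decoy=False,
    )


class TestAlignment:
    def test_reference_run_gets_identity_warp(self):
        rng = np.random.default_rng(0)
        rts = np.sort(rng.uniform(10, 100, 20))
        rows = [prsm("A", f"P{i}", rt=rts[i]) for i in range(20)]
        rows += [prsm("B", f"P{i}", rt=rts[i]) for i in range(10)]
        warps = quant.align_retention_times(pd.DataFrame(rows))
        probe = np.linspace(10, 100, 50)
        assert np.abs(warps["A"](probe) - probe).max() < 1e-9

    def test_linear_drift_recovered(self):
        rng = np.random.default_rng(1)
        rts = np.sort(rng.uniform(10, 100, 40))
        rows = [prsm("A", f"P{i}", rt=rts[i]) for i in range(40)]
        rows += [prsm("B", f"P{i}", rt=1.05 * rts[i] + 2.0) for i in range(30)]
        warps = quant.align_retention_times(pd.DataFrame(rows))
        rec = warps["B"](1.05 * rts[:30] + 2.0)
        rmse = np.sqrt(np.mean((rec - rts[:30]) ** 2))
        assert rmse < 0.1

    def test_single_run_passes_through(self):
        rows = [prsm("A", f"P{i}", rt=float(10 + i)) for i in range(8)]
        warps = quant.align_retention_times(pd.DataFrame(rows))
        assert list(warps) == ["A"] and warps["A"].identity

    def test_too_few_anchors_falls_back_to_identity(self):
        rows = [prsm("A", f"P{i}", rt=float(10 + i)) for i in range(10)]
        rows += [prsm("B", f"P{i}", rt=float(50 + i)) for i in range(3)]
        warps = quant.align_retention_times(pd.DataFrame(rows))
        assert warps["B"].identity


def brute_force_partition(df, mass_tol=0.8, rt_window=2.0):
    n = len(df)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            i = parent[i]
        return i

    for i, j in itertools.combinations(range(n), 2):
        if df["gene"].iloc[i] != df["gene"].iloc[j]:
            continue
        if (
            abs(df["mass_da"].iloc[i] - df["mass_da"].iloc[j]) <= mass_tol
            and abs(df["rt_aligned"].iloc[i] - df["rt_aligned"].iloc[j]) <= rt_window
        ):
            parent[find(i)] = find(j)
    return [find(i) for i in range(n)]


def partition_key(labels):
    groups = {}
    for i, lab in enumerate(labels):
        groups.setdefault(lab, []).append(i)
    return sorted(tuple(sorted(g)) for g in groups.values())


class TestClustering:
    def test_within_tolerance_pair_merges(self):
        df = pd.DataFrame(
            [prsm("A", "P", mass=1000.0, rt=30.0), prsm("B", "P", mass=1000.5, rt=30.3)]
        )
        df["rt_aligned"] = df["rt_min"]
        catalog, membership = quant.cluster_proteoforms(df)
        assert len(catalog) == 1

    def test_beyond_mass_tolerance_splits(self):
        df = pd.DataFrame(
            [prsm("A", "P", mass=1000.0, rt=30.0), prsm("B", "P", mass=1001.5, rt=30.0)]
        )
        df["rt_aligned"] = df["rt_min"]
        catalog, _ = quant.cluster_proteoforms(df)
        assert len(catalog) == 2

    def test_matches_brute_force_single_linkage(self):
        rng = np.random.default_rng(2)
        rows = []
        for i in range(30):
            rows.append(
                prsm(
                    rng.choice(list("ABC")), f"P{i}",
                    gene=rng.choice(["G1", "G2"]),
                    mass=float(rng.choice([1000, 1000.5, 1002, 1005]) + rng.normal(0, 0.1)),
                    rt=float(rng.choice([20, 21, 40]) + rng.normal(0, 0.3)),
                    evalue=float(rng.uniform(1e-8, 1e-4)),
                )
            )
        df = pd.DataFrame(rows)
        df["rt_aligned"] = df["rt_min"]
        _, membership = quant.cluster_proteoforms(df)
        assert partition_key(membership["proteoform_id"]) == partition_key(
            brute_force_partition(df)
        )

    def test_partition_invariant_to_row_order(self):
        rng = np.random.default_rng(3)
        rows = [
            prsm(
                rng.choice(list("AB")), f"P{i}", gene=rng.choice(["G1", "G2"]),
                mass=float(rng.uniform(1000, 1010)), rt=float(rng.uniform(20, 30)),
                evalue=float(rng.uniform(1e-8, 1e-4)),
            )
            for i in range(25)
        ]
        df = pd.DataFrame(rows)
        df["rt_aligned"] = df["rt_min"]
        _, m1 = quant.cluster_proteoforms(df)
        shuffled = df.sample(frac=1.0, random_state=7).reset_index(drop=True)
        _, m2 = quant.cluster_proteoforms(shuffled)
        key1 = {
            (r["mass_da"], r["rt_aligned"]): r["proteoform_id"] for _, r in m1.iterrows()
        }
        key2 = {
            (r["mass_da"], r["rt_aligned"]): r["proteoform_id"] for _, r in m2.iterrows()
        }
        assert partition_key(
            [key1[k] for k in sorted(key1)]
        ) == partition_key([key2[k] for k in sorted(key2)])

    def test_conflicting_strings_resolved_by_lowest_evalue(self):
        df = pd.DataFrame(
            [
                prsm("A", "PFORM_X", mass=1000.0, rt=30.0, evalue=1e-3),
                prsm("B", "PFORM_Y", mass=1000.2, rt=30.1, evalue=1e-8),
            ]
        )
        df["rt_aligned"] = df["rt_min"]
        catalog, _ = quant.cluster_proteoforms(df)
        assert catalog["proteoform"].iloc[0] == "PFORM_Y"


class TestMatchBetweenRuns:
    def make_setup(self):
        df = pd.DataFrame(
            [prsm("A", "P", mass=1000.0, rt=30.0), prsm("B", "P", mass=1000.1, rt=30.1)]
        )
        df["rt_aligned"] = df["rt_min"]
        catalog, membership = quant.cluster_proteoforms(df)
        warps = {
            s: quant.Warp(x=np.array([]), y=np.array([]), identity=True)
            for s in "ABC"
        }
        return catalog, membership, warps

    def test_exact_match_filled_and_flagged(self):
        catalog, membership, warps = self.make_setup()
        features = pd.DataFrame(
            [dict(sample_id="C", mass_da=1000.05, rt_min=30.0, intensity=5e5)]
        )
        out = quant.match_between_runs(catalog, membership, features, warps)
        c_cell = out[(out["sample_id"] == "C")]
        assert len(c_cell) == 1
        assert c_cell["transferred"].iloc[0]
        assert c_cell["intensity"].iloc[0] == pytest.approx(5e5)

    def test_nearer_mass_candidate_wins(self):
        catalog, membership, warps = self.make_setup()
        features = pd.DataFrame(
            [
                dict(sample_id="C", mass_da=catalog["mass_da"].iloc[0] + 0.3,
                     rt_min=30.0, intensity=111.0),
                dict(sample_id="C", mass_da=catalog["mass_da"].iloc[0] + 0.1,
                     rt_min=31.0, intensity=222.0),
            ]
        )
        out = quant.match_between_runs(catalog, membership, features, warps)
        assert out.loc[out["sample_id"] == "C", "intensity"].iloc[0] == 222.0

    def test_identified_cells_never_overwritten(self):
        catalog, membership, warps = self.make_setup()
        features = pd.DataFrame(
            [dict(sample_id="A", mass_da=1000.0, rt_min=30.0, intensity=9e9)]
        )
        out = quant.match_between_runs(catalog, membership, features, warps)
        a_cell = out[(out["sample_id"] == "A")]
        assert not a_cell["transferred"].any()
        assert a_cell["intensity"].iloc[0] == pytest.approx(1e6)

    def test_disabled_mbr_returns_identified_only(self):
        catalog, membership, warps = self.make_setup()
        features = pd.DataFrame(
            [dict(sample_id="C", mass_da=1000.0, rt_min=30.0, intensity=5e5)]
        )
        cfg = AlignConfig(mbr_enabled=False)
        out = quant.match_between_runs(catalog, membership, features, warps, cfg)
        assert set(out["sample_id"]) == {"A", "B"}

    def test_mbr_reduces_missingness_and_recovers_truth(self, small_study,
                                                        small_true_prsms):
        warps = quant.align_retention_times(small_true_prsms)
        aligned = quant.apply_warps(small_true_prsms, warps)
        catalog, membership = quant.cluster_proteoforms(aligned)
        n_samples = small_study.cohort.shape[0]
        ident = membership.groupby(["proteoform_id", "sample_id"])["intensity"].max()
        total = len(catalog) * n_samples
        before = total - int(ident.notna().sum())
        out = quant.match_between_runs(
            catalog, membership, small_study.features, warps
        )
        after = total - int(out["intensity"].notna().sum())
        assert after < before
        # transferred intensities track the generator's true abundances
        transferred = out[out["transferred"]]
        truth_map = membership.groupby("proteoform_id")["truth_id"].agg(
            lambda s: s.mode().iloc[0]
        )
        true_vals, obs_vals = [], []
        tl = small_study.truth.true_log2
        for _, r in transferred.iterrows():
            tid = truth_map.get(r["proteoform_id"], -1)
            if tid in tl.index:
                true_vals.append(tl.loc[tid, r["sample_id"]])
                obs_vals.append(np.log2(r["intensity"]))
        assert len(true_vals) > 20
        assert np.corrcoef(true_vals, obs_vals)[0, 1] > 0.9


class TestQuantMatrices:
    def build(self, n_samples=103, observed=50):
        rng = np.random.default_rng(4)
        cohort = synth.make_cohort(n_samples, 6, seed=5)
        samples = list(cohort["sample_id"])
        rows = []
        for s in samples[:observed]:
            rows.append(prsm(s, "PF_OBS", mass=1000.0, rt=30.0))
        for s in samples:
            rows.append(prsm(s, "PF_FULL", mass=2000.0, rt=50.0))
        df = pd.DataFrame(rows)
        df["rt_aligned"] = df["rt_min"]
        catalog, membership = quant.cluster_proteoforms(df)
        ident = (
            membership.groupby(["proteoform_id", "sample_id"])["intensity"]
            .max()
            .reset_index()
        )
        ident["transferred"] = False
        return catalog, membership, ident, cohort

    def test_completeness_filter_at_50_of_103(self):
        catalog, membership, ident, cohort = self.build(observed=50)
        iqm, _ = quant.build_quant_matrices(catalog, membership, ident, cohort)
        assert iqm.values.shape[0] == 2
        catalog, membership, ident, cohort = self.build(observed=49)
        iqm, _ = quant.build_quant_matrices(catalog, membership, ident, cohort)
        assert iqm.values.shape[0] == 1  # 49-sample proteoform excluded

    def test_counts_filter_six_samples_three_batches(self):
        cohort = synth.make_cohort(103, 6, seed=6)
        samples = list(cohort["sample_id"])
        by_batch = cohort.groupby("batch")["sample_id"].apply(list)
        chosen = by_batch[1][:2] + by_batch[2][:2] + by_batch[3][:2]
        rows = [prsm(s, "PF_A", mass=1000.0, rt=30.0) for s in chosen]
        rows += [prsm(s, "PF_BG", mass=3000.0, rt=70.0) for s in samples]
        df = pd.DataFrame(rows)
        df["rt_aligned"] = df["rt_min"]
        catalog, membership = quant.cluster_proteoforms(df)
        ident = (
            membership.groupby(["proteoform_id", "sample_id"])["intensity"]
            .max()
            .reset_index()
        )
        ident["transferred"] = False
        _, cqm = quant.build_quant_matrices(catalog, membership, ident, cohort)
        kept = set(cqm.proteoforms["proteoform"])
        assert "PF_A" in kept

    def test_constant_intensities_give_zero_log_ratios(self):
        catalog, membership, ident, cohort = self.build(observed=103)
        iqm, _ = quant.build_quant_matrices(catalog, membership, ident, cohort)
        assert np.allclose(iqm.values.to_numpy(), 0.0)

    def test_counts_conservation_per_sample(self, small_true_prsms, small_study):
        aligned = small_true_prsms.copy()
        aligned["rt_aligned"] = aligned["rt_min"]
        _, membership = quant.cluster_proteoforms(aligned)
        counts = quant.spectral_counts(membership, small_study.cohort["sample_id"])
        observed_totals = counts.sum(axis=0)
        expected = small_true_prsms.groupby("sample_id").size()
        for s, n in expected.items():
            assert observed_totals[s] == n

    def test_unknown_sample_raises(self):
        catalog, membership, ident, cohort = self.build(observed=103)
        bad = membership.copy()
        bad.loc[bad.index[0], "sample_id"] = "NOT_A_SAMPLE"
        with pytest.raises(ValueError, match="NOT_A_SAMPLE"):
            quant.build_quant_matrices(catalog, bad, ident, cohort)

    def test_zero_noise_catalog_matches_truth_exactly(self):
        ref = synth.make_reference_db(15, seed=80)
        cohort = synth.make_cohort(12, 2, seed=81)
        cfg = synth.SimulationConfig(
            sigma_noise=0.0, pmi_frac=0.0, trait_effects={}, n_modules=0,
            miss_intercept=-50.0, rt_noise_sd=0.0, mass_ppm_sd=0.0,
            rt_warp_dev=0.0, rt_shift_sd=0.0, mean_count=8.0,
            noise_matches_per_entry=0.0,
        )
        study = synth.simulate_study(ref, cohort, cfg, seed=82)
        df = study.prsms[study.prsms["truth_id"] >= 0].copy()
        warps = quant.align_retention_times(df)
        aligned = quant.apply_warps(df, warps)
        catalog, _ = quant.cluster_proteoforms(aligned)
        assert len(catalog) == len(study.truth.catalog)
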