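"""Germline bundle and repertoire simulator against ground truth."""

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from bcelldev.cleanup import cluster_duplicates
from bcelldev.germline import (
    DEFAULT_BUNDLE_SEED,
    build_germline_bundle,
    load_bundled_germline,
)
from bcelldev.simulate import (
    ProfileError,
    SimulationConfig,
    SubsetProfile,
    default_profiles,
    simulate_repertoire,
)
from bcelldev.usage import usage_frequencies


class TestGermlineBundle:
    def test_gene_counts(self):
        b = load_bundled_germline()
        counts = b.genes.groupby(["locus", "segment"]).size()
        assert counts[("IGH", "V")] >= 25
        assert counts[("IGH", "D")] >= 10
        assert counts[("IGH", "J")] == 6

    def test_v_genes_end_with_in_frame_cys(self):
        b = load_bundled_germline()
        for _, row in b.genes[b.genes["segment"] == "V"].iterrows():
            assert b.v_anchor_codon(row["gene"]) in ("TGT", "TGC")
            # anchor is in frame: everything before it is whole codons
            seq = row["sequence"]
            assert (len(seq) - 6 - 3) % 3 == 0

    def test_j_anchor_is_trp_or_phe_followed_by_gly(self):
        b = load_bundled_germline()
        for _, row in b.genes[b.genes["segment"] == "J"].iterrows():
            anchor = b.j_anchor_codon(row["gene"])
            expected = "W" if row["locus"] == "IGH" else "F"
            assert str(Seq(anchor).translate()) == expected
            assert b.j_rest(row["gene"]).startswith("GG")

    def test_regeneration_is_bit_identical(self):
        b1 = build_germline_bundle(DEFAULT_BUNDLE_SEED)
        b2 = build_germline_bundle(DEFAULT_BUNDLE_SEED)
        pd.testing.assert_frame_equal(b1.genes, b2.genes)
        bundled = load_bundled_germline()
        pd.testing.assert_frame_equal(b1.genes, bundled.genes)


class TestDefaultProfiles:
    def test_frequency_maps_sum_to_one(self):
        for chain in ("IGH", "IGK", "IGL"):
            for p in default_profiles(chain):
                assert sum(p.v_family_freqs.values()) == pytest.approx(1.0)
                assert sum(p.j_family_freqs.values()) == pytest.approx(1.0)
                if chain == "IGH":
                    assert sum(p.d_family_freqs.values()) == pytest.approx(1.0)

    def test_planted_heavy_chain_deltas(self):
        by_subset = {p.subset: p for p in default_profiles("IGH")}
        v3 = lambda s: by_subset[s].v_family_freqs[3]
        assert 100 * (v3("preB") - v3("naive")) == pytest.approx(14.0)
        j6 = lambda s: by_subset[s].j_family_freqs[6]
        others = np.mean([j6("preB"), j6("immature"), j6("naive")])
        assert 100 * (j6("transitional") - others) > 9.0
        d2 = lambda s: by_subset[s].d_family_freqs[2]
        assert 100 * (d2("preB") - d2("naive")) == pytest.approx(7.0)
        d3 = lambda s: by_subset[s].d_family_freqs[3]
        d3_others = np.mean([d3("preB"), d3("immature"), d3("naive")])
        assert 100 * (d3("transitional") - d3_others) == pytest.approx(5.5)

    def test_planted_lambda_deltas_and_flat_kappa(self):
        lam = {p.subset: p for p in default_profiles("IGL")}
        assert 100 * (lam["naive"].v_family_freqs[2]
                      - lam["immature"].v_family_freqs[2]) == pytest.approx(12.0)
        assert 100 * (lam["naive"].j_family_freqs[1]
                      - lam["immature"].j_family_freqs[1]) == pytest.approx(3.5)
        kap = {p.subset: p for p in default_profiles("IGK")}
        for subset in ("transitional", "naive"):
            assert kap[subset].v_family_freqs == kap["immature"].v_family_freqs

    def test_light_chains_have_three_subsets(self):
        assert len(default_profiles("IGH")) == 4
        assert len(default_profiles("IGK")) == 3
        assert len(default_profiles("IGL")) == 3

    def test_cdr3_length_means_shrink_toward_naive(self):
        by_subset = {p.subset: p for p in default_profiles("IGH")}
        means = [by_subset[s].cdr3_len_mean
                 for s in ("preB", "immature", "transitional", "naive")]
        assert means == sorted(means, reverse=True)

    def test_profile_validation(self):
        with pytest.raises(ProfileError):
            SubsetProfile(subset="preB", chain="IGH",
                          v_family_freqs={3: 0.5},
                          j_family_freqs={6: 1.0},
                          d_family_freqs={2: 1.0})
        with pytest.raises(ProfileError):
            SubsetProfile(subset="preB", chain="IGH",
                          v_family_freqs={}, j_family_freqs={6: 1.0},
                          d_family_freqs={2: 1.0})


class TestSimulateRepertoire:
    def test_noise_free_simulation_is_identity_under_dedup(self):
        cfg = SimulationConfig(n_donors=2, clonotypes_per_subset=100, seed=3,
                               pcr_copies_mean=1.0, error_rate_sub=0.0,
                               error_rate_indel=0.0)
        res = simulate_repertoire(cfg, chain="IGH")
        assert len(res.records) == res.truth.n_true_clonotypes
        clonos = cluster_duplicates(res.records, threshold=0)
        # a rare CDR3 collision between two true clonotypes may merge them
        assert len(clonos) >= 0.99 * res.truth.n_true_clonotypes

    def test_truth_count_matches_request(self):
        cfg = SimulationConfig(n_donors=3, clonotypes_per_subset=50, seed=2)
        res = simulate_repertoire(cfg, chain="IGH")
        assert res.truth.n_true_clonotypes == 3 * 4 * 50
        assert set(res.truth.clone_of.values()) == {
            res.truth.clone_of[r.read_id] for r in res.records
        }

    def test_empirical_family_frequency_close_to_profile(self):
        cfg = SimulationConfig(n_donors=1, clonotypes_per_subset=10000,
                               seed=4, pcr_copies_mean=1.0,
                               error_rate_sub=0.0, error_rate_indel=0.0)
        res = simulate_repertoire(cfg, chain="IGH")
        preB = [r for r in res.records if r.subset == "preB"]
        clonos = cluster_duplicates(preB, threshold=0)
        table = usage_frequencies(clonos, axis="family", chain="IGH")
        v3 = table.wide()[("IGHV3")].iloc[0]
        assert v3 == pytest.approx(55.0, abs=1.5)

    def test_determinism_byte_identical(self):
        cfg = SimulationConfig(n_donors=2, clonotypes_per_subset=60, seed=13)
        df1 = simulate_repertoire(cfg, chain="IGH").to_frame()
        df2 = simulate_repertoire(cfg, chain="IGH").to_frame()
        pd.testing.assert_frame_equal(df1, df2)

    def test_productive_fraction_and_cdr3_consistency(self):
        cfg = SimulationConfig(n_donors=2, clonotypes_per_subset=300, seed=5,
                               pcr_copies_mean=1.0, error_rate_sub=0.0,
                               error_rate_indel=0.0)
        res = simulate_repertoire(cfg, chain="IGH")
        frac = np.mean([r.productive for r in res.records])
        assert frac == pytest.approx(2 / 3, abs=0.05)
        for r in res.records:
            if r.productive:
                assert len(r.cdr3_aa) == len(r.cdr3_nt) // 3
                assert "*" not in r.cdr3_aa
            else:
                assert r.cdr3_aa == ""

    def test_light_chain_simulation_has_no_d_calls(self):
        cfg = SimulationConfig(n_donors=2, clonotypes_per_subset=50, seed=6)
        res = simulate_repertoire(cfg, chain="IGL")
        assert all(r.d_call is None for r in res.records)
        assert {r.subset for r in res.records} == {
            "immature", "transitional", "naive"
        }

    def test_older_donors_keep_longer_naive_cdr3(self):
        cfg = SimulationConfig(
            n_donors=2, donor_ages=[25.0, 85.0],
            clonotypes_per_subset=3000, seed=8, pcr_copies_mean=1.0,
            error_rate_sub=0.0, error_rate_indel=0.0,
        )
        res = simulate_repertoire(cfg, chain="IGH")
        naive = pd.DataFrame(
            [(r.donor_id, len(r.cdr3_aa)) for r in res.records
             if r.subset == "naive" and r.productive],
            columns=["donor", "len"],
        )
        means = naive.groupby("donor")["len"].mean()
        assert means["D02"] - means["D01"] > 0.4  # 0.25 aa/decade * 3.5 decades

    def test_dedup_stress_within_two_percent(self):
        cfg = SimulationConfig(n_donors=1, clonotypes_per_subset=1500,
                               seed=21, pcr_copies_mean=3.0,
                               error_rate_sub=0.002, error_rate_indel=0.0)
        res = simulate_repertoire(cfg, chain="IGH")
        clonos = cluster_duplicates(res.records, threshold=1)
        truth = res.truth.n_true_clonotypes
        assert abs(len(clonos) - truth) / truth <= 0.02
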