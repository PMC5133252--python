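"""Usage frequencies, subset comparisons, and the mixed-model LRT."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from bcelldev.cleanup import cluster_duplicates
from bcelldev.usage import (
    combination_tensor,
    compare_usage,
    mixed_model_lrt,
    random_intercept_loglik,
    usage_frequencies,
)

from conftest import make_read


def _clonotype(i, donor="D01", subset="preB", v="IGHV3-23", d="IGHD3-10",
               j="IGHJ4", chain="IGH"):
    nts = "ACGT"
    cdr3 = "".join(nts[(i >> (2 * k)) % 4] for k in range(9))
    read = make_read(read_id=f"c{donor}{subset}{i}", donor_id=donor,
                     subset=subset, chain=chain, v_call=v, d_call=d,
                     j_call=j, cdr3_nt=cdr3, cdr3_aa="")
    return cluster_duplicates([read], threshold=0)[0]


class TestUsageFrequencies:
    def test_simple_family_fractions(self):
        clonos = [
            _clonotype(0, v="IGHV3-23"), _clonotype(1, v="IGHV3-30"),
            _clonotype(2, v="IGHV1-18"), _clonotype(3, v="IGHV4-34"),
        ]
        table = usage_frequencies(clonos, axis="family", chain="IGH")
        wide = table.wide()
        assert wide.loc[("D01", "preB"), "IGHV3"] == pytest.approx(50.0)
        assert wide.loc[("D01", "preB"), "IGHV1"] == pytest.approx(25.0)

    def test_single_clonotype_is_100_percent(self):
        table = usage_frequencies([_clonotype(0)], axis="gene", chain="IGH")
        assert table.wide().loc[("D01", "preB"), "IGHV3-23"] == 100.0

    def test_hand_tally_on_mixed_fixture(self):
        clonos = []
        i = 0
        for donor in ("D01", "D02"):
            for v, n in (("IGHV3-23", 3), ("IGHV1-18", 1), ("IGHV5-51", 1)):
                for _ in range(n):
                    clonos.append(_clonotype(i, donor=donor, v=v))
                    i += 1
        table = usage_frequencies(clonos, axis="family", chain="IGH")
        wide = table.wide()
        for donor in ("D01", "D02"):
            assert wide.loc[(donor, "preB"), "IGHV3"] == pytest.approx(60.0)
            assert table.denominators[(donor, "preB")] == 5

    def test_frequencies_sum_to_100(self, small_heavy_sim):
        clonos = cluster_duplicates(small_heavy_sim.records[:2000])
        for axis, seg in (("family", "V"), ("family", "J"), ("gene", "V"),
                          ("family_combination", None)):
            table = usage_frequencies(clonos, axis=axis, chain="IGH",
                                      segment=seg or "V")
            sums = table.data.groupby(["donor_id", "subset"])["frequency"].sum()
            assert np.allclose(sums, 100.0, atol=1e-9)

    def test_clonotypes_not_reads(self):
        reads = [make_read(read_id=f"r{i}", cdr3_nt="ACGACGACG",
                           v_call="IGHV3-23") for i in range(5)]
        reads.append(make_read(read_id="r9", cdr3_nt="TTTTTTTTT",
                               v_call="IGHV1-18"))
        clonos = cluster_duplicates(reads, threshold=0)
        table = usage_frequencies(clonos, axis="family", chain="IGH")
        # 5 reads collapse to 1 clonotype: family split is 50/50, not 5/1
        assert table.wide().loc[("D01", "preB"), "IGHV3"] == pytest.approx(50.0)


class TestCombinationTensor:
    def test_single_combination_all_mass(self):
        clonos = [_clonotype(i) for i in range(4)]
        table = combination_tensor(clonos, chain="IGH")
        assert table.wide().loc[("D01", "preB"), "V3-D3-J4"] == 100.0

    def test_marginalization_reproduces_v_family_usage(self, small_heavy_sim):
        clonos = cluster_duplicates(small_heavy_sim.records[:2000])
        combo = combination_tensor(clonos, chain="IGH").wide()
        vfam = usage_frequencies(clonos, axis="family", chain="IGH").wide()
        marg = {}
        for col in combo.columns:
            v = col.split("-")[0].replace("V", "IGHV")
            marg[v] = marg.get(v, 0) + combo[col]
        for fam in vfam.columns:
            assert np.allclose(marg[fam], vfam[fam], atol=1e-9)


class TestCompareUsage:
    def _table(self, shift=0.0, n_donors=8, seed=3):
        rng = np.random.default_rng(seed)
        rows = []
        for d in range(n_donors):
            donor = f"D{d:02d}"
            for subset in ("preB", "naive"):
                base = {"IGHV1": 20.0, "IGHV3": 55.0, "IGHV4": 25.0}
                if subset == "naive":
                    base["IGHV3"] -= shift
                    base["IGHV1"] += shift / 2
                    base["IGHV4"] += shift / 2
                noise = rng.normal(0, 1.0, 3)
                noise -= noise.mean()
                for (k, v), e in zip(base.items(), noise):
                    rows.append({"donor_id": donor, "subset": subset,
                                 "key": k, "frequency": v + e})
        from bcelldev.usage import UsageTable

        return UsageTable(axis="family", chain="IGH",
                          data=pd.DataFrame(rows))

    def test_identical_groups_adjusted_p_near_one(self):
        from bcelldev.usage import UsageTable

        rows = [
            {"donor_id": f"D{d}", "subset": s, "key": "IGHV3",
             "frequency": 50.0}
            for d in range(4) for s in ("preB", "naive")
        ]
        table = UsageTable(axis="family", chain="IGH",
                           data=pd.DataFrame(rows))
        results = compare_usage(table, subsets=("preB", "naive"))
        assert all(r.adjusted_p >= 0.99 for r in results)

    def test_planted_shift_detected(self):
        table = self._table(shift=20.0)
        results = compare_usage(table, subsets=("preB", "naive"))
        v3 = next(r for r in results if r.key == "IGHV3")
        assert v3.adjusted_p < 0.05
        assert v3.effect == pytest.approx(-20.0, abs=2.0)

    def test_null_is_not_rejected(self):
        results = compare_usage(self._table(shift=0.0),
                                subsets=("preB", "naive"))
        assert all(r.adjusted_p > 0.05 for r in results)

    def test_effect_sign_convention(self):
        results = compare_usage(self._table(shift=10.0),
                                subsets=("preB", "naive"))
        v3 = next(r for r in results if r.key == "IGHV3")
        assert v3.groups == ("preB", "naive")
        assert v3.effect < 0  # naive minus preB

    def test_adjusted_at_least_raw(self):
        for r in compare_usage(self._table(shift=5.0)):
            assert 0.0 <= r.raw_p <= r.adjusted_p <= 1.0


def _mixed_data(n_donors=6, n_per=20, effect=0.0, seed=5, donor_sd=0.5):
    rng = np.random.default_rng(seed)
    rows = []
    for d in range(n_donors):
        b = rng.normal(0, donor_sd)
        for subset in ("preB", "naive"):
            mu = effect if subset == "naive" else 0.0
            for v in rng.normal(mu + b, 1.0, n_per):
                rows.append({"donor_id": f"D{d:02d}", "subset": subset,
                             "length": v})
    return pd.DataFrame(rows)


class TestMixedModelLRT:
    def test_zero_variance_gives_zero_statistic(self):
        df = _mixed_data()
        df["length"] = 12.0
        res = mixed_model_lrt(df, "length")
        assert res.statistic == 0.0 and res.raw_p == 1.0

    def test_strong_effect_detected(self):
        res = mixed_model_lrt(_mixed_data(effect=1.0), "length")
        assert res.raw_p < 1e-4
        assert res.effect == pytest.approx(1.0, abs=0.3)

    def test_ml_fit_matches_direct_likelihood_optimization(self):
        """statsmodels ML solution vs scipy optimization of the exact
        4-parameter random-intercept likelihood on a 50-observation set."""
        df = _mixed_data(n_donors=5, n_per=5, effect=0.8, seed=9)
        y = df["length"].to_numpy()
        X = np.column_stack(
            [np.ones(len(df)), (df["subset"] == "naive").to_numpy(float)]
        )
        groups = df["donor_id"].to_numpy()

        def neg_ll(theta):
            b0, b1, log_sb, log_se = theta
            return -random_intercept_loglik(
                y, X, groups, np.array([b0, b1]),
                np.exp(log_sb), np.exp(log_se),
            )

        best = min(
            (
                optimize.minimize(neg_ll, x0, method="Nelder-Mead",
                                  options={"xatol": 1e-8, "fatol": 1e-10,
                                           "maxiter": 5000})
                for x0 in ([0, 0, -1, 0], [0, 1, 0, 0], [1, 0, -2, -1])
            ),
            key=lambda r: r.fun,
        )
        import statsmodels.formula.api as smf

        fit = smf.mixedlm("length ~ C(subset)", df,
                          groups=df["donor_id"]).fit(reml=False)
        assert fit.llf == pytest.approx(-best.fun, abs=1e-3)

    def test_requires_replication(self):
        df = _mixed_data(n_donors=2)
        with pytest.raises(ValueError):
            mixed_model_lrt(df, "length")

    def test_lrt_p_matches_chi2_of_statistic(self):
        res = mixed_model_lrt(_mixed_data(effect=0.5), "length")
        assert res.raw_p == pytest.approx(stats.chi2.sf(res.statistic, 1))
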