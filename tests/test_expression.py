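import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from _oracles import bh_stepup
from conftest import nb_counts
from cernapipe.containers import CountMatrix
from cernapipe.expression import (bh_adjust, call_de, fpkm, nb_wald_test,
                                  size_factors, size_factors_from_totals,
                                  srpbm, tpm)


def _cm(values, cls="mRNA", lengths=None):
    df = pd.DataFrame(values)
    df.index = pd.Index([f"f{i}" for i in range(len(df))], name="feature_id")
    df.columns = [f"s{j}" for j in range(df.shape[1])]
    if lengths is not None:
        lengths = pd.Series(lengths, index=df.index)
    return CountMatrix(df, cls, lengths)


class TestNormalization:
    def test_fpkm_unit_case(self):
        # one read per kilobase per million mapped reads is FPKM 1
        cm = _cm([[10], [999_990]], lengths=[1000, 100])
        out = fpkm(cm)
        assert out.values.iloc[0, 0] == pytest.approx(10.0)

    def test_fpkm_zero_feature(self, toy_counts):
        vals = toy_counts.values.copy()
        vals.loc["f3", :] = 0
        out = fpkm(CountMatrix(vals, "mRNA", toy_counts.lengths))
        assert (out.values.loc["f3"] == 0).all()

    def test_fpkm_matches_hand_formula(self, toy_counts):
        out = fpkm(toy_counts).values
        totals = toy_counts.values.sum(axis=0)
        for f in toy_counts.feature_ids:
            for s in toy_counts.sample_ids:
                expected = toy_counts.values.loc[f, s] / (
                    (toy_counts.lengths[f] / 1e3) * (totals[s] / 1e6))
                assert out.loc[f, s] == pytest.approx(expected)

    def test_fpkm_requires_lengths(self, toy_counts):
        cm = CountMatrix(toy_counts.values, "mRNA", None)
        with pytest.raises(ValueError, match="length"):
            fpkm(cm)

    def test_tpm_single_feature_is_1e6(self):
        out = tpm(_cm([[7, 3]], lengths=[800]))
        assert np.allclose(out.values.to_numpy(), 1e6)

    def test_tpm_equal_features_split_evenly(self):
        out = tpm(_cm([[10, 4], [10, 4]], lengths=[500, 500]))
        assert np.allclose(out.values.to_numpy(), 5e5)

    def test_tpm_columns_sum_to_1e6(self):
        rng = np.random.default_rng(0)
        cm = _cm(rng.integers(0, 500, size=(40, 6)) + 1,
                 lengths=rng.integers(200, 5000, size=40))
        sums = tpm(cm).values.sum(axis=0)
        assert np.allclose(sums, 1e6, rtol=1e-6)

    def test_tpm_mirna_without_lengths_is_reads_per_million(self):
        cm = _cm([[30, 1], [70, 3]], cls="miRNA")
        out = tpm(cm).values
        assert out.iloc[0, 0] == pytest.approx(3e5)
        assert out.iloc[1, 1] == pytest.approx(7.5e5)

    def test_srpbm_cases(self):
        cm = _cm([[5, 0]], cls="circRNA")
        mapped = pd.Series([1_000_000_000, 2_000_000_000],
                           index=cm.values.columns)
        out = srpbm(cm, mapped).values
        assert out.iloc[0, 0] == pytest.approx(5.0)
        assert out.iloc[0, 1] == 0.0
        with pytest.raises(ValueError):
            srpbm(cm, pd.Series([0, 1], index=cm.values.columns))

    def test_srpbm_hand_computed(self, toy_counts):
        cm = CountMatrix(toy_counts.values, "circRNA", None)
        mapped = pd.Series([2e9, 5e8], index=cm.values.columns)
        out = srpbm(cm, mapped).values
        assert out.loc["f2", "s1"] == pytest.approx(100 / 2.0)
        assert out.loc["f2", "s2"] == pytest.approx(50 / 0.5)


class TestSizeFactors:
    def test_identical_columns_give_unity(self):
        cm = _cm([[10, 10], [40, 40], [7, 7]])
        assert np.allclose(size_factors(cm), 1.0)

    def test_doubled_column_closed_form(self):
        # geometric mean sqrt(2)*c => factors 1/sqrt(2), sqrt(2)
        cm = _cm([[10, 20], [50, 100], [3, 6]])
        sf = size_factors(cm)
        assert sf.iloc[0] == pytest.approx(1 / np.sqrt(2))
        assert sf.iloc[1] == pytest.approx(np.sqrt(2))

    def test_column_scaling_equivariance(self):
        # scaling one library by c scales its factor by c relative to the
        # others (the absolute factors also shift through the geometric
        # means, so only the ratio is invariant)
        rng = np.random.default_rng(1)
        base = rng.integers(1, 1000, size=(50, 4))
        sf = size_factors(_cm(base))
        scaled = base.copy()
        scaled[:, 2] *= 3
        sf2 = size_factors(_cm(scaled))
        ratio = (sf2.iloc[2] / sf2.iloc[0]) / (sf.iloc[2] / sf.iloc[0])
        assert ratio == pytest.approx(3.0, rel=1e-9)

    def test_requires_all_positive_feature(self):
        with pytest.raises(ValueError):
            size_factors(_cm([[0, 5], [5, 0]]))

    def test_from_totals_geometric_mean_one(self):
        sf = size_factors_from_totals(pd.Series([1e7, 2e7, 4e7]))
        assert np.exp(np.log(sf).mean()) == pytest.approx(1.0)


class TestNBWald:
    def test_identical_groups_null(self):
        rng = np.random.default_rng(2)
        half = nb_counts(rng, 200.0, 0.05, size=(30, 3))
        cm = _cm(np.hstack([half, half]))
        groups = pd.Series(["A"] * 3 + ["B"] * 3, index=cm.values.columns)
        res = nb_wald_test(cm, groups)
        assert np.allclose(res["log2FC"], 0.0)
        assert np.allclose(res["p"], 1.0)

    def test_group_swap_negates_log2fc(self):
        rng = np.random.default_rng(3)
        cm = _cm(nb_counts(rng, 150.0, 0.05, size=(40, 8)))
        groups = pd.Series(["A"] * 4 + ["B"] * 4, index=cm.values.columns)
        a = nb_wald_test(cm, groups, reference="A")
        b = nb_wald_test(cm, groups, reference="B")
        assert np.allclose(a["log2FC"], -b["log2FC"])
        assert np.allclose(a["p"], b["p"])

    def test_sample_relabeling_within_groups_is_irrelevant(self):
        rng = np.random.default_rng(4)
        cm = _cm(nb_counts(rng, 100.0, 0.1, size=(25, 10)))
        groups = pd.Series(["A"] * 5 + ["B"] * 5, index=cm.values.columns)
        res = nb_wald_test(cm, groups)
        perm = cm.values.columns[[3, 1, 0, 4, 2, 8, 6, 9, 5, 7]]
        res2 = nb_wald_test(CountMatrix(cm.values[perm], "mRNA"),
                            groups[perm])
        assert np.allclose(res["stat"], res2["stat"])

    def test_null_type_one_error_calibrated(self):
        rng = np.random.default_rng(123)
        mu = np.exp(rng.uniform(np.log(50), np.log(1000), 2000))
        cm = _cm(nb_counts(rng, mu[:, None], 0.1, size=(2000, 10)))
        groups = pd.Series(["A"] * 5 + ["B"] * 5, index=cm.values.columns)
        res = nb_wald_test(cm, groups)
        frac = (res["p"] < 0.05).mean()
        assert 0.035 <= frac <= 0.065

    def test_power_on_planted_effects(self):
        # 20% of features carry log2FC = 3; the null majority anchors the
        # size factors so the shift is attributable to the features
        rng = np.random.default_rng(5)
        mu = np.exp(rng.uniform(np.log(100), np.log(1000), 1500))
        fc = np.ones(1500)
        fc[:300] = 8.0
        a = nb_counts(rng, mu[:, None], 0.01, size=(1500, 6))
        b = nb_counts(rng, (fc * mu)[:, None], 0.01, size=(1500, 6))
        cm = _cm(np.hstack([a, b]))
        groups = pd.Series(["A"] * 6 + ["B"] * 6, index=cm.values.columns)
        res = nb_wald_test(cm, groups)
        assert (res["p"].iloc[:300] < 1e-3).mean() >= 0.95

    def test_rejects_small_groups(self):
        cm = _cm([[1, 2, 3]])
        groups = pd.Series(["A", "A", "B"], index=cm.values.columns)
        with pytest.raises(ValueError):
            nb_wald_test(cm, groups)


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_worked_stepup_case(self):
        out = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_rejects_out_of_range(self):
        for bad in ([0.0, 0.5], [0.5, 1.2], [np.nan, 0.1]):
            with pytest.raises(ValueError):
                bh_adjust(bad)

    def test_matches_bruteforce_on_random_vectors(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            p = rng.uniform(1e-12, 1.0, size=rng.integers(1, 400))
            assert np.allclose(bh_adjust(p), bh_stepup(p), atol=0, rtol=1e-12)

    @given(st.lists(st.floats(min_value=1e-9, max_value=1.0), min_size=1,
                    max_size=60))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_padj_dominates_p(self, p):
        assert (bh_adjust(p) >= np.asarray(p) - 1e-15).all()


class TestCallDE:
    @pytest.mark.parametrize("lfc,padj,expected", [
        (1.5, 0.01, "up"),
        (-0.8, 1e-6, "ns"),
        (-2.0, 0.049, "down"),
        (1.0, 0.05, "ns"),    # padj not strictly below the cutoff
        (1.0, 0.049, "up"),   # |log2FC| >= cut is inclusive
    ])
    def test_direction_thresholds(self, lfc, padj, expected):
        rec = pd.DataFrame({"log2FC": [lfc], "p": [min(padj, 1.0)],
                            "padj": [padj]}, index=["f"])
        table, _ = call_de(rec, 1.0, 0.05)
        assert table["direction"].iloc[0] == expected

    def test_counts_consistent_and_order_invariant(self):
        rng = np.random.default_rng(6)
        rec = pd.DataFrame({
            "log2FC": rng.normal(0, 2, 100),
            "p": rng.uniform(1e-6, 1, 100)},
            index=[f"g{i}" for i in range(100)])
        t1, c1 = call_de(rec)
        t2, c2 = call_de(rec.sample(frac=1, random_state=0))
        assert c1 == c2
        assert c1["total"] == c1["up"] + c1["down"]
        assert (t1["padj"] >= t1["p"] - 1e-15).all()
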