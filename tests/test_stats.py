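import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps
from hypothesis import given, settings
from hypothesis import strategies as st

from nvuquant import stats as nvs


# ---------------------------------------------------------------------------
# aggregation and normalization


class TestAggregate:
    def _df(self, rows):
        return pd.DataFrame(rows, columns=["animal_id", "group", "metric",
                                           "value"])

    def test_mean_over_images(self):
        df = self._df([("m1", "g", "x", 2.0), ("m1", "g", "x", 4.0)])
        out = nvs.aggregate_per_animal(df)
        assert len(out) == 1
        assert out["value"].iloc[0] == 3.0

    def test_passthrough_single_images(self):
        df = self._df([("m1", "g", "x", 1.0), ("m2", "g", "x", 5.0)])
        out = nvs.aggregate_per_animal(df)
        assert sorted(out["value"]) == [1.0, 5.0]

    def test_unbalanced_images_do_not_reweight(self):
        # m1 has 3 images at 0, m2 has 1 image at 6; animal-level group
        # mean is 3, while image-pooled mean would be 1.5
        df = self._df(
            [("m1", "g", "x", 0.0)] * 3 + [("m2", "g", "x", 6.0)]
        )
        out = nvs.aggregate_per_animal(df)
        assert out["value"].mean() == 3.0
        assert df["value"].mean() == 1.5

    def test_missing_animal_id(self):
        df = self._df([(None, "g", "x", 1.0)])
        with pytest.raises(ValueError):
            nvs.aggregate_per_animal(df)


class TestRelativeToControl:
    def _df(self, triples):
        return pd.DataFrame(
            [
                {"animal_id": f"m{i}", "group": g, "metric": "x", "value": v}
                for i, (g, v) in enumerate(triples)
            ]
        )

    def test_control_vs_itself(self):
        df = self._df([("young", 4.0), ("young", 6.0)])
        _, summary = nvs.relative_to_control(df, "young")
        assert summary["relative_mean"].iloc[0] == pytest.approx(1.0)

    def test_treated_scaling(self):
        df = self._df([("young", 10.0), ("young", 10.0),
                       ("aged", 25.0), ("aged", 35.0)])
        norm, summary = nvs.relative_to_control(df, "young")
        aged = summary[summary["group"] == "aged"]
        assert aged["relative_mean"].iloc[0] == pytest.approx(3.0)
        assert sorted(norm[norm["group"] == "aged"]["value"]) == [2.5, 3.5]

    def test_sem(self):
        df = self._df([("young", 1.0), ("young", 2.0), ("young", 3.0)])
        _, summary = nvs.relative_to_control(df, "young")
        # SEM of [1,2,3] is sd/sqrt(3) = 0.5774, then scaled by mean 2
        assert summary["sem"].iloc[0] == pytest.approx(
            (1.0 / np.sqrt(3)) / 2.0
        )

    def test_scale_equivariance(self):
        df = self._df([("young", 3.0), ("young", 5.0), ("aged", 9.0),
                       ("aged", 13.0)])
        n1, _ = nvs.relative_to_control(df, "young")
        df2 = df.copy()
        df2["value"] *= 17.0
        n2, _ = nvs.relative_to_control(df2, "young")
        np.testing.assert_allclose(n1["value"], n2["value"])

    def test_zero_control_mean(self):
        df = self._df([("young", 0.0), ("young", 0.0), ("aged", 1.0)])
        with pytest.raises(ValueError):
            nvs.relative_to_control(df, "young")

    def test_absent_control(self):
        df = self._df([("aged", 1.0)])
        with pytest.raises(ValueError):
            nvs.relative_to_control(df, "young")


# ---------------------------------------------------------------------------
# t test


class TestUnpairedT:
    def test_identical_groups(self):
        r = nvs.unpaired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.t == 0.0
        assert r.p == pytest.approx(1.0)

    def test_swap_antisymmetry(self):
        a, b = [1.0, 2.0, 5.0], [2.0, 4.0, 9.0]
        r1, r2 = nvs.unpaired_t(a, b), nvs.unpaired_t(b, a)
        assert r1.t == pytest.approx(-r2.t)
        assert r1.p == pytest.approx(r2.p)

    def test_hand_quartet_matches_oracle(self):
        # pooled-variance t on [1,2,3,4] vs [3,4,5,6]: sp^2 = 10/6,
        # t = -2 / sqrt(sp^2 / 2) = -2.1909, df = 6, p = 0.07099
        r = nvs.unpaired_t([1, 2, 3, 4], [3, 4, 5, 6])
        assert r.t == pytest.approx(-2.190890230020664, abs=1e-12)
        assert r.df == 6
        assert r.p == pytest.approx(0.07098765432098762, abs=1e-12)
        o = sps.ttest_ind([1, 2, 3, 4], [3, 4, 5, 6])
        assert r.t == pytest.approx(o.statistic, abs=1e-12)
        assert r.p == pytest.approx(o.pvalue, abs=1e-12)

    def test_zero_variance_conventions(self):
        r = nvs.unpaired_t([2.0, 2.0], [2.0, 2.0])
        assert r.p == 1.0
        with pytest.warns(UserWarning):
            r = nvs.unpaired_t([2.0, 2.0], [3.0, 3.0])
        assert r.p == 0.0

    def test_welch_matches_oracle(self, rng):
        a = rng.normal(0, 1, 7)
        b = rng.normal(1, 3, 12)
        r = nvs.unpaired_t(a, b, welch=True)
        o = sps.ttest_ind(a, b, equal_var=False)
        assert r.t == pytest.approx(o.statistic, abs=1e-10)
        assert r.p == pytest.approx(o.pvalue, abs=1e-10)

    def test_min_group_size(self):
        with pytest.raises(ValueError):
            nvs.unpaired_t([1.0], [1.0, 2.0])


# ---------------------------------------------------------------------------
# ANOVA + Tukey


class TestAnovaTukey:
    def test_hand_triple(self):
        r = nvs.anova_tukey([[1, 2, 3], [2, 3, 4], [6, 7, 8]])
        assert r.f == pytest.approx(21.0, abs=1e-12)
        assert r.p == pytest.approx(0.001953125, abs=1e-9)

    def test_identical_constant_groups(self):
        with pytest.warns(UserWarning):
            r = nvs.anova_tukey([[5.0, 5.0], [5.0, 5.0], [5.0, 5.0]])
        assert r.f == 0.0
        assert r.p == 1.0

    def test_location_invariance(self, rng):
        groups = [rng.normal(i, 1, 6) for i in range(3)]
        r1 = nvs.anova_tukey(groups)
        r2 = nvs.anova_tukey([g + 123.4 for g in groups])
        assert r1.f == pytest.approx(r2.f, rel=1e-12)
        np.testing.assert_allclose(
            r1.pairwise["p_adj"], r2.pairwise["p_adj"], rtol=1e-9
        )

    def test_matches_scipy_oracles(self, rng):
        for _ in range(20):
            groups = [
                rng.normal(rng.normal(0, 1), 1, int(rng.integers(3, 9)))
                for _ in range(int(rng.integers(3, 6)))
            ]
            r = nvs.anova_tukey(groups)
            o = sps.f_oneway(*groups)
            assert r.f == pytest.approx(o.statistic, rel=1e-9)
            assert r.p == pytest.approx(o.pvalue, rel=1e-6, abs=1e-12)
            tk = sps.tukey_hsd(*groups)
            for row in r.pairwise.itertuples():
                i, j = int(row.group_a), int(row.group_b)
                assert row.p_adj == pytest.approx(
                    tk.pvalue[i, j], rel=1e-6, abs=1e-9
                )

    def test_two_groups_rejected(self):
        with pytest.raises(ValueError):
            nvs.anova_tukey([[1.0, 2.0], [3.0, 4.0]])


# ---------------------------------------------------------------------------
# correlation


class TestLinearR2:
    def test_exact_line(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        r = nvs.linear_r2(x, 3 * x + 1)
        assert r["r_squared"] == pytest.approx(1.0)

    def test_null_behavior(self, rng):
        x = rng.normal(0, 1, 5000)
        y = rng.normal(0, 1, 5000)
        assert nvs.linear_r2(x, y)["r_squared"] < 0.01

    def test_hand_pairs_match_oracle(self):
        # (1,2),(2,1),(3,4),(4,3),(5,6): r = 10/sqrt(10*14.8) = 0.82199,
        # r^2 = 25/37 = 0.675676
        x = [1, 2, 3, 4, 5]
        y = [2, 1, 4, 3, 6]
        r = nvs.linear_r2(x, y)
        assert r["r_squared"] == pytest.approx(25.0 / 37.0, abs=1e-12)
        o = sps.pearsonr(x, y)
        assert r["r_squared"] == pytest.approx(o.statistic**2, abs=1e-12)
        assert r["p"] == pytest.approx(o.pvalue, abs=1e-12)

    def test_degenerate(self):
        with pytest.raises(ValueError):
            nvs.linear_r2([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


# ---------------------------------------------------------------------------
# ddCt


def ct_table(rows):
    return pd.DataFrame(
        rows, columns=["sample_id", "group", "gene", "replicate", "ct"]
    )


def worked_example_table():
    """Control dCts {5.0, 5.2, 4.8}; treated sample dCt 3.0."""
    rows = []
    gene_cts = {
        ("y1", "young"): 20.0,
        ("y2", "young"): 20.2,
        ("y3", "young"): 19.8,
        ("t1", "aged"): 18.0,
    }
    for (sample, group), ctv in gene_cts.items():
        for rep in range(3):
            rows.append((sample, group, "Gx", rep, ctv))
            rows.append((sample, group, "Actb", rep, 15.0))
    return ct_table(rows)


class TestDdct:
    def test_worked_example(self):
        out = nvs.ddct_fold_change(
            worked_example_table(), ["Actb"], "young"
        )
        by = out.set_index("sample_id")
        assert by.loc["t1", "delta_ct"] == pytest.approx(3.0)
        assert by.loc["t1", "delta_delta_ct"] == pytest.approx(-2.0)
        assert by.loc["t1", "fold_change"] == pytest.approx(4.0)
        assert by.loc["t1", "fold_unsigned"] == pytest.approx(4.0)
        # control signed folds {1.0, -2^0.2, 2^0.2}
        assert by.loc["y1", "fold_change"] == pytest.approx(1.0)
        assert by.loc["y2", "fold_change"] == pytest.approx(-(2**0.2))
        assert by.loc["y3", "fold_change"] == pytest.approx(2**0.2)
        # unsigned branch for every control sample
        assert by.loc["y2", "fold_unsigned"] == pytest.approx(2**-0.2)
        assert by.loc["y3", "fold_unsigned"] == pytest.approx(2**0.2)
        # DE rule: |4 - mean| > 2 sd of control folds
        ctrl = np.array([1.0, -(2**0.2), 2**0.2])
        sd = ctrl.std(ddof=1)
        assert bool(by.loc["t1", "de_flag"]) == (
            abs(4.0 - ctrl.mean()) > 2 * sd
        )
        assert by.loc["t1", "de_flag"]
        assert not by.loc["y1", "de_flag"]

    def test_ddct_zero_is_unit_fold(self):
        tbl = worked_example_table()
        out = nvs.ddct_fold_change(tbl, ["Actb"], "young")
        y1 = out[out["sample_id"] == "y1"].iloc[0]
        assert y1["delta_delta_ct"] == pytest.approx(0.0)
        assert y1["fold_change"] == pytest.approx(1.0)
        assert not y1["de_flag"]

    def test_global_ct_shift_invariance(self):
        tbl = worked_example_table()
        out1 = nvs.ddct_fold_change(tbl, ["Actb"], "young")
        shifted = tbl.copy()
        shifted["ct"] += 3.25  # exactly representable: cancellation is exact
        out2 = nvs.ddct_fold_change(shifted, ["Actb"], "young")
        np.testing.assert_allclose(
            out1["fold_change"], out2["fold_change"], atol=1e-12
        )

    def test_replicates_averaged(self):
        rows = []
        for rep, ctv in enumerate([20.0, 20.4, 20.6]):  # mean 20.333
            rows.append(("y1", "young", "Gx", rep, ctv))
        for s in ("y1", "y2"):
            for rep in range(3):
                rows.append((s, "young", "Actb", rep, 15.0))
        rows += [("y2", "young", "Gx", r, 20.0) for r in range(3)]
        out = nvs.ddct_fold_change(ct_table(rows), ["Actb"], "young")
        y1 = out[out["sample_id"] == "y1"].iloc[0]
        assert y1["ct"] == pytest.approx(np.mean([20.0, 20.4, 20.6]))

    def test_geometric_mean_of_normalizers(self):
        rows = []
        for s, grp in (("y1", "young"), ("y2", "young")):
            rows += [(s, grp, "Gx", 0, 20.0)]
            rows += [(s, grp, "N1", 0, 10.0), (s, grp, "N2", 0, 40.0)]
        out = nvs.ddct_fold_change(ct_table(rows), ["N1", "N2"], "young")
        # geometric mean of {10, 40} is 20, so dCt = 0
        assert out["delta_ct"].iloc[0] == pytest.approx(0.0)

    def test_missing_normalizer_drops_sample(self):
        tbl = worked_example_table()
        tbl = tbl[~((tbl["sample_id"] == "t1") & (tbl["gene"] == "Actb"))]
        with pytest.warns(UserWarning, match="dropped"):
            out = nvs.ddct_fold_change(tbl, ["Actb"], "young")
        assert "t1" not in set(out["sample_id"])

    def test_nonpositive_ct_rejected(self):
        tbl = worked_example_table()
        tbl.loc[0, "ct"] = -1.0
        with pytest.raises(ValueError):
            nvs.ddct_fold_change(tbl, ["Actb"], "young")

    def test_signed_fold_round_trip(self):
        for ddct in (-3.0, -0.5, 0.0, 0.5, 3.0):
            assert nvs.ddct_from_signed_fold(
                nvs.signed_fold(ddct)
            ) == pytest.approx(ddct, abs=1e-12)


@settings(max_examples=50, deadline=None)
@given(st.floats(-20, 20))
def test_signed_fold_branch_consistency(ddct):
    f = nvs.signed_fold(ddct)
    assert abs(f) >= 1.0
    if f >= 1.0:  # up-regulated branch
        assert f == 2.0 ** (-ddct)
    else:  # signed down-regulated branch
        assert f == -(2.0**ddct)
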