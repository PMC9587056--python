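"""TMM factors against a direct-formula oracle, stability statistics on
worked examples, CV%-based reference selection, and HK standardization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fragdex as fx
from fragdex import DataError
from fragdex.normalization import cv_percent, hk_stats, select_hk, standardize, tmm_factors
from fragdex.refpanel import ACCEPTED_REFERENCES, SELF_CONSISTENT_ROWS, candidate_panel


# --------------------------------------------------------------------------
# independent TMM oracle: literal evaluation of the published recipe
# --------------------------------------------------------------------------

def _tmm_oracle(arr: np.ndarray, trim_m=0.30, trim_a=0.05) -> np.ndarray:
    arr = arr.astype(float)
    lib = arr.sum(axis=0)
    q75 = np.array([np.quantile(arr[:, j] / lib[j], 0.75) for j in range(arr.shape[1])])
    ref = int(np.argmin(np.abs(q75 - q75.mean())))
    factors = np.ones(arr.shape[1])
    for j in range(arr.shape[1]):
        if j == ref:
            continue
        keep = (arr[:, j] > 0) & (arr[:, ref] > 0)
        yk, yr = arr[keep, j], arr[keep, ref]
        nk, nr = lib[j], lib[ref]
        m = np.log2((yk / nk) / (yr / nr))
        a = 0.5 * np.log2((yk / nk) * (yr / nr))
        n = m.size
        mr = pd.Series(m).rank().to_numpy()
        ar = pd.Series(a).rank().to_numpy()
        lo_m = np.floor(n * trim_m) + 1
        lo_a = np.floor(n * trim_a) + 1
        sel = ((mr >= lo_m) & (mr <= n + 1 - lo_m) & (ar >= lo_a) & (ar <= n + 1 - lo_a))
        if not sel.any():
            continue
        v = (nk - yk[sel]) / (nk * yk[sel]) + (nr - yr[sel]) / (nr * yr[sel])
        factors[j] = 2.0 ** (np.sum(m[sel] / v) / np.sum(1.0 / v))
    return factors / np.exp(np.mean(np.log(factors)))


class TestTMM:
    def test_proportional_libraries_give_unit_factors(self):
        a = np.array([10, 50, 200, 35, 80, 400], dtype=float)
        counts = pd.DataFrame({"s1": a, "s2": 2 * a},
                              index=[f"f{i}" for i in range(6)])
        f = tmm_factors(counts)
        assert np.allclose(f.to_numpy(), 1.0, atol=1e-12)

    def test_toy_matrix_matches_direct_formula_oracle(self):
        rng = np.random.default_rng(17)
        arr = rng.integers(1, 500, size=(6, 2)).astype(float)
        counts = pd.DataFrame(arr, columns=["s1", "s2"],
                              index=[f"f{i}" for i in range(6)])
        assert np.allclose(tmm_factors(counts).to_numpy(), _tmm_oracle(arr), atol=1e-10)

    def test_random_matrices_match_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            arr = rng.integers(0, 800, size=(40, 5)).astype(float)
            arr[arr.sum(axis=1) == 0, 0] = 1  # avoid empty rows everywhere
            counts = pd.DataFrame(arr, columns=[f"s{j}" for j in range(5)],
                                  index=[f"f{i}" for i in range(40)])
            assert np.allclose(tmm_factors(counts).to_numpy(), _tmm_oracle(arr),
                               atol=1e-10)

    def test_factors_have_unit_geometric_mean(self, small_dataset):
        _, counts, _ = small_dataset
        f = tmm_factors(counts)
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, abs=1e-12)

    def test_sample_permutation_equivariance_and_row_order_invariance(self):
        rng = np.random.default_rng(8)
        arr = rng.integers(1, 600, size=(30, 4)).astype(float)
        counts = pd.DataFrame(arr, columns=list("abcd"),
                              index=[f"f{i}" for i in range(30)])
        f = tmm_factors(counts)
        perm = counts[["c", "a", "d", "b"]]
        fp = tmm_factors(perm)
        assert np.allclose([fp[c] for c in "abcd"], [f[c] for c in "abcd"], atol=1e-12)
        shuffled = counts.sample(frac=1.0, random_state=1)
        assert np.allclose(tmm_factors(shuffled).to_numpy(), f.to_numpy(), atol=1e-12)

    def test_disjoint_support_sample_raises_naming_it(self):
        counts = pd.DataFrame({"s1": [5, 9, 0, 0], "s2": [4, 7, 0, 0],
                               "s3": [0, 0, 3, 8]},
                              index=[f"f{i}" for i in range(4)])
        with pytest.raises(DataError, match="s3"):
            tmm_factors(counts)


class TestHKStats:
    def test_printed_mean_and_sd_reproduce_printed_cv(self):
        panel = candidate_panel()
        for name in SELF_CONSISTENT_ROWS:
            cv = cv_percent(panel.loc[name, "sd"], panel.loc[name, "mean"])
            assert round(float(cv), 2) == panel.loc[name, "cv_percent"]

    def test_constant_vector_has_zero_sd_and_cv(self):
        expr = pd.DataFrame([[100.0, 100.0, 100.0, 100.0]], index=["t1"],
                            columns=list("abcd"))
        stats = hk_stats(expr)
        assert stats.loc["t1", "sd"] == 0.0
        assert stats.loc["t1", "cv_percent"] == 0.0

    def test_textbook_formulas_on_one_to_ten(self):
        expr = pd.DataFrame([np.arange(1, 11, dtype=float)], index=["t1"],
                            columns=[f"s{i}" for i in range(10)])
        stats = hk_stats(expr)
        assert stats.loc["t1", "mean"] == pytest.approx(5.5)
        assert stats.loc["t1", "sd"] == pytest.approx(3.02765, abs=1e-5)
        assert stats.loc["t1", "median"] == pytest.approx(5.5)
        assert stats.loc["t1", "minimum"] == 1.0 and stats.loc["t1", "maximum"] == 10.0

    def test_min_le_median_le_max_invariant(self, small_tmm):
        tmm, _ = small_tmm
        stats = hk_stats(tmm)
        assert (stats["minimum"] <= stats["median"] + 1e-12).all()
        assert (stats["median"] <= stats["maximum"] + 1e-12).all()
        assert (stats["cv_percent"] >= 0).all()

    def test_missing_candidate_is_a_lookup_error(self, small_tmm):
        tmm, _ = small_tmm
        with pytest.raises(DataError, match="nope"):
            hk_stats(tmm, ["nope"])

    @settings(max_examples=40, derandomize=True)
    @given(
        values=st.lists(st.floats(1.0, 1e5), min_size=3, max_size=12),
        scale=st.floats(0.01, 1000.0),
    )
    def test_cv_is_scale_invariant(self, values, scale):
        expr = pd.DataFrame([values], index=["t"],
                            columns=[f"s{i}" for i in range(len(values))])
        a = hk_stats(expr).loc["t", "cv_percent"]
        b = hk_stats(expr * scale).loc["t", "cv_percent"]
        assert np.isclose(a, b, rtol=1e-9) or (np.isnan(a) and np.isnan(b))


class TestSelectHK:
    def test_panel_rule_retains_nine_of_twelve(self):
        kept = select_hk(candidate_panel(), cv_max=20.0)
        assert len(kept) == 9
        assert set(kept) == set(ACCEPTED_REFERENCES)
        assert {"tuba1", "g3pdh", "acta4"}.isdisjoint(kept)

    def test_stricter_ceiling_keeps_only_most_stable(self):
        kept = select_hk(candidate_panel(), cv_max=10.0)
        assert kept == ["tuba", "ef1a0", "ef1g-a"]  # ascending CV%

    def test_zero_cv_everywhere_retains_all(self):
        stats = pd.DataFrame({"cv_percent": [0.0, 0.0]}, index=["a", "b"])
        assert set(select_hk(stats)) == {"a", "b"}

    def test_empty_selection_warns(self):
        stats = pd.DataFrame({"cv_percent": [55.0]}, index=["a"])
        with pytest.warns(UserWarning):
            assert select_hk(stats, cv_max=20.0) == []


class TestStandardize:
    def _toy(self, toy_design):
        cols = list(toy_design.index)
        data = {c: [100.0, 50.0, 80.0] for c in cols}
        expr = pd.DataFrame(data, index=["hk1", "hk2", "g1"])
        expr.loc["hk1", "AZM6_r1"] = 120.0
        expr.loc["hk2", "AZM6_r1"] = 55.0
        return expr

    def test_two_hk_toy_factor_is_mean_of_ratios(self, toy_design):
        info, _, _ = standardize(self._toy(toy_design), ["hk1", "hk2"], toy_design)
        # hk1: 120/100 = 1.2; hk2: 55/50 = 1.1 -> F = 1.15
        assert info.per_sample["AZM6_r1"] == pytest.approx(1.15, abs=1e-12)
        assert info.per_sample["control_r1"] == pytest.approx(1.0, abs=1e-12)

    def test_constant_hk_makes_standardization_an_identity(self, toy_design):
        expr = self._toy(toy_design)
        expr.loc["hk1"] = 100.0
        expr.loc["hk2"] = 50.0
        info, std, rel = standardize(expr, ["hk1", "hk2"], toy_design)
        assert np.allclose(info.per_sample.to_numpy(), 1.0)
        assert np.allclose(std[toy_design.index].to_numpy(), expr.to_numpy())

    def test_control_relative_expression_is_one_by_construction(self, toy_design):
        _, _, rel = standardize(self._toy(toy_design), ["hk1", "hk2"], toy_design)
        assert np.allclose(rel["control"].to_numpy(), 1.0)

    def test_control_mean_factor_is_one(self, small_tmm, small_dataset):
        design, _, truth = small_dataset
        tmm, _ = small_tmm
        frags = [f for f in tmm.index if tmm.loc[f, "gene_id"] in truth.hk_gene_ids]
        info, _, _ = standardize(tmm, frags[:6], design)
        ctrl = design.index[design["treatment"] == "control"]
        assert info.per_sample[ctrl].mean() == pytest.approx(1.0, abs=1e-9)

    def test_hk_relative_expression_near_one_per_treatment(self, small_tmm, small_dataset):
        design, _, truth = small_dataset
        tmm, _ = small_tmm
        stats = hk_stats(tmm)
        panel = [f for f in tmm.index if tmm.loc[f, "group_tag"] == "A"]
        hk = select_hk(stats.loc[panel], 20.0)
        _, _, rel = standardize(tmm, hk, design)
        hk_rel = rel.loc[hk]
        assert np.allclose(hk_rel.mean(axis=0).to_numpy(), 1.0, atol=0.05)

    def test_zero_control_mean_hk_is_an_error(self, toy_design):
        expr = self._toy(toy_design)
        expr.loc["hk1", ["control_r1", "control_r2"]] = 0.0
        with pytest.raises(DataError):
            standardize(expr, ["hk1", "hk2"], toy_design)

    def test_missing_control_group_is_an_error(self, toy_design):
        design = toy_design[toy_design["treatment"] != "control"]
        with pytest.raises(DataError):
            standardize(self._toy(toy_design), ["hk1"], design)
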