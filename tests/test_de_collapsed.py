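"""Collapse/dispersion/exact-test contracts: brute-force split-enumeration
oracle, null super-uniformity, threshold monotonicity, and rank bins."""

import math

import numpy as np
import pandas as pd
import pytest

import fragdex as fx
from fragdex.de_collapsed import (
    call_degs,
    collapse_fragments,
    estimate_common_dispersion,
    nb_analyze,
    nb_exact_test,
    rank_bin,
    rank_degs,
)


# --------------------------------------------------------------------------
# oracle: exhaustive enumeration of all splits of the pooled total with a
# hand-written NB log-pmf (lgamma form)
# --------------------------------------------------------------------------

def _nb_logpmf(x, mean, phi):
    if phi <= 1e-12:
        return x * math.log(mean) - mean - math.lgamma(x + 1)
    r = 1.0 / phi
    return (math.lgamma(x + r) - math.lgamma(r) - math.lgamma(x + 1)
            + r * math.log(r / (r + mean)) + x * math.log(mean / (r + mean)))


def _nb_exact_oracle(s1, s2, n1, n2, phi):
    total = s1 + s2
    mu = total / (n1 + n2)
    probs = [math.exp(_nb_logpmf(x, n1 * mu, phi / n1 if phi > 1e-12 else 0.0)
                      + _nb_logpmf(total - x, n2 * mu, phi / n2 if phi > 1e-12 else 0.0))
             for x in range(total + 1)]
    z = sum(probs)
    obs = probs[s1]
    return sum(p for p in probs if p <= obs * (1 + 1e-10)) / z


def _unit_libs(n):
    return np.full(n, 1.0e6)


class TestCollapse:
    def test_two_fragments_sum_per_column(self):
        counts = pd.DataFrame(
            {"gene_id": ["g1", "g1"], "group_tag": ["B", "B"],
             "s1": [3, 7], "s2": [5, 5]},
            index=pd.Index(["f1", "f2"], name="fragment_id"),
        )
        gc = collapse_fragments(counts)
        assert gc.loc["g1"].tolist() == [10, 10]

    def test_single_fragment_gene_row_unchanged(self):
        counts = pd.DataFrame(
            {"gene_id": ["g1"], "group_tag": ["B"], "s1": [4], "s2": [9]},
            index=pd.Index(["f1"], name="fragment_id"),
        )
        assert collapse_fragments(counts).loc["g1"].tolist() == [4, 9]

    def test_random_matrix_matches_naive_double_loop(self, small_dataset):
        _, counts, _ = small_dataset
        sub = counts.iloc[:50]
        gc = collapse_fragments(sub)
        samples = [c for c in sub.columns if c not in ("gene_id", "group_tag")]
        for gene in gc.index:
            for s in samples:
                expected = 0
                for f in sub.index:  # naive oracle
                    if sub.loc[f, "gene_id"] == gene:
                        expected += sub.loc[f, s]
                assert gc.loc[gene, s] == expected
        assert list(gc.index) == sorted(gc.index)


class TestDispersion:
    def _design(self):
        return pd.DataFrame(
            {"treatment": np.repeat(["control", "A", "B", "C", "D"], 2)},
            index=[f"s{i}" for i in range(10)],
        )

    def _simulate(self, phi, n_genes, seed):
        rng = np.random.default_rng(seed)
        mu = rng.lognormal(5.0, 1.0, size=n_genes)
        m = np.tile(mu[:, None], (1, 10))
        if phi == 0:
            y = rng.poisson(m)
        else:
            size = 1.0 / phi
            y = rng.negative_binomial(size, size / (size + m))
        return pd.DataFrame(y, index=[f"g{i}" for i in range(n_genes)],
                            columns=self._design().index)

    def test_poisson_counts_give_near_zero_dispersion(self):
        est = estimate_common_dispersion(self._simulate(0.0, 2000, 1), self._design())
        assert est <= 0.02

    def test_nb_simulated_dispersion_recovered_within_band(self):
        est = estimate_common_dispersion(self._simulate(0.1, 2000, 2), self._design())
        assert 0.05 <= est <= 0.2

    def test_constant_counts_give_zero(self):
        gc = pd.DataFrame([[50] * 10], index=["g1"], columns=self._design().index)
        assert estimate_common_dispersion(gc, self._design()) == 0.0


class TestNBExact:
    def test_identical_group_sums_give_p_one_and_zero_lfc(self):
        p, lfc = nb_exact_test([5, 5], [5, 5], _unit_libs(2), _unit_libs(2), 0.1)
        assert p == 1.0 and lfc == 0.0

    def test_label_swap_antisymmetry(self):
        p1, l1 = nb_exact_test([12, 9], [3, 4], _unit_libs(2), _unit_libs(2), 0.1)
        p2, l2 = nb_exact_test([3, 4], [12, 9], _unit_libs(2), _unit_libs(2), 0.1)
        assert p1 == pytest.approx(p2, abs=1e-12)
        assert l1 == pytest.approx(-l2, abs=1e-12)

    def test_fifteen_vs_five_matches_split_enumeration_oracle(self):
        p, _ = nb_exact_test([15], [5], _unit_libs(1), _unit_libs(1), 0.1)
        assert p == pytest.approx(_nb_exact_oracle(15, 5, 1, 1, 0.1), abs=1e-10)

    @pytest.mark.parametrize("phi", [0.0, 0.05, 0.3])
    def test_random_totals_up_to_fifty_match_oracle(self, phi):
        rng = np.random.default_rng(11)
        for _ in range(25):
            total = int(rng.integers(1, 51))
            s1 = int(rng.integers(0, total + 1))
            n1, n2 = int(rng.integers(1, 4)), int(rng.integers(1, 4))
            t = np.zeros(n1); t[0] = s1
            c = np.zeros(n2); c[0] = total - s1
            p, _ = nb_exact_test(t, c, _unit_libs(n1), _unit_libs(n2), phi)
            assert p == pytest.approx(_nb_exact_oracle(s1, total - s1, n1, n2, phi),
                                      abs=1e-10)

    def test_zero_total_in_both_groups(self):
        p, lfc = nb_exact_test([0, 0], [0, 0], _unit_libs(2), _unit_libs(2), 0.1)
        assert p == 1.0 and lfc == 0.0

    def test_null_p_values_are_super_uniform(self):
        phi, mu, n = 0.1, 200.0, 2
        rng = np.random.default_rng(42)
        size = 1.0 / phi
        draws = rng.negative_binomial(size, size / (size + mu), size=(2000, 2 * n))
        ps = np.array([
            nb_exact_test(row[:n], row[n:], _unit_libs(n), _unit_libs(n), phi)[0]
            for row in draws
        ])
        for alpha in (0.01, 0.05):
            assert (ps <= alpha).mean() <= alpha + 0.01

    def test_collapse_then_test_equals_direct_test_for_single_fragment_genes(
        self, toy_design
    ):
        rng = np.random.default_rng(3)
        samples = list(toy_design.index)
        counts = pd.DataFrame(rng.integers(5, 400, size=(20, 10)),
                              columns=samples,
                              index=pd.Index([f"f{i}" for i in range(20)],
                                             name="fragment_id"))
        counts.insert(0, "group_tag", "B")
        counts.insert(0, "gene_id", [f"g{i}" for i in range(20)])
        res = nb_analyze(counts, toy_design, phi=0.1).set_index(["gene_id", "comparison"])
        gc = collapse_fragments(counts)
        values = counts[samples]
        for i in range(20):
            assert (gc.loc[f"g{i}"].to_numpy() == values.loc[f"f{i}"].to_numpy()).all()
        # the pipeline result equals testing the fragment rows directly
        lib = values.sum(axis=0).astype(float)
        ctrl_cols = [s for s in samples if toy_design.loc[s, "treatment"] == "control"]
        t_cols = [s for s in samples if toy_design.loc[s, "treatment"] == "AZM6"]
        for i in (0, 7, 19):
            p, lfc = nb_exact_test(
                values.loc[f"f{i}", t_cols].to_numpy(),
                values.loc[f"f{i}", ctrl_cols].to_numpy(),
                lib[t_cols].to_numpy(), lib[ctrl_cols].to_numpy(), 0.1)
            row = res.loc[(f"g{i}", "AZM6")]
            assert row["p"] == pytest.approx(p, abs=1e-12)
            assert row["log2FC"] == pytest.approx(lfc, abs=1e-12)


class TestCalling:
    def _results(self, rows):
        return pd.DataFrame(rows, columns=["gene_id", "comparison", "p", "log2FC"])

    @pytest.mark.parametrize(
        "log2fc,p,expected",
        [(1.5, 0.01, "up"), (0.8, 0.001, "none"), (-1.2, 0.06, "none"),
         (-1.0, 0.05, "down"), (1.0, 0.05, "up")],
    )
    def test_joint_fold_change_and_p_rule(self, log2fc, p, expected):
        res = call_degs(self._results([("g1", "T", p, log2fc)]))
        assert res["call"].iloc[0] == expected

    def test_tightening_thresholds_never_adds_calls(self):
        rng = np.random.default_rng(1)
        rows = [(f"g{i}", "T", rng.uniform(0, 0.2), rng.normal(0, 1.5))
                for i in range(200)]
        loose = call_degs(self._results(rows), fc_threshold=2.0, p_max=0.05)
        tight_fc = call_degs(self._results(rows), fc_threshold=3.0, p_max=0.05)
        tight_p = call_degs(self._results(rows), fc_threshold=2.0, p_max=0.01)
        called = lambda r: set(r.loc[r["call"] != "none", "gene_id"])
        assert called(tight_fc) <= called(loose)
        assert called(tight_p) <= called(loose)

    def test_ranks_are_a_bijection_and_ordered_by_abs_lfc(self):
        rng = np.random.default_rng(2)
        rows = [(f"g{i}", "T", rng.uniform(0, 0.1), rng.normal(0, 2)) for i in range(60)]
        ranked = rank_degs(call_degs(self._results(rows)))
        sig = ranked[ranked["call"] != "none"].sort_values("rank")
        assert sorted(sig["rank"]) == list(range(1, len(sig) + 1))
        assert (sig["log2FC"].abs().diff().dropna() <= 1e-12).all()

    def test_rank_bins_match_boundaries(self):
        assert rank_bin(7) == "top-10"
        assert rank_bin(10) == "top-10"
        assert rank_bin(11) == "10-50"
        assert rank_bin(600) == "500-1500"
        assert rank_bin(1501) == ">1500"
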