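"""Species-level index battery: closed forms, oracles, invariances."""

import numpy as np
import pandas as pd
import pytest

from frugnet.matrix import ConsumptionMatrix, normalize_percent
from frugnet.indices import (bipartite_centrality, core_periphery,
                             correlate_indices, degree_indices,
                             diversity_indices, kl_specialization, nested_rank,
                             species_index_table, species_strength,
                             summarize_indices)
from tests.conftest import enumerate_fixed_marginals


class TestDegreeFamily:
    def test_degree_and_normalized_degree(self, small_matrix):
        t = degree_indices(small_matrix, "plants")
        assert list(t["D"]) == [2, 1, 3, 1]
        assert t.loc["Pc", "ND"] == pytest.approx(1.0)  # interacts with all

    def test_nested_rank_closed_form(self):
        m = ConsumptionMatrix([[1, 1, 1, 1, 1], [1, 1, 1, 0, 0], [1, 0, 0, 0, 0]],
                              ["a", "b", "c"], list("vwxyz"))
        nr = nested_rank(m, "plants")
        assert list(nr) == [0.0, 0.5, 1.0]
        assert nr.mean() == pytest.approx(0.5)

    def test_nested_rank_mean_half_always(self, random_matrix):
        assert nested_rank(random_matrix, "plants").mean() == pytest.approx(0.5)
        assert nested_rank(random_matrix, "frugivores").mean() == pytest.approx(0.5)

    def test_degree_tie_broken_by_total_weight(self):
        m = ConsumptionMatrix([[5, 1, 0], [2, 1, 0]], ["heavy", "light"],
                              ["x", "y", "z"])
        nr = nested_rank(m, "plants")
        assert nr["heavy"] == 0.0 and nr["light"] == 1.0

    def test_single_species_level_errors(self):
        m = ConsumptionMatrix([[1, 2]], ["only"], ["x", "y"])
        with pytest.raises(ValueError, match="at least 2"):
            nested_rank(m, "plants")


class TestCentrality:
    def test_star_projection_hub_takes_all_betweenness(self):
        # hub shares partners with every leaf; leaves share nothing pairwise
        vals = np.zeros((5, 4))
        vals[0] = 1            # hub uses all 4 frugivores
        for leaf in range(1, 5):
            vals[leaf, leaf - 1] = 1   # each leaf uses exactly one
        m = ConsumptionMatrix(vals, [f"p{i}" for i in range(5)],
                              [f"f{j}" for j in range(4)])
        t = bipartite_centrality(m, "plants")
        assert t.loc["p0", "WB"] == pytest.approx(1.0)
        assert np.allclose(t.loc["p1":, "WB"], 0.0)

    def test_path_projection_betweenness_enumeration(self):
        # plants a-b-c-d in a path: shortest paths by hand give raw
        # betweenness (0, 2, 2, 0)
        vals = np.array([[1, 0, 0],
                         [1, 1, 0],
                         [0, 1, 1],
                         [0, 0, 1]], dtype=float)
        m = ConsumptionMatrix(vals, list("abcd"), ["x", "y", "z"])
        t = bipartite_centrality(m, "plants")
        assert np.allclose(t["WB"], np.array([0, 2, 2, 0]) / 4)

    def test_wb_wc_sum_to_one(self, random_matrix):
        for level in ("plants", "frugivores"):
            t = bipartite_centrality(random_matrix, level)
            assert t["WB"].sum() == pytest.approx(1.0) or t["WB"].sum() == 0
            assert t["WC"].sum() == pytest.approx(1.0)

    def test_disconnected_component_handled(self):
        vals = np.array([[1, 1, 0, 0], [1, 1, 0, 0], [0, 0, 1, 1], [0, 0, 1, 1]],
                        dtype=float)
        m = ConsumptionMatrix(vals, list("abcd"), list("wxyz"))
        t = bipartite_centrality(m, "plants")
        assert np.isfinite(t.to_numpy()).all()
        assert t["WC"].sum() == pytest.approx(1.0)


class TestStrengthAndDiversity:
    def test_sole_plant_strength_equals_frugivore_count(self):
        m = ConsumptionMatrix([[3, 7, 2]], ["only"], ["x", "y", "z"])
        assert species_strength(m, "plants")["only"] == pytest.approx(3.0)

    def test_strength_sums_to_nonempty_partner_count(self, random_matrix):
        ss = species_strength(random_matrix, "plants")
        n_nonempty = int((random_matrix.values.sum(axis=0) > 0).sum())
        assert ss.sum() == pytest.approx(n_nonempty)

    def test_effective_partners_closed_forms(self):
        m = ConsumptionMatrix([[2, 2], [4, 0]], ["even", "single"], ["x", "y"])
        t = diversity_indices(m, "plants")
        assert t.loc["even", "EP"] == pytest.approx(2.0)
        assert t.loc["single", "EP"] == pytest.approx(1.0)
        assert t.loc["single", "SSP"] == pytest.approx(1.0)

    def test_ssp_zero_for_uniform_row(self):
        m = ConsumptionMatrix([[3, 3, 3, 3], [1, 0, 0, 0]], ["u", "s"], list("wxyz"))
        t = diversity_indices(m, "plants")
        assert t.loc["u", "SSP"] == pytest.approx(0.0)
        assert t.loc["s", "SSP"] == pytest.approx(1.0)

    def test_zero_total_species_reported_missing(self):
        m = ConsumptionMatrix([[0, 0], [1, 2]], ["empty", "ok"], ["x", "y"])
        t = diversity_indices(m, "plants")
        assert np.isnan(t.loc["empty", "EP"]) and np.isnan(t.loc["empty", "SSP"])


class TestKLSpecialization:
    def test_opportunist_has_zero_d(self):
        # row proportional to the column marginals -> d = 0 = d'
        vals = np.array([[6.0, 3.0, 1.0], [6.0, 3.0, 1.0]])
        m = ConsumptionMatrix(vals, ["a", "b"], ["x", "y", "z"])
        t = kl_specialization(m, "plants")
        assert np.allclose(t["d"], 0.0, atol=1e-12)
        assert np.allclose(t["d_prime"], 0.0)

    def test_diagonal_matrix_maximally_specialized(self):
        m = ConsumptionMatrix([[1, 0], [0, 1]], ["a", "b"], ["x", "y"])
        t = kl_specialization(m, "plants")
        assert np.allclose(t["d"], np.log(2))
        assert np.allclose(t["d_prime"], 1.0)

    def test_heuristic_bounds_bracket_exhaustive_truth(self):
        """Brute force: over every integer matrix sharing the marginals,
        the observed d must lie within [d_min, d_max] as computed by the
        heuristics for the shared marginal profile."""
        rng = np.random.default_rng(10)
        for _ in range(6):
            while True:
                arr = rng.integers(0, 3, size=(3, 3)).astype(float)
                if arr.sum() <= 9 and (arr.sum(axis=1) > 0).all() \
                        and (arr.sum(axis=0) > 0).all():
                    break
            row_t = arr.sum(axis=1).astype(int)
            col_t = arr.sum(axis=0).astype(int)
            M = arr.sum()
            q = col_t / M
            # collect true per-row d range over all matrices w/ same marginals
            true_d = {i: [] for i in range(3)}
            for alt in enumerate_fixed_marginals(row_t, col_t):
                for i in range(3):
                    p = alt[i] / alt[i].sum()
                    nz = p > 0
                    true_d[i].append(float((p[nz] * np.log(p[nz] / q[nz])).sum()))
            m = ConsumptionMatrix(arr, list("abc"), list("xyz"))
            t = kl_specialization(m, "plants")
            for i, lab in enumerate("abc"):
                lo, hi = min(true_d[i]), max(true_d[i])
                assert lo - 1e-9 <= t.loc[lab, "d"] <= hi + 1e-9
                assert 0.0 <= t.loc[lab, "d_prime"] <= 1.0

    def test_single_partner_level_gives_zero_dprime(self):
        m = ConsumptionMatrix([[4.0], [2.0]], ["a", "b"], ["only"])
        t = kl_specialization(m, "plants")
        assert np.allclose(t["d"], 0.0)
        assert np.allclose(t["d_prime"], 0.0)


class TestCorePeriphery:
    def test_hub_is_core(self):
        vals = np.zeros((5, 10))
        vals[0, :] = 1
        for i in range(1, 5):
            vals[i, 0] = 1
        m = ConsumptionMatrix(vals, [f"p{i}" for i in range(5)],
                              [f"f{j}" for j in range(10)])
        t = core_periphery(m, "plants")
        assert t.loc["p0", "core_flag"] == "core"
        assert (t.iloc[1:]["core_flag"] == "periphery").all()

    def test_equal_degrees_no_core(self):
        m = ConsumptionMatrix([[1, 1], [1, 1]], ["a", "b"], ["x", "y"])
        with pytest.warns(UserWarning, match="all degrees equal"):
            t = core_periphery(m, "plants")
        assert (t["core_flag"] == "periphery").all()

    def test_gaining_partners_never_demotes(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            vals = (rng.random((6, 8)) < 0.4).astype(float)
            vals[vals.sum(axis=1) == 0, 0] = 1
            m = ConsumptionMatrix(vals, [f"p{i}" for i in range(6)],
                                  [f"f{j}" for j in range(8)])
            t = core_periphery(m, "plants")
            zeros = np.argwhere(vals == 0)
            if not len(zeros):
                continue
            i, j = zeros[rng.integers(len(zeros))]
            vals2 = vals.copy()
            vals2[i, j] = 1
            t2 = core_periphery(ConsumptionMatrix(
                vals2, [f"p{i}" for i in range(6)],
                [f"f{j}" for j in range(8)]), "plants")
            if t.iloc[i]["core_flag"] == "core":
                assert t2.iloc[i]["core_flag"] == "core"


class TestTableAndSummaries:
    def test_full_table_columns_and_conversions(self, random_matrix):
        t = species_index_table(random_matrix, "plants")
        for col in ("D", "ND", "NR", "WB", "WC", "SS", "EP", "SSP", "d",
                    "d_prime", "one_minus_d_prime", "core_flag"):
            assert col in t.columns
        assert np.allclose(t["one_minus_NR"], 1 - t["NR"])
        bounded = t[["ND", "NR", "SSP", "d_prime"]].to_numpy(dtype=float)
        assert ((bounded >= -1e-9) & (bounded <= 1 + 1e-9)).all()
        assert (t["EP"] >= 1 - 1e-9).all() and (t["EP"] <= t["D"] + 1e-9).all()

    def test_permutation_invariance(self, random_matrix):
        rng = np.random.default_rng(0)
        pi = rng.permutation(random_matrix.shape[0])
        pj = rng.permutation(random_matrix.shape[1])
        shuffled = ConsumptionMatrix(
            random_matrix.values[np.ix_(pi, pj)],
            [random_matrix.plant_labels[i] for i in pi],
            [random_matrix.frugivore_labels[j] for j in pj])
        t1 = species_index_table(random_matrix, "plants").sort_index()
        t2 = species_index_table(shuffled, "plants").sort_index()
        num = t1.select_dtypes(float).columns
        assert np.allclose(t1[num].fillna(-1), t2[num].fillna(-1), atol=1e-9)

    def test_scale_invariance_of_unweighted_family(self, random_matrix):
        pct = normalize_percent(random_matrix)
        for fn in (lambda m: degree_indices(m, "plants")["D"],
                   lambda m: degree_indices(m, "plants")["ND"],
                   lambda m: diversity_indices(m, "plants")["EP"]):
            assert np.allclose(fn(random_matrix), fn(pct))

    def test_summary_means_and_variance(self, random_matrix):
        t = species_index_table(random_matrix, "plants")
        s = summarize_indices(t)
        assert s.loc["NR", "mean"] == pytest.approx(0.5)
        assert s.loc["D", "variance"] == pytest.approx(t["D"].var(ddof=1))
        const = t.assign(const=1.0)
        assert summarize_indices(const).loc["const", "variance"] == 0.0

    def test_correlations_and_flags(self, random_matrix):
        t = species_index_table(random_matrix, "plants")
        r, flags = correlate_indices(t)
        assert r.loc["D", "ND"] == pytest.approx(1.0)
        assert flags.loc["D", "ND"]
        assert not flags.to_numpy().diagonal().any()
        const = t.assign(const=1.0)
        r2, _ = correlate_indices(const)
        assert r2["const"].drop("const").isna().all()
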