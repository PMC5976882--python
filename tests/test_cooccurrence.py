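"""Spearman correlation, permutation significance, BH adjustment,
hierarchical ordering and promiscuity summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from maglink.cooccurrence import (bh_adjust, normalize_abundance,
                                  order_by_hclust, promiscuity_summary,
                                  significant_partners, spearman_matrix)
from maglink.errors import InvalidParameterError
from maglink.synthetic import simulate_time_series
from maglink.tables import AbundanceTable


def table(values, taxa, kind="raw-counts", samples=None):
    values = np.asarray(values, dtype=float)
    samples = samples or [f"2007-05-{d:02d}" for d in range(1, len(values) + 1)]
    return AbundanceTable(sample_ids=samples, taxon_ids=taxa, values=values,
                          kind=kind)


class TestNormalizeAbundance:
    def test_equal_counts_equal_lengths(self):
        t = table([[10, 10, 10, 10]], list("abcd"))
        out = normalize_abundance(t, {x: 1000 for x in "abcd"})
        assert np.allclose(out.values, 0.25)

    def test_length_weighting(self):
        t = table([[10, 10]], ["short", "long"])
        out = normalize_abundance(t, {"short": 1000, "long": 2000})
        # double length, same count -> half the weight
        assert np.allclose(out.values, [[2 / 3, 1 / 3]])

    def test_all_zero_sample_dropped(self):
        rows = [[1, 2]] * 9 + [[0, 0]]
        out = normalize_abundance(table(rows, ["a", "b"]),
                                  {"a": 100, "b": 100})
        assert len(out.sample_ids) == 9

    def test_missing_length_rejected(self):
        with pytest.raises(InvalidParameterError):
            normalize_abundance(table([[1, 1]], ["a", "b"]), {"a": 100})


class TestSpearmanMatrix:
    def test_monotone_and_antimonotone(self):
        focal = table([[1], [2], [3], [4], [5]], ["f"])
        partners = table([[2, 10], [4, 8], [6, 6], [8, 4], [10, 2]], ["up", "down"])
        res = spearman_matrix(focal, partners, n_permutations=99, seed=1)
        assert res.rho.at["f", "up"] == 1.0
        assert res.rho.at["f", "down"] == -1.0

    def test_ties_match_hand_computed_average_ranks(self):
        # x = (1,2,2,4) -> ranks (1, 2.5, 2.5, 4)
        # y = (3,1,1,2) -> ranks (4, 1.5, 1.5, 3)
        x, y = [1, 2, 2, 4], [3, 1, 1, 2]
        rx, ry = [1, 2.5, 2.5, 4], [4, 1.5, 1.5, 3]
        mx, my = np.mean(rx), np.mean(ry)
        expected = (sum((a - mx) * (b - my) for a, b in zip(rx, ry)) /
                    np.sqrt(sum((a - mx) ** 2 for a in rx) *
                            sum((b - my) ** 2 for b in ry)))
        res = spearman_matrix(table([[v] for v in x], ["f"]),
                              table([[v] for v in y], ["p"]),
                              n_permutations=99, seed=1)
        assert res.rho.at["f", "p"] == pytest.approx(expected, abs=1e-12)

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(5)
        a = rng.random((20, 1))
        b = rng.random((20, 1))
        r1 = spearman_matrix(table(a, ["x"]), table(b, ["y"]),
                             n_permutations=99, seed=1).rho.at["x", "y"]
        r2 = spearman_matrix(table(b, ["y"]), table(a, ["x"]),
                             n_permutations=99, seed=1).rho.at["y", "x"]
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_rank_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(6)
        a = rng.random((30, 1))
        b = rng.random((30, 1))
        r1 = spearman_matrix(table(a, ["x"]), table(b, ["y"]),
                             n_permutations=99, seed=1).rho.at["x", "y"]
        r2 = spearman_matrix(table(np.exp(5 * a), ["x"]), table(b, ["y"]),
                             n_permutations=99, seed=1).rho.at["x", "y"]
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_constant_vector_undefined(self):
        res = spearman_matrix(table([[1]] * 5, ["const"]),
                              table([[v] for v in range(5)], ["p"]),
                              n_permutations=99, seed=1)
        assert np.isnan(res.rho.at["const", "p"])
        assert np.isnan(res.p.at["const", "p"])

    def test_mismatched_samples_rejected(self):
        f = table([[1], [2], [3]], ["f"])
        p = table([[1], [2], [3]], ["p"], samples=["a", "b", "c"])
        with pytest.raises(InvalidParameterError):
            spearman_matrix(f, p, n_permutations=99, seed=1)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(7)
        f = table(rng.random((15, 2)), ["f1", "f2"])
        p = table(rng.random((15, 3)), ["p1", "p2", "p3"])
        r1 = spearman_matrix(f, p, n_permutations=199, seed=42)
        r2 = spearman_matrix(f, p, n_permutations=199, seed=42)
        assert r1.p.equals(r2.p) and r1.q.equals(r2.q)

    def test_permutation_p_valid_under_null(self):
        """P(p <= alpha) stays near alpha for independent vectors."""
        alpha, hits, total = 0.2, 0, 0
        rng = np.random.default_rng(0)
        for seed in range(50):
            f = table(rng.random((30, 1)), ["f"])
            p = table(rng.random((30, 20)), [f"p{i}" for i in range(20)])
            res = spearman_matrix(f, p, n_permutations=99, seed=seed)
            hits += int((res.p.to_numpy() <= alpha).sum())
            total += 20
        assert hits / total <= alpha + 1 / 100 + 0.05


class TestBHAdjustment:
    @staticmethod
    def brute_force_bh(p):
        """Step-up rule computed directly from its definition."""
        m = len(p)
        order = np.argsort(p, kind="stable")
        q = np.empty(m)
        running_min = 1.0
        for rank_from_top in range(m, 0, -1):
            i = order[rank_from_top - 1]
            running_min = min(running_min, p[i] * m / rank_from_top)
            q[i] = running_min
        return q

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=20))
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_matches_brute_force(self, p):
        p = np.array(p)
        assert np.allclose(bh_adjust(p), self.brute_force_bh(p), atol=1e-12)


class TestOrdering:
    def test_identical_rows_adjacent(self):
        rng = np.random.default_rng(1)
        base = rng.random((10, 4))
        f = table(np.column_stack([base[:, 0], base[:, 1], base[:, 0]]),
                  ["twin_a", "mid", "twin_b"])
        p = table(rng.random((10, 5)), [f"p{i}" for i in range(5)])
        res = order_by_hclust(spearman_matrix(f, p, n_permutations=99, seed=1))
        order = res.row_order
        assert abs(order.index("twin_a") - order.index("twin_b")) == 1

    def test_permutation_invariant(self):
        rng = np.random.default_rng(2)
        f_vals = rng.random((12, 3))
        p = table(rng.random((12, 4)), [f"p{i}" for i in range(4)])
        res1 = order_by_hclust(spearman_matrix(
            table(f_vals, ["a", "b", "c"]), p, n_permutations=99, seed=1))
        res2 = order_by_hclust(spearman_matrix(
            table(f_vals[:, ::-1], ["c", "b", "a"]), p, n_permutations=99, seed=1))
        assert res1.row_order == res2.row_order
        assert res1.reordered().rho.equals(res2.reordered().rho)

    def test_planted_blocks_contiguous(self):
        blocks = {f"culture_{i:02d}": f"b{i % 2}" for i in range(1, 5)}
        blocks.update({f"ts_{j:02d}": f"b{j % 2}" for j in range(1, 9)})
        ts = simulate_time_series(4, 8, 60, blocks, 0.9, seed=3)
        focal = ts.subset_taxa([t for t in ts.taxon_ids if t.startswith("culture_")])
        part = ts.subset_taxa([t for t in ts.taxon_ids if t.startswith("ts_")])
        res = order_by_hclust(spearman_matrix(focal, part, n_permutations=99, seed=1))
        col_blocks = [blocks[c] for c in res.col_order]
        # each planted block occupies one contiguous run of columns
        changes = sum(1 for a, b in zip(col_blocks, col_blocks[1:]) if a != b)
        assert changes == 1


class TestPartnersAndPromiscuity:
    def test_planted_partners_detected_and_null_clean(self):
        blocks = {"culture_01": "b0", "ts_01": "b0", "ts_02": "b0",
                  "ts_03": "b1", "ts_04": "b1"}
        ts = simulate_time_series(1, 4, 45, blocks, 0.8, seed=4)
        focal = ts.subset_taxa(["culture_01"])
        part = ts.subset_taxa(["ts_01", "ts_02", "ts_03", "ts_04"])
        res = spearman_matrix(focal, part, n_permutations=999, seed=5)
        partners = significant_partners(res)
        assert partners["culture_01"] >= {"ts_01", "ts_02"}

    def test_determinism(self):
        blocks = {"culture_01": "b0", "ts_01": "b0", "ts_02": "b1"}
        ts = simulate_time_series(1, 2, 30, blocks, 0.7, seed=6)
        focal = ts.subset_taxa(["culture_01"])
        part = ts.subset_taxa(["ts_01", "ts_02"])
        p1 = significant_partners(spearman_matrix(focal, part, 199, seed=7))
        p2 = significant_partners(spearman_matrix(focal, part, 199, seed=7))
        assert p1 == p2

    def test_promiscuity_counts(self):
        taxonomy = {"f": "acI", "p1": "g1", "p2": "g2", "p3": "g3", "p4": "g4",
                    "q1": "acI", "q2": "acI"}
        spread = promiscuity_summary({"f": {"p1", "p2", "p3", "p4"}}, taxonomy)
        n, groups, _ids, promiscuous = spread.records["f"]
        assert (n, groups, promiscuous) == (4, 4, True)
        narrow = promiscuity_summary({"f": {"q1", "q2"}}, taxonomy)
        assert narrow.records["f"][3] is False  # partners all in own group
        empty = promiscuity_summary({"f": set()}, taxonomy)
        assert empty.records["f"][:2] == (0, 0)
        assert empty.records["f"][3] is False

    def test_missing_taxonomy_rejected(self):
        with pytest.raises(InvalidParameterError):
            promiscuity_summary({"f": {"unknown"}}, {"f": "acI"})
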