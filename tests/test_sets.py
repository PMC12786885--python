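from math import comb

import numpy as np
import pandas as pd
import pytest

from epicirc.io import ProbeAnnotation
from epicirc.sets import (
    SetsError,
    category_distribution,
    consistent_specific_set,
    host_gene_query,
    hypergeometric_ora,
    membership_table,
    read_gmt,
    venn_counts,
    venn_table,
)


def calls_frame(calls: dict[str, dict[str, str]]) -> pd.DataFrame:
    """calls[contrast][probe] -> membership table."""
    frame = pd.DataFrame(calls).fillna("untested")
    frame.index.name = "probe_id"
    return frame


class TestVennCounts:
    def test_disjoint_sets_have_empty_intersections(self):
        m = calls_frame({
            "c1": {"p1": "hyper", "p2": "hyper", "p3": "ns", "p4": "ns"},
            "c2": {"p1": "ns", "p2": "ns", "p3": "hyper", "p4": "hyper"},
        })
        counts = venn_counts(m, ["c1", "c2"], "hyper")
        assert counts[frozenset({"c1"})] == 2
        assert counts[frozenset({"c2"})] == 2
        assert counts[frozenset({"c1", "c2"})] == 0

    def test_containment_a_subset_of_b(self):
        m = calls_frame({
            "A": {"p1": "hypo", "p2": "hypo", "p3": "ns"},
            "B": {"p1": "hypo", "p2": "hypo", "p3": "hypo"},
        })
        counts = venn_counts(m, ["A", "B"], "hypo")
        assert counts[frozenset({"A"})] == 0
        assert counts[frozenset({"A", "B"})] == 2
        assert counts[frozenset({"B"})] == 1

    def test_random_three_contrast_partition_matches_per_probe_oracle(self):
        rng = np.random.default_rng(9)
        probes = [f"p{i}" for i in range(200)]
        contrasts = ["c1", "c2", "c3"]
        m = calls_frame({
            c: {p: rng.choice(["hyper", "hypo", "ns"]) for p in probes}
            for c in contrasts
        })
        counts = venn_counts(m, contrasts, "hyper")
        oracle: dict[frozenset, int] = {}
        for p in probes:
            region = frozenset(c for c in contrasts if m.loc[p, c] == "hyper")
            if region:
                oracle[region] = oracle.get(region, 0) + 1
        for region, n in oracle.items():
            assert counts[region] == n
        union = sum(1 for p in probes if any(m.loc[p, c] == "hyper" for c in contrasts))
        assert sum(counts.values()) == union  # regions partition the union

    def test_unknown_contrast_and_bad_direction_error(self):
        m = calls_frame({"c1": {"p1": "ns"}, "c2": {"p1": "ns"}})
        with pytest.raises(SetsError):
            venn_counts(m, ["c1", "nope"], "hyper")
        with pytest.raises(SetsError):
            venn_counts(m, ["c1", "c2"], "up")

    def test_flat_table_region_labels(self):
        m = calls_frame({
            "c1": {"p1": "hyper"}, "c2": {"p1": "hyper"},
        })
        table = venn_table(venn_counts(m, ["c1", "c2"], "hyper"), "hyper")
        assert set(table["region"]) == {"c1", "c2", "c1&c2"}
        assert table.set_index("region").loc["c1&c2", "count"] == 1


class TestConsistentSpecificSet:
    def test_probe_called_in_all_target_contrasts_is_included(self):
        # mirrors the subtype-specific consistency rule: hypomethylated in
        # every comparison against the other subtypes
        m = calls_frame({
            "T_vs_L": {"vav3_like": "hypo", "other": "hypo"},
            "T_vs_LA": {"vav3_like": "hypo", "other": "ns"},
            "T_vs_LB": {"vav3_like": "hypo", "other": "hypo"},
        })
        got = consistent_specific_set(m, ["T_vs_L", "T_vs_LA", "T_vs_LB"], "hypo")
        assert got == ["vav3_like"]

    def test_partial_consistency_is_excluded(self):
        m = calls_frame({
            "c1": {"p1": "hyper"}, "c2": {"p1": "hyper"}, "c3": {"p1": "ns"},
        })
        assert consistent_specific_set(m, ["c1", "c2", "c3"], "hyper") == []

    def test_empty_membership_table(self):
        m = calls_frame({"c1": {}, "c2": {}})
        assert consistent_specific_set(m, ["c1", "c2"], "hypo") == []

    def test_subset_of_every_contrast_significant_set(self):
        rng = np.random.default_rng(10)
        probes = [f"p{i}" for i in range(100)]
        m = calls_frame({
            c: {p: rng.choice(["hyper", "hypo", "ns"]) for p in probes}
            for c in ["c1", "c2", "c3"]
        })
        consistent = set(consistent_specific_set(m, ["c1", "c2", "c3"], "hyper"))
        for c in ["c1", "c2", "c3"]:
            assert consistent <= set(m.index[m[c] == "hyper"])


class TestCategoryDistribution:
    def _annotation(self, cats):
        return [
            ProbeAnnotation(f"p{i}", f"G{i}", "chr1", "+", c, False)
            for i, c in enumerate(cats)
        ]

    def test_counts_match_hand_tally(self):
        ann = self._annotation(
            ["exonic", "exonic", "intronic", "antisense", "sense_overlapping"]
        )
        m = calls_frame({"c1": {
            "p0": "hyper", "p1": "hyper", "p2": "hyper", "p3": "hypo", "p4": "ns",
        }})
        table = category_distribution(m, ann)
        hyper = table.loc[("c1", "hyper")]
        assert hyper["exonic"] == 2 and hyper["intronic"] == 1
        assert hyper.sum() == 3
        hypo = table.loc[("c1", "hypo")]
        assert hypo["antisense"] == 1 and hypo.sum() == 1

    def test_all_exonic_gives_single_nonzero_column(self):
        ann = self._annotation(["exonic"] * 4)
        m = calls_frame({"c1": {f"p{i}": "hyper" for i in range(4)}})
        table = category_distribution(m, ann)
        assert table.loc[("c1", "hyper"), "exonic"] == 4
        assert table.loc[("c1", "hyper")].sum() == 4

    def test_no_significant_probes_gives_all_zero_table(self):
        ann = self._annotation(["exonic", "intronic"])
        m = calls_frame({"c1": {"p0": "ns", "p1": "ns"}})
        assert (category_distribution(m, ann).values == 0).all()

    def test_unannotated_probe_errors_naming_it(self):
        ann = self._annotation(["exonic"])
        m = calls_frame({"c1": {"p0": "hyper", "mystery": "hyper"}})
        with pytest.raises(SetsError, match="mystery"):
            category_distribution(m, ann)


class TestHypergeometricOra:
    def test_closed_form_full_overlap(self):
        # N=10, K=5, n=5, k=5 -> P = 1/C(10,5) = 1/252
        universe = [f"g{i}" for i in range(10)]
        sets_ = {"T": ("term", set(universe[:5]))}
        res = hypergeometric_ora(universe[:5], sets_, universe)
        assert res["p"].iloc[0] == pytest.approx(1 / comb(10, 5))
        assert (res["k"].iloc[0], res["K"].iloc[0], res["n"].iloc[0], res["N"].iloc[0]) == (5, 5, 5, 10)

    def test_zero_overlap_gives_p_one(self):
        universe = [f"g{i}" for i in range(10)]
        sets_ = {"T": ("term", set(universe[:5]))}
        res = hypergeometric_ora(universe[5:], sets_, universe)
        assert res["p"].iloc[0] == 1.0

    def test_query_identical_to_term_is_most_enriched(self):
        universe = [f"g{i}" for i in range(50)]
        sets_ = {
            "match": ("exact", set(universe[:8])),
            "half": ("partial", set(universe[4:12])),
            "none": ("disjoint", set(universe[20:28])),
        }
        res = hypergeometric_ora(universe[:8], sets_, universe).set_index("term_id")
        assert res["p"].idxmin() == "match"
        assert res.loc["match", "p"] < res.loc["half", "p"] < res.loc["none", "p"]

    def test_direct_tail_summation_oracle(self):
        # P(X >= k) summed from the hypergeometric pmf by hand
        N, K, n = 30, 10, 8
        universe = [f"g{i}" for i in range(N)]
        query = universe[:4] + universe[10:14]   # overlap k=4 with the term
        sets_ = {"T": ("term", set(universe[:K]))}
        res = hypergeometric_ora(query, sets_, universe)

        def pmf(k):
            return comb(K, k) * comb(N - K, n - k) / comb(N, n)

        expected = sum(pmf(k) for k in range(4, min(K, n) + 1))
        assert res["p"].iloc[0] == pytest.approx(expected, rel=1e-12)

    def test_monotone_decreasing_p_in_overlap(self):
        N, K, n = 40, 12, 10
        universe = [f"g{i}" for i in range(N)]
        term = set(universe[:K])
        previous = 1.1
        for k in range(0, n + 1):
            query = universe[:k] + universe[K:K + (n - k)]
            res = hypergeometric_ora(query, {"T": ("t", term)}, universe)
            p = res["p"].iloc[0]
            assert p < previous + 1e-15
            previous = p

    def test_invariant_to_gene_relabeling(self):
        universe = [f"g{i}" for i in range(30)]
        rng = np.random.default_rng(11)
        perm = dict(zip(universe, rng.permutation(universe)))
        query = universe[:6]
        term = set(universe[3:12])
        p1 = hypergeometric_ora(query, {"T": ("t", term)}, universe)["p"].iloc[0]
        p2 = hypergeometric_ora(
            [perm[g] for g in query], {"T": ("t", {perm[g] for g in term})},
            [perm[g] for g in universe],
        )["p"].iloc[0]
        assert p1 == pytest.approx(p2)

    def test_empty_universe_errors_and_bh_flags(self):
        with pytest.raises(SetsError):
            hypergeometric_ora(["g1"], {"T": ("t", {"g1"})}, [])
        universe = [f"g{i}" for i in range(100)]
        sets_ = {"hit": ("t", set(universe[:10])), "miss": ("t", set(universe[50:60]))}
        res = hypergeometric_ora(universe[:10], sets_, universe).set_index("term_id")
        assert bool(res.loc["hit", "significant"])
        assert not bool(res.loc["miss", "significant"])
        assert (res["q"] >= res["p"] - 1e-15).all()


def test_gmt_round_trip_and_host_gene_dedup(tmp_path):
    path = tmp_path / "sets.gmt"
    path.write_text("WNT\tWnt signaling\tGSK3B\tJUP\tZBTB16\n\nCDC42\tGTPase cycle\tVAV3\tDOCK1\n")
    sets_ = read_gmt(path)
    assert sets_["WNT"] == ("Wnt signaling", {"GSK3B", "JUP", "ZBTB16"})
    assert sets_["CDC42"][1] == {"VAV3", "DOCK1"}

    ann = [
        ProbeAnnotation("p1", "VAV3", "chr1", "+", "exonic", False),
        ProbeAnnotation("p2", "VAV3", "chr1", "-", "exonic", False),
        ProbeAnnotation("p3", "DOCK1", "chr10", "+", "exonic", False),
    ]
    assert host_gene_query(["p1", "p2", "p3"], ann) == ["DOCK1", "VAV3"]


def test_membership_table_marks_untested_probes():
    c1 = pd.DataFrame({"probe_id": ["p1", "p2"], "call": ["hyper", "ns"]})
    c2 = pd.DataFrame({"probe_id": ["p2", "p3"], "call": ["hypo", "hyper"]})
    m = membership_table({"c1": c1, "c2": c2})
    assert m.loc["p1", "c2"] == "untested"
    assert m.loc["p3", "c1"] == "untested"
    assert m.loc["p2", "c2"] == "hypo"
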