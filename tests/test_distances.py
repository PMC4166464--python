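import math
import warnings

import numpy as np
import pytest

from crypticdelim.diagnostics import map_alignment_to_sequence_position
from crypticdelim.distances import (coverage_filter, discover_distance_groups,
                                    group_summary, pairwise_p_distance,
                                    partition_groups, relative_threshold_test,
                                    trim_alignment)
from .conftest import make_alignment, random_alignment

# --- independent oracle: per-pair character comparison from scratch ---

_SETS = {"A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
         "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
         "K": {"G", "T"}, "M": {"A", "C"}, "B": {"C", "G", "T"},
         "D": {"A", "G", "T"}, "H": {"A", "C", "T"}, "V": {"A", "C", "G"}}


def _oracle_p(seq_a: str, seq_b: str):
    comparable = mismatches = 0
    for x, y in zip(seq_a, seq_b):
        if x in "-?N" or y in "-?N":
            continue
        comparable += 1
        if not (_SETS[x] & _SETS[y]):
            mismatches += 1
    return (mismatches / comparable if comparable else float("nan"),
            comparable)


class TestPairwisePDistance:
    @pytest.mark.parametrize("a,b,expected,sites", [
        ("ACGT", "ACGT", 0.0, 4),
        ("AAAA", "TTTT", 1.0, 4),
        ("AC-GT", "ACCGA", 0.25, 4),   # gap column dropped from denominator
        ("RCGT", "ACGT", 0.0, 4),      # ambiguity overlap is a match
        ("NNNN", "ACGT", float("nan"), 0),
    ])
    def test_examples(self, a, b, expected, sites):
        aln = make_alignment({"x": a, "y": b})
        dm = pairwise_p_distance(aln)
        got = dm.value("x", "y")
        if math.isnan(expected):
            assert math.isnan(got)
        else:
            assert got == pytest.approx(expected)
        assert dm.comparable_sites[0, 1] == sites

    def test_matches_brute_force_on_randomized_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(60):
            aln = random_alignment(rng, rng.integers(2, 9),
                                   rng.integers(5, 50),
                                   chars="ACGT-N?RYSWKMBDHV")
            dm = pairwise_p_distance(aln)
            for i in range(aln.n_specimens):
                for j in range(aln.n_specimens):
                    exp, sites = _oracle_p("".join(aln.states[i]),
                                           "".join(aln.states[j]))
                    if i == j:
                        continue
                    assert dm.comparable_sites[i, j] == sites
                    if math.isnan(exp):
                        assert math.isnan(dm.values[i, j])
                    else:
                        assert dm.values[i, j] == pytest.approx(exp)

    def test_invariant_under_row_and_column_permutation(self):
        rng = np.random.default_rng(7)
        aln = random_alignment(rng, 6, 30)
        dm = pairwise_p_distance(aln)
        col_perm = rng.permutation(aln.columns)
        row_perm = rng.permutation(aln.n_specimens)
        shuffled = make_alignment(
            {aln.specimen_ids[i]: "".join(aln.states[i][col_perm])
             for i in row_perm})
        dm2 = pairwise_p_distance(shuffled)
        for a in aln.specimen_ids:
            for b in aln.specimen_ids:
                if a == b:
                    continue
                assert dm.value(a, b) == pytest.approx(dm2.value(a, b))

    def test_zero_comparable_sites_flagged_undefined_not_zero(self):
        aln = make_alignment({"x": "AC--", "y": "--GT"})
        dm = pairwise_p_distance(aln)
        assert math.isnan(dm.value("x", "y"))
        assert dm.comparable_sites[0, 1] == 0


class TestCoverageFilter:
    def test_below_half_resolved_is_excluded(self):
        aln = make_alignment({"ok": "ACGTACGTAC",
                              "low": "ACGT??????"})  # 40% resolved
        kept, excluded = coverage_filter(aln, 0.5)
        assert excluded == ["low"]
        assert kept.specimen_ids == ["ok"]

    def test_fully_resolved_alignment_keeps_everyone(self):
        aln = make_alignment({"a": "ACGT", "b": "ACGT", "c": "ACGT"})
        kept, excluded = coverage_filter(aln, 0.5)
        assert excluded == []
        assert kept.n_specimens == 3

    def test_exactly_the_constructed_low_coverage_rows_are_excluded(self):
        rng = np.random.default_rng(3)
        rows = {}
        low = {"s02", "s05", "s08"}
        for i in range(10):
            sid = f"s{i:02d}"
            if sid in low:
                n_resolved = 7          # 7/20 = 35% < 50%
            else:
                n_resolved = 15
            chars = ["?"] * 20
            pos = rng.choice(20, size=n_resolved, replace=False)
            for p in pos:
                chars[p] = "ACGT"[rng.integers(4)]
            rows[sid] = "".join(chars)
        _, excluded = coverage_filter(make_alignment(rows), 0.5)
        assert set(excluded) == low

    def test_all_excluded_is_error(self):
        aln = make_alignment({"a": "????", "b": "????"})
        with pytest.raises(ValueError, match="all specimens"):
            coverage_filter(aln, 0.5)


class TestTrimAlignment:
    def test_full_range_is_identity(self):
        aln = make_alignment({"a": "ACGTACGTAC", "b": "TGCATGCATG"})
        out = trim_alignment(aln, 1, aln.columns)
        assert np.array_equal(out.states, aln.states)

    def test_interval_shifts_coordinates(self):
        aln = make_alignment({"a": "ACGTACGTAC"})
        out = trim_alignment(aln, 3, 7)
        assert out.columns == 5
        assert out.row("a") == "GTACG"   # old column 3 is new column 1

    def test_empty_or_invalid_interval_is_error(self):
        aln = make_alignment({"a": "ACGT"})
        with pytest.raises(ValueError):
            trim_alignment(aln, 3, 2)
        with pytest.raises(ValueError):
            trim_alignment(aln, 0, 2)

    def test_post_trim_position_maps_back_to_original_column(self):
        # composition: position found after trimming + the trim offset
        # recovers the original alignment column (and thus the same
        # reference-sequence coordinate)
        aln = make_alignment({"a": "AC-GTAC-TA", "b": "ACCGTACGTA"})
        start = 4
        trimmed = trim_alignment(aln, start, 10)
        pos_trim = 3                       # column in trimmed coordinates
        orig_col = pos_trim + start - 1
        assert map_alignment_to_sequence_position(trimmed, "a", pos_trim) \
            + (aln.row("a")[:start - 1].replace("-", "").__len__()) \
            == map_alignment_to_sequence_position(aln, "a", orig_col)


class TestGroupSummary:
    def test_two_uniform_groups(self):
        aln = make_alignment({"a1": "AAAA", "a2": "AAAA",
                              "b1": "AATT", "b2": "AATT"})
        dm = pairwise_p_distance(aln)
        part = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        s = group_summary(dm, part)
        assert s.mean_intra["A"] == 0.0
        assert s.mean_inter[("A", "B")] == pytest.approx(0.5)
        assert s.nearest_group["A"] == "B"

    def test_singleton_group_intra_undefined(self):
        aln = make_alignment({"a1": "AAAA", "a2": "AAAA", "b1": "TTTT"})
        s = group_summary(pairwise_p_distance(aln),
                          {"a1": "A", "a2": "A", "b1": "B"})
        assert math.isnan(s.mean_intra["B"])
        assert not s.intra_defined("B")

    def test_means_match_brute_force_recount(self):
        rng = np.random.default_rng(11)
        aln = random_alignment(rng, 12, 40, chars="ACGT-N")
        dm = pairwise_p_distance(aln)
        part = {sid: f"g{i % 3}" for i, sid in enumerate(aln.specimen_ids)}
        s = group_summary(dm, part)
        groups = partition_groups(part)
        for g, members in groups.items():
            intra = [dm.value(a, b) for i, a in enumerate(members)
                     for b in members[i + 1:]
                     if not math.isnan(dm.value(a, b))]
            if intra:
                assert s.mean_intra[g] == pytest.approx(np.mean(intra))
            for h, other in groups.items():
                if h <= g:
                    continue
                inter = [dm.value(a, b) for a in members for b in other
                         if not math.isnan(dm.value(a, b))]
                assert s.mean_inter[(g, h)] == pytest.approx(np.mean(inter))


class TestRelativeThresholdTest:
    def _summary(self, intra, inter):
        aln = make_alignment({"a1": "A" * 1000, "a2": "A" * 1000,
                              "b1": "A" * 1000})
        dm = pairwise_p_distance(aln)
        s = group_summary(dm, {"a1": "A", "a2": "A", "b1": "B"})
        s.mean_intra["A"] = intra
        s.min_mean_inter["A"] = inter
        return s

    def test_large_ratio_passes(self):
        er = relative_threshold_test(self._summary(0.001, 0.048), "A")
        assert er.passes and er.ratio == pytest.approx(48.0)

    def test_inclusive_boundary_at_two_passes(self):
        er = relative_threshold_test(self._summary(0.002, 0.004), "A")
        assert er.passes and er.ratio == pytest.approx(2.0)

    def test_below_two_fails(self):
        er = relative_threshold_test(self._summary(0.003, 0.005), "A")
        assert not er.passes
        assert er.ratio == pytest.approx(5 / 3)

    def test_singleton_passes_with_flag(self):
        aln = make_alignment({"a1": "AAAA", "a2": "AAAA", "b1": "TTTT"})
        s = group_summary(pairwise_p_distance(aln),
                          {"a1": "A", "a2": "A", "b1": "B"})
        er = relative_threshold_test(s, "B")
        assert er.passes and er.intra_undefined and math.isinf(er.ratio)


def _group_sets(partition):
    return {frozenset(m) for m in partition_groups(partition).values()}


class TestDiscoverDistanceGroups:
    def test_two_identical_clusters_give_two_groups(self):
        aln = make_alignment({"a1": "AAAAAAAAAA", "a2": "AAAAAAAAAA",
                              "b1": "AAAAATTTTT", "b2": "AAAAATTTTT"})
        part = discover_distance_groups(pairwise_p_distance(aln))
        assert _group_sets(part) == {frozenset({"a1", "a2"}),
                                     frozenset({"b1", "b2"})}

    def test_all_identical_gives_one_group(self):
        aln = make_alignment({f"s{i}": "ACGTACGT" for i in range(5)})
        part = discover_distance_groups(pairwise_p_distance(aln))
        assert len(_group_sets(part)) == 1

    def test_recovers_true_partition_on_simulated_species(self, default_sim):
        dataset, truth = default_sim
        aln, _ = coverage_filter(dataset.loci["lsu_like"], 0.5)
        part = discover_distance_groups(pairwise_p_distance(aln))
        true_here = {s: truth.partition[s] for s in part}
        assert _group_sets(part) == _group_sets(true_here)

    def test_stable_under_relabeling_and_reordering(self):
        rng = np.random.default_rng(5)
        aln = make_alignment({"a1": "AAAAAAAAAA", "a2": "AAAAAAAAAA",
                              "b1": "AAAAATTTTT", "b2": "AAAAATTTTT",
                              "c1": "GGGGGTTTTT"})
        dm = pairwise_p_distance(aln)
        base = discover_distance_groups(dm)
        order = rng.permutation(aln.n_specimens)
        shuffled = make_alignment({aln.specimen_ids[i]:
                                   "".join(aln.states[i]) for i in order})
        assert discover_distance_groups(
            pairwise_p_distance(shuffled)) == base

    def test_merging_returned_groups_weakens_the_evidence(self, default_sim):
        # lumping any two returned groups always drops the evidence
        # ratio below both constituents' ratios; when separations are
        # of comparable magnitude the merged group fails outright
        dataset, truth = default_sim
        aln, _ = coverage_filter(dataset.loci["lsu_like"], 0.5)
        dm = pairwise_p_distance(aln)
        part = discover_distance_groups(dm)
        summary = group_summary(dm, part)
        labels = sorted(set(part.values()))
        for i, g in enumerate(labels):
            for h in labels[i + 1:]:
                merged = {s: (g if lab == h else lab)
                          for s, lab in part.items()}
                er = relative_threshold_test(group_summary(dm, merged), g)
                assert er.ratio < min(
                    relative_threshold_test(summary, g).ratio,
                    relative_threshold_test(summary, h).ratio)

    def test_merging_equidistant_clusters_fails_outright(self):
        # three clusters at comparable mutual separations: any lump has
        # within-divergence on the same scale as its separation
        rows = {}
        blocks = {"A": "AAAAAAAAAAAA", "B": "TTTTTTTTAAAA",
                  "C": "TTTTAAAATTTT"}   # all pairs differ at 8/12
        for g, block in blocks.items():
            for k in range(3):
                rows[f"{g.lower()}{k}"] = block
        aln = make_alignment(rows)
        dm = pairwise_p_distance(aln)
        part = discover_distance_groups(dm)
        assert len(_group_sets(part)) == 3
        for g, h in [("A", "B"), ("A", "C"), ("B", "C")]:
            merged = {s: {"a": "A", "b": "B", "c": "C"}[s[0]] for s in rows}
            merged = {s: (g if lab == h else lab)
                      for s, lab in merged.items()}
            er = relative_threshold_test(group_summary(dm, merged), g)
            assert not er.passes

    def test_no_structure_falls_back_to_single_group_with_warning(self):
        # a uniform cloud: within ~ between, no 2x gap anywhere
        rng = np.random.default_rng(9)
        aln = random_alignment(rng, 10, 60, chars="ACGT")
        with warnings.catch_warnings(record=True) as rec:
            warnings.simplefilter("always")
            part = discover_distance_groups(pairwise_p_distance(aln))
        assert len(_group_sets(part)) == 1
        assert any("single group" in str(w.message) for w in rec)
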