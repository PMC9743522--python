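"""Multi-caller SV consensus, filtering, normals, fusions, annotation."""

import numpy as np
import pytest

from fusion4c.sv_consensus import (
    FusionCall,
    GeneModel,
    SVCall,
    aggregate_fusions,
    annotate_breakpoints,
    filter_consensus,
    match_calls,
    read_bedpe,
    subtract_normal,
    write_bedpe,
)


def call(p1, p2, caller, chrom1="chr1", chrom2="chr1", sv_type="DEL", **kw):
    return SVCall(chrom1=chrom1, pos1=p1, chrom2=chrom2, pos2=p2,
                  sv_type=sv_type, caller=caller, **kw).canonical()


def brute_force_components(calls, tolerance):
    """O(n^2) single-linkage oracle over the double-breakpoint rule."""
    calls = [c.canonical() for c in calls]
    n = len(calls)
    adj = {k: set() for k in range(n)}
    for a in range(n):
        for b in range(a + 1, n):
            ca, cb = calls[a], calls[b]
            if (
                ca.chrom1 == cb.chrom1
                and ca.chrom2 == cb.chrom2
                and abs(ca.pos1 - cb.pos1) <= tolerance
                and abs(ca.pos2 - cb.pos2) <= tolerance
            ):
                adj[a].add(b)
                adj[b].add(a)
    seen, comps = set(), []
    for start in range(n):
        if start in seen:
            continue
        comp, stack = [], [start]
        while stack:
            x = stack.pop()
            if x in seen:
                continue
            seen.add(x)
            comp.append(x)
            stack.extend(adj[x])
        comps.append(frozenset(calls[x].sort_key() for x in comp))
    return set(comps)


def random_callsets(rng, n_calls, n_callers=4):
    calls = []
    for _ in range(n_calls):
        chrom1 = f"chr{rng.integers(1, 4)}"
        trans = rng.random() < 0.2
        chrom2 = f"chr{rng.integers(1, 4)}" if trans else chrom1
        p1 = int(rng.integers(0, 200_000))
        p2 = int(rng.integers(0, 200_000))
        calls.append(
            SVCall(
                chrom1=chrom1, pos1=p1, chrom2=chrom2, pos2=p2,
                sv_type=str(rng.choice(["DEL", "DUP", "BND"])),
                caller=f"c{rng.integers(n_callers)}",
            ).canonical()
        )
    return calls


class TestMatchCalls:
    def test_identical_breakpoints_merge_across_callers(self):
        groups = match_calls({"a": [call(100, 5000, "a")],
                              "b": [call(100, 5000, "b")]})
        assert len(groups) == 1
        assert groups[0].callers == ("a", "b")

    def test_tolerance_boundary_is_inclusive(self):
        merged = match_calls([[call(0, 50_000, "a")],
                              [call(1000, 51_000, "b")]])
        assert len(merged) == 1
        split = match_calls([[call(0, 50_000, "a")],
                             [call(1001, 50_000, "b")]])
        assert len(split) == 2

    def test_sv_type_not_required_to_match(self):
        groups = match_calls([[call(100, 60_000, "a", sv_type="DUP")],
                              [call(100, 60_000, "b", sv_type="BND")]])
        assert len(groups) == 1

    def test_different_chromosome_pairs_never_merge(self):
        groups = match_calls([[call(100, 5000, "a")],
                              [call(100, 5000, "b", chrom1="chr2",
                                    chrom2="chr2")]])
        assert len(groups) == 2

    def test_permutation_invariance_and_idempotence(self):
        rng = np.random.default_rng(0)
        calls = random_callsets(rng, 80)
        g1 = match_calls([calls])
        g2 = match_calls([calls[::-1]])
        key = lambda g: g.representative.sort_key()
        assert [key(g) for g in g1] == [key(g) for g in g2]
        # idempotence: re-matching the representatives reproduces the groups
        reps = [g.representative for g in g1]
        g3 = match_calls([reps], tolerance=1000)
        assert len(g3) == len(g1)

    @pytest.mark.parametrize("tolerance", [0, 500, 1000, 5000])
    def test_components_equal_brute_force_oracle(self, tolerance):
        rng = np.random.default_rng(tolerance + 1)
        for _ in range(25):
            calls = random_callsets(rng, int(rng.integers(10, 500)))
            got = {
                frozenset(c.sort_key() for c in g.member_calls)
                for g in match_calls([calls], tolerance=tolerance)
            }
            assert got == brute_force_components(calls, tolerance)

    def test_representative_is_medoid(self):
        calls = [call(0, 50_000, "a"), call(600, 50_600, "b"),
                 call(1100, 51_100, "c")]
        (group,) = match_calls([calls])
        assert group.representative.pos1 == 600  # middle call minimizes distance


class TestFilterConsensus:
    def _group(self, p1, p2, callers, chrom2="chr1"):
        members = [call(p1, p2, c, chrom2=chrom2,
                        sv_type="TRA" if chrom2 != "chr1" else "DUP")
                   for c in callers]
        (g,) = match_calls([members])
        return g

    def test_small_event_removed_despite_caller_support(self):
        g = self._group(0, 9_000, ["a", "b", "c"])
        assert filter_consensus([g]) == []

    def test_single_caller_event_removed_despite_size(self):
        g = self._group(0, 150_000, ["a"])
        assert filter_consensus([g]) == []

    def test_exactly_10kb_removed_strict_boundary(self):
        g = self._group(0, 10_000, ["a", "b"])
        assert filter_consensus([g]) == []
        g2 = self._group(0, 10_001, ["a", "b"])
        assert filter_consensus([g2]) == [g2]

    def test_trans_calls_pass_size_filter_by_default(self):
        g = self._group(100, 200, ["a", "b"], chrom2="chr2")
        assert filter_consensus([g]) == [g]
        assert filter_consensus([g], keep_trans=False) == []


class TestSubtractNormal:
    def test_empty_normal_means_all_somatic(self):
        (g,) = match_calls([[call(0, 50_000, "a"), call(0, 50_000, "b")]])
        subtract_normal([g], [])
        assert g.somatic is True

    def test_exact_normal_match_is_germline(self):
        (g,) = match_calls([[call(0, 50_000, "a"), call(0, 50_000, "b")]])
        subtract_normal([g], [[call(0, 50_000, "n")]])
        assert g.somatic is False

    def test_simulated_germline_somatic_mixture(self):
        somatic = [call(100_000, 200_000, c) for c in "ab"]
        germline = [call(500_000, 700_000, c) for c in "ab"]
        groups = match_calls([somatic + germline])
        normal = [[call(500_300, 699_800, "n")]]
        subtract_normal(groups, normal)
        flags = {g.representative.pos1: g.somatic for g in groups}
        assert flags == {100_000: True, 500_000: False}


class TestAggregateFusions:
    def frame(self, rows):
        import pandas as pd

        return pd.DataFrame(
            rows,
            columns=["gene5", "gene3", "chrom5", "pos5", "chrom3", "pos3",
                     "split_reads", "spanning_pairs"],
        )

    def test_same_pair_from_three_callers_unioned(self):
        row = ["A", "B", "chr1", 100, "chr2", 200, 3, 2]
        fusions, skipped = aggregate_fusions(
            {f"c{k}": self.frame([row]) for k in range(3)}
        )
        assert skipped == 0
        assert len(fusions) == 1
        assert fusions[0].n_callers == 3

    def test_priority_filter_keeps_single_caller_pair(self):
        sets = {
            "c1": self.frame([["BRAF", "KIAA1549", "chr7", 1, "chr7", 2, 1, 1],
                              ["X", "Y", "chr1", 1, "chr1", 2, 9, 9]]),
            "c2": self.frame([["X", "Y", "chr1", 1, "chr1", 2, 5, 5]]),
        }
        fusions, _ = aggregate_fusions(sets, priority_genes={"BRAF"})
        assert [f.gene_pair for f in fusions] == [frozenset({"BRAF", "KIAA1549"})]
        assert fusions[0].n_callers == 1

    def test_malformed_and_readthrough_rows_skipped_with_count(self):
        sets = {
            "c1": self.frame(
                [
                    ["A", "B", "chr1", 100, "chr2", 200, 1, 1],
                    ["A", "A", "chr1", 100, "chr1", 200, 1, 1],  # read-through
                    ["", "B", "chr1", 100, "chr2", 200, 1, 1],
                    ["A", "B", "chr1", "oops", "chr2", 200, 1, 1],
                ]
            )
        }
        fusions, skipped = aggregate_fusions(sets)
        assert len(fusions) == 1
        assert skipped == 3

    def test_caller_count_histogram_matches_construction(self):
        rng = np.random.default_rng(2)
        pairs = [(f"G{k}", f"H{k}") for k in range(12)]
        planted = {}
        sets = {}
        for c in range(3):
            rows = []
            for k, (g5, g3) in enumerate(pairs):
                if rng.random() < 0.6:
                    rows.append([g5, g3, "chr1", 10 * k, "chr2", 20 * k, 1, 1])
                    planted[frozenset((g5, g3))] = planted.get(
                        frozenset((g5, g3)), 0) + 1
            sets[f"c{c}"] = self.frame(rows)
        fusions, _ = aggregate_fusions(sets)
        got = {f.gene_pair: f.n_callers for f in fusions}
        assert got == planted


class TestAnnotateBreakpoints:
    GENES = [
        GeneModel("FWD", "chr1", 10_000, 50_000, "+",
                  exons=[(10_000 + 2_000 * k, 11_000 + 2_000 * k)
                         for k in range(17)]),
        GeneModel("REV", "chr2", 10_000, 30_000, "-"),
    ]

    def test_breakpoint_inside_gene_body_reported(self):
        ann = annotate_breakpoints(
            call(20_500, 25_000, "a", chrom2="chr1"), self.GENES
        )
        assert any(name == "FWD" for name, _, _ in ann.bp1.genes)

    def test_intron_15_of_toy_transcript(self):
        # between exon 15 ([38000,39000)) and exon 16 ([40000,41000))
        ann = annotate_breakpoints(
            call(39_500, 49_000, "a", chrom2="chr1"), self.GENES
        )
        assert ("FWD", "+", "intron 15") in ann.bp1.genes

    def test_intron_numbering_respects_minus_strand(self):
        gene = GeneModel(
            "REV3", "chr1", 0, 7_000, "-",
            exons=[(0, 1_000), (2_000, 3_000), (4_000, 5_000), (6_000, 7_000)],
        )
        # coordinate gap between exon blocks 1 and 2 is transcript intron 3
        ann = annotate_breakpoints(
            call(1_500, 6_500, "a", chrom2="chr1"), [gene]
        )
        assert ("REV3", "-", "intron 3") in ann.bp1.genes

    def test_intergenic_breakpoint_labelled_not_error(self):
        ann = annotate_breakpoints(
            call(500, 25_000, "a", chrom2="chr2", sv_type="TRA"), self.GENES
        )
        assert ann.bp1.intergenic
        assert not ann.bp2.intergenic

    def test_tandem_dup_fusion_orientation_minus_strand_genes(self):
        """DUP junction keeps partner 5' and gene 3' on minus-strand pair."""
        genes = [
            GeneModel("PARTNER", "chr7", 1_950_000, 2_050_000, "-"),
            GeneModel("GENE", "chr7", 3_900_000, 4_120_000, "-"),
        ]
        ann = annotate_breakpoints(
            call(2_000_000, 3_980_000, "a", chrom1="chr7", chrom2="chr7",
                 sv_type="DUP"),
            genes,
        )
        assert ann.gene5 == "PARTNER"
        assert ann.gene3 == "GENE"


class TestBedpeIO:
    def test_round_trip(self, tmp_path):
        calls = [call(100, 50_000, "a", name="e1"),
                 call(5_000, 9_000, "a", chrom2="chr2", sv_type="TRA",
                      name="e2")]
        p = tmp_path / "x.bedpe"
        write_bedpe(calls, p)
        back = read_bedpe(p)
        assert [(c.chrom1, c.pos1, c.chrom2, c.pos2, c.sv_type, c.name)
                for c in back] == \
               [(c.chrom1, c.pos1, c.chrom2, c.pos2, c.sv_type, c.name)
                for c in calls]
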