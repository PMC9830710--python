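"""Chimera detection/splitting, greedy placement, pseudo-chromosome assembly."""

import numpy as np
import pytest

from refanchor import (AnchorConfig, Assembly, GapMap, SequenceRecord,
                       anchor_pipeline, assemble_from_agp,
                       build_pseudochromosomes, detect_chimeras,
                       place_scaffolds, reverse_complement, split_scaffold)
from refanchor.anchor import BreakDirective, Placement
from refanchor.seedchain import Chain

from conftest import random_seq


def mk_chain(q_id, r_id, strand, q0, q1, r0, r1, score=None):
    return Chain(q_id=q_id, r_id=r_id, strand=strand, seeds=[],
                 score=score if score is not None else q1 - q0,
                 q_start=q0, q_end=q1, r_start=r0, r_end=r1,
                 r_median=(r0 + r1) // 2)


CFG = AnchorConfig(min_seed_len=20, sig_abs=100, sig_frac=0.25,
                   dist_thresh=1_000_000)


class TestDetectChimeras:
    def test_single_chain_not_chimeric(self):
        chains = {"s1": [mk_chain("s1", "chr1", "+", 0, 50_000, 0, 50_000)]}
        assert detect_chimeras(chains, CFG) == []

    def test_two_chromosomes_break_at_midpoint(self):
        chains = {"s7": [mk_chain("s7", "chr1", "+", 0, 40_000, 0, 40_000),
                         mk_chain("s7", "chr2", "+", 60_000, 100_000, 0, 40_000)]}
        (d,) = detect_chimeras(chains, CFG)
        assert d.positions == [50_000]
        assert d.reasons == ["different_chromosomes"]

    def test_break_snaps_to_gap_run(self):
        chains = {"s7": [mk_chain("s7", "chr1", "+", 0, 40_000, 0, 40_000),
                         mk_chain("s7", "chr2", "+", 60_000, 100_000, 0, 40_000)]}
        gm = GapMap({"s7": [(48_000, 49_000)]})
        (d,) = detect_chimeras(chains, CFG, gapmap=gm)
        assert d.positions == [48_000]

    def test_nearby_same_chromosome_not_chimeric(self):
        # reference intervals 0.1 Mb apart, threshold 1 Mb
        chains = {"s1": [mk_chain("s1", "chr1", "+", 0, 40_000, 0, 40_000),
                         mk_chain("s1", "chr1", "+", 45_000, 90_000, 140_000, 185_000)]}
        assert detect_chimeras(chains, CFG) == []

    def test_distant_same_chromosome_is_chimeric(self):
        cfg = AnchorConfig(min_seed_len=20, sig_abs=100, dist_thresh=50_000)
        chains = {"s1": [mk_chain("s1", "chr1", "+", 0, 40_000, 0, 40_000),
                         mk_chain("s1", "chr1", "+", 45_000, 90_000, 500_000, 545_000)]}
        (d,) = detect_chimeras(chains, cfg)
        assert d.reasons == ["distant_same_chromosome"]

    def test_insignificant_secondary_chain_ignored(self):
        chains = {"s1": [mk_chain("s1", "chr1", "+", 0, 40_000, 0, 40_000),
                         mk_chain("s1", "chr2", "+", 50_000, 50_150, 0, 150)]}
        # secondary score 150 < 0.25 * 40000
        assert detect_chimeras(chains, CFG) == []


class TestSplitScaffold:
    def test_split_names_and_intervals(self):
        rec = SequenceRecord("s7", "A" * 100_000)
        parts = split_scaffold(rec, BreakDirective("s7", [48_000], ["different_chromosomes"]))
        assert [p.id for p in parts] == ["s7-1", "s7-2"]
        assert [len(p.seq) for p in parts] == [48_000, 52_000]

    def test_no_directive_is_identity(self):
        rec = SequenceRecord("s7", "ACGT" * 100)
        assert split_scaffold(rec, None) == [rec]

    def test_concatenation_reproduces_original(self, rng):
        rec = SequenceRecord("s", random_seq(rng, 5000))
        parts = split_scaffold(rec, BreakDirective("s", [1000, 3500], ["x", "y"]))
        assert "".join(p.seq for p in parts) == rec.seq

    def test_gap_run_goes_to_left_part(self, rng):
        seq = random_seq(rng, 2000) + "N" * 300 + random_seq(rng, 2000)
        rec = SequenceRecord("s", seq)
        parts = split_scaffold(rec, BreakDirective("s", [2000], ["x"]))
        assert parts[0].seq.endswith("N" * 300)
        assert "N" not in parts[1].seq

    def test_break_at_sequence_edge_rejected(self):
        rec = SequenceRecord("s", "ACGT" * 50)
        with pytest.raises(ValueError, match="outside"):
            split_scaffold(rec, BreakDirective("s", [0], ["x"]))


class TestPlacement:
    def test_disjoint_spans_both_placed(self):
        chains = {"S1": [mk_chain("S1", "chr1", "+", 0, 300, 0, 300, 300)],
                  "S2": [mk_chain("S2", "chr1", "+", 0, 400, 500, 900, 400)]}
        cfg = AnchorConfig(min_seed_len=20, sig_abs=50)
        placements = place_scaffolds(chains, None, cfg)
        assert all(p.status == "placed" for p in placements)
        keys = sorted((p.r_median, p.scaffold_id) for p in placements)
        assert [k[1] for k in keys] == ["S1", "S2"]

    def test_loser_falls_back_to_second_best_location(self):
        cfg = AnchorConfig(min_seed_len=20, sig_abs=50, sig_frac=0.25, ovl_frac=0.2)
        chains = {
            "win": [mk_chain("win", "chr1", "+", 0, 1000, 0, 1000, 1000)],
            "lose": [mk_chain("lose", "chr1", "+", 0, 800, 0, 800, 800),
                     mk_chain("lose", "chr2", "+", 0, 700, 0, 700, 700)],
        }
        placements = {p.scaffold_id: p for p in place_scaffolds(chains, None, cfg)}
        assert placements["win"].r_id == "chr1"
        assert placements["lose"].r_id == "chr2"

    def test_all_chains_below_threshold_unplaced(self):
        cfg = AnchorConfig(min_seed_len=20, sig_abs=500)
        chains = {"s": [mk_chain("s", "chr1", "+", 0, 100, 0, 100, 100)]}
        (p,) = place_scaffolds(chains, None, cfg)
        assert p.status == "unplaced"


class TestBuild:
    def test_object_arithmetic_and_agp_rows(self, rng):
        scaffolds = Assembly([SequenceRecord("S1", random_seq(rng, 300)),
                              SequenceRecord("S2", random_seq(rng, 400))])
        placements = [
            Placement("S1", "chr1", 10, "+", "placed",
                      mk_chain("S1", "chr1", "+", 0, 300, 0, 300)),
            Placement("S2", "chr1", 500, "+", "placed",
                      mk_chain("S2", "chr1", "+", 0, 400, 400, 800)),
        ]
        pseudo = build_pseudochromosomes(placements, scaffolds, gap_len=100)
        assert len(pseudo.assembly["chr1"].seq) == 800
        rows = [(r.object_beg, r.object_end, r.component_type) for r in pseudo.agp]
        assert rows == [(1, 300, "W"), (301, 400, "N"), (401, 800, "W")]
        rebuilt = assemble_from_agp(pseudo.agp, scaffolds)
        assert rebuilt["chr1"].seq == pseudo.assembly["chr1"].seq

    def test_minus_placement_reverse_complemented(self, rng):
        scaffolds = Assembly([SequenceRecord("S1", random_seq(rng, 250))])
        placements = [Placement("S1", "chr1", 5, "-", "placed",
                                mk_chain("S1", "chr1", "-", 0, 250, 0, 250))]
        pseudo = build_pseudochromosomes(placements, scaffolds)
        assert pseudo.assembly["chr1"].seq == reverse_complement(scaffolds["S1"].seq)

    def test_median_tie_broken_by_scaffold_id(self, rng):
        scaffolds = Assembly([SequenceRecord("b", random_seq(rng, 100)),
                              SequenceRecord("a", random_seq(rng, 100))])
        placements = [
            Placement("b", "chr1", 50, "+", "placed",
                      mk_chain("b", "chr1", "+", 0, 100, 0, 100)),
            Placement("a", "chr1", 50, "+", "placed",
                      mk_chain("a", "chr1", "+", 0, 100, 0, 100)),
        ]
        pseudo = build_pseudochromosomes(placements, scaffolds, gap_len=10)
        assert pseudo.assembly["chr1"].seq == (
            scaffolds["a"].seq + "N" * 10 + scaffolds["b"].seq)

    def test_duplicate_placement_rejected(self, rng):
        scaffolds = Assembly([SequenceRecord("S1", random_seq(rng, 100))])
        placements = [Placement("S1", "chr1", 0, "+", "placed"),
                      Placement("S1", "chr2", 0, "+", "placed")]
        with pytest.raises(ValueError, match="duplicate placement"):
            build_pseudochromosomes(placements, scaffolds)


class TestAnchorPipeline:
    CFG = AnchorConfig(min_seed_len=20, stride=1, dist_base=20_000)

    def _reference(self, rng, n=2, length=30_000):
        return Assembly([SequenceRecord(f"chr{i+1}", random_seq(rng, length))
                         for i in range(n)], name="ref")

    def test_clean_contigs_reanchor_exactly(self, rng):
        ref = self._reference(rng)
        contigs = []
        k = 0
        for rec in ref:
            for s in range(0, len(rec.seq), 3000):
                k += 1
                contigs.append(SequenceRecord(f"ctg{k:03d}", rec.seq[s : s + 3000]))
        query = Assembly(contigs, name="ctgs")
        pseudo = anchor_pipeline(query, ref, self.CFG)
        assert all(p.status == "placed" for p in pseudo.placements)
        assert all(p.orientation == "+" for p in pseudo.placements)
        for rec in ref:
            got = pseudo.assembly[rec.id].seq.replace("N", "")
            assert got == rec.seq

    def test_chimeric_scaffold_split_and_placed(self, rng):
        ref = self._reference(rng)
        chimera = SequenceRecord("chim", ref["chr1"].seq[:10_000] + ref["chr2"].seq[-10_000:])
        query = Assembly([chimera], name="q")
        pseudo = anchor_pipeline(query, ref, self.CFG)
        placed = {p.scaffold_id: p for p in pseudo.placements if p.status == "placed"}
        assert set(placed) == {"chim-1", "chim-2"}
        assert placed["chim-1"].r_id == "chr1"
        assert placed["chim-2"].r_id == "chr2"

    def test_empty_query_warns(self, caplog):
        ref = Assembly([SequenceRecord("chr1", "ACGT" * 100)])
        with caplog.at_level("WARNING"):
            pseudo = anchor_pipeline(Assembly([], name="empty"), ref, self.CFG)
        assert len(pseudo.assembly) == 0
        assert "empty" in caplog.text

    def test_base_conservation_with_unplaced(self, rng):
        ref = self._reference(rng)
        foreign = SequenceRecord("foreign", random_seq(rng, 5000))
        contigs = [SequenceRecord("c1", ref["chr1"].seq[:8000]), foreign]
        pseudo = anchor_pipeline(Assembly(contigs, name="q"), ref, self.CFG)
        placed_bases = sum(
            r.component_interval[1] for r in pseudo.agp if r.component_type == "W")
        unplaced_bases = pseudo.unplaced.total_length()
        assert placed_bases + unplaced_bases == 8000 + 5000
        assert "foreign" in pseudo.unplaced
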