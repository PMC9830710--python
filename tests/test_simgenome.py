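"""Simulator: determinism, planted-SV semantics, fragmentation bookkeeping."""

import collections

import pytest

from refanchor import (Assembly, SequenceRecord, SimConfig, SvSpec, apply_svs,
                       fragment_assembly, random_sv_specs, reverse_complement,
                       simulate_mate_pairs, simulate_reference)


def small_cfg(**kw):
    defaults = dict(n_chrom=2, chrom_len=50_000, frag_mean=5000, frag_sd=1000,
                    contigs_per_scaffold=2.0, seed=11)
    defaults.update(kw)
    return SimConfig(**defaults)


class TestReference:
    def test_deterministic_given_seed(self):
        cfg = small_cfg()
        a = simulate_reference(cfg)
        b = simulate_reference(cfg)
        assert [(r.id, r.seq) for r in a] == [(r.id, r.seq) for r in b]

    def test_gc_fraction_within_binomial_bound(self):
        # 6-sigma band for a 10^6-base binomial draw at p = 0.5 is ~0.003,
        # so 0.5 +/- 0.01 is a comfortable deterministic check
        cfg = SimConfig(n_chrom=1, chrom_len=1_000_000, gc=0.5, seed=3)
        seq = simulate_reference(cfg)["chr1"].seq
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert abs(gc - 0.5) < 0.01

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(n_chrom=1, chrom_len=0)


class TestApplySvs:
    def test_empty_specs_is_identity(self):
        ref = simulate_reference(small_cfg())
        derived, truth = apply_svs(ref, [])
        assert [(r.id, r.seq) for r in derived] == [(r.id, r.seq) for r in ref]
        assert truth.planted_svs == []

    def test_inversion_is_reverse_complement_in_place(self):
        ref = simulate_reference(small_cfg())
        derived, truth = apply_svs(ref, [SvSpec("INV", "chr1", 10_000, 10_000)])
        assert derived["chr1"].seq[10_000:20_000] == reverse_complement(
            ref["chr1"].seq[10_000:20_000])
        assert derived["chr1"].seq[:10_000] == ref["chr1"].seq[:10_000]
        assert derived["chr1"].seq[20_000:] == ref["chr1"].seq[20_000:]
        sv = truth.planted_svs[0]
        assert (sv.derived_start, sv.derived_end, sv.inverted) == (10_000, 20_000, True)

    def test_translocation_length_bookkeeping(self):
        ref = simulate_reference(small_cfg())
        spec = SvSpec("TRL", "chr1", 0, 20_000, dest_chrom="chr2",
                      dest_pos=len(ref["chr2"].seq))
        derived, truth = apply_svs(ref, [spec])
        assert len(derived["chr1"].seq) == len(ref["chr1"].seq) - 20_000
        assert len(derived["chr2"].seq) == len(ref["chr2"].seq) + 20_000
        assert derived.total_length() == ref.total_length()
        assert derived["chr2"].seq[-20_000:] == ref["chr1"].seq[:20_000]
        sv = truth.planted_svs[0]
        assert sv.derived_chrom == "chr2"
        assert sv.derived_end - sv.derived_start == 20_000

    def test_duplication_conserves_and_adds(self):
        ref = simulate_reference(small_cfg())
        spec = SvSpec("DUP", "chr1", 5000, 4000, dest_chrom="chr2", dest_pos=1000)
        derived, truth = apply_svs(ref, [spec])
        assert len(derived["chr1"].seq) == len(ref["chr1"].seq)
        assert len(derived["chr2"].seq) == len(ref["chr2"].seq) + 4000
        assert derived["chr2"].seq[1000:5000] == ref["chr1"].seq[5000:9000]
        sv = truth.planted_svs[0]
        assert (sv.derived_chrom, sv.derived_start, sv.derived_end) == ("chr2", 1000, 5000)

    def test_overlapping_specs_rejected(self):
        ref = simulate_reference(small_cfg())
        with pytest.raises(ValueError, match="overlap"):
            apply_svs(ref, [SvSpec("INV", "chr1", 1000, 5000),
                            SvSpec("INV", "chr1", 4000, 5000)])

    def test_truth_registry_reproduces_derived(self):
        """Re-applying each recorded event to the reference reproduces the
        derived sequence (independent reconstruction from the registry)."""
        ref = simulate_reference(small_cfg())
        specs = [SvSpec("INV", "chr1", 8000, 6000), SvSpec("INV", "chr2", 2000, 9000)]
        derived, truth = apply_svs(ref, specs)
        for chrom in ref.ids():
            seq = list(ref[chrom].seq)
            for sv in truth.planted_svs:
                if sv.ref_chrom == chrom and sv.kind == "INV":
                    seq[sv.ref_start:sv.ref_end] = reverse_complement(
                        "".join(seq[sv.ref_start:sv.ref_end]))
            assert "".join(seq) == derived[chrom].seq


class TestFragmentation:
    def test_colinear_without_chimeras(self):
        cfg = small_cfg(chimera_rate=0.0)
        genome = simulate_reference(cfg)
        scf, agp, truth = fragment_assembly(genome, cfg)
        for scf_id, members in truth.scaffold_members.items():
            chroms = {truth.frag_map[m][0] for m in members}
            assert len(chroms) == 1
            spans = [truth.frag_map[m][1:] for m in members]
            assert all(a[1] == b[0] for a, b in zip(spans, spans[1:]))
        assert truth.chimera_joins == {}

    def test_concatenated_contigs_reproduce_genome(self):
        cfg = small_cfg()
        genome = simulate_reference(cfg)
        _, _, truth = fragment_assembly(genome, cfg)
        per_chrom = {}
        for cid, (chrom, s, e) in truth.frag_map.items():
            per_chrom.setdefault(chrom, []).append((s, e, cid))
        for chrom, pieces in per_chrom.items():
            pieces.sort()
            assert pieces[0][0] == 0 and pieces[-1][1] == len(genome[chrom].seq)
            assert all(a[1] == b[0] for a, b in zip(pieces, pieces[1:]))

    def test_base_conservation(self):
        cfg = small_cfg(chimera_rate=0.3)
        genome = simulate_reference(cfg)
        scf, _, _ = fragment_assembly(genome, cfg)
        got = collections.Counter("".join(r.seq for r in scf).replace("N", ""))
        want = collections.Counter("".join(r.seq for r in genome))
        assert got == want

    def test_forced_cuts_keep_breakpoints_out_of_contigs(self):
        cfg = small_cfg()
        genome = simulate_reference(cfg)
        boundaries = [12_345, 23_456]
        _, _, truth = fragment_assembly(genome, cfg,
                                        force_cuts={"chr1": boundaries})
        for cid, (chrom, s, e) in truth.frag_map.items():
            if chrom != "chr1":
                continue
            for b in boundaries:
                assert not s < b < e, f"contig {cid} [{s},{e}) spans breakpoint {b}"

    def test_avoid_intervals_keep_contigs_spanning(self):
        cfg = small_cfg()
        genome = simulate_reference(cfg)
        region = (20_000, 26_000)
        _, _, truth = fragment_assembly(
            genome, cfg, avoid_intervals={"chr1": [region]})
        spanning = [cid for cid, (chrom, s, e) in truth.frag_map.items()
                    if chrom == "chr1" and s <= region[0] and e >= region[1]]
        assert spanning, "no contig fully contains the protected region"

    def test_chimera_joins_reference_distinct_loci(self):
        cfg = small_cfg(chimera_rate=0.5, n_chrom=2)
        genome = simulate_reference(cfg)
        _, _, truth = fragment_assembly(genome, cfg)
        assert truth.chimera_joins, "expected at least one chimera at rate 0.5"
        for scf_id, joins in truth.chimera_joins.items():
            members = truth.scaffold_members[scf_id]
            chroms = {truth.frag_map[m][0] for m in members}
            starts = {truth.frag_map[m][1] for m in members}
            assert len(chroms) > 1 or max(starts) - min(starts) > 10 * cfg.frag_mean


class TestMatePairs:
    def test_inserts_within_configured_range(self):
        cfg = small_cfg()
        genome = simulate_reference(cfg)
        pairs = simulate_mate_pairs(genome, 1000, cfg)
        inserts = (pairs["pos2"] - pairs["pos1"]).abs()
        assert inserts.between(2000, 5000).all()

    def test_no_flags_means_all_usable(self):
        cfg = small_cfg()
        genome = simulate_reference(cfg)
        pairs = simulate_mate_pairs(genome, 200, cfg)
        assert pairs["unique"].all() and (~pairs["duplicate"]).all()

    def test_flag_fractions_applied(self):
        cfg = small_cfg()
        genome = simulate_reference(cfg)
        pairs = simulate_mate_pairs(genome, 4000, cfg,
                                    nonunique_fraction=0.2, duplicate_fraction=0.1)
        assert 0.1 < (~pairs["unique"]).mean() < 0.3
        assert 0.05 < pairs["duplicate"].mean() < 0.2

    def test_short_sequence_skipped_with_warning(self, caplog):
        cfg = small_cfg()
        asm = Assembly([SequenceRecord("tiny", "ACGT" * 375)])  # 1500 bp
        with caplog.at_level("WARNING"):
            pairs = simulate_mate_pairs(asm, 10, cfg)
        assert pairs.empty
        assert "tiny" in caplog.text


def test_full_determinism_of_generator_chain():
    """Identical SimConfig (seed included) gives byte-identical outputs."""
    def run():
        cfg = small_cfg(chimera_rate=0.2)
        rng = cfg.rng()
        ref = simulate_reference(cfg, rng)
        specs = random_sv_specs(ref, rng, 2, "INV", (3000, 6000), margin=2000)
        derived, truth = apply_svs(ref, specs, seed=cfg.seed)
        scf, agp, truth = fragment_assembly(derived, cfg, rng, truth=truth)
        pairs = simulate_mate_pairs(scf, 500, cfg, rng)
        return ([(r.id, r.seq) for r in scf], truth.to_frame(), pairs)

    scf_a, truth_a, pairs_a = run()
    scf_b, truth_b, pairs_b = run()
    assert scf_a == scf_b
    assert truth_a.equals(truth_b)
    assert pairs_a.equals(pairs_b)
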