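"""Seed index, MEM discovery and chaining against brute-force oracles."""

import numpy as np
import pytest

from refanchor import (Assembly, SeedIndex, SequenceRecord, chain_seeds,
                       find_seeds, reverse_complement)
from refanchor.seedchain import Seed

from conftest import random_seq
from oracles import best_chain_score_brute, brute_force_mems, oracle_chain_score


def mem_tuples(seeds):
    return {(s.q_start, s.q_end, s.r_id, s.r_start, s.r_end, s.strand) for s in seeds}


class TestSeedIndex:
    def test_short_probe_rejected(self, rng):
        ref = Assembly([SequenceRecord("r", random_seq(rng, 200))])
        with pytest.raises(ValueError, match="collision-prone"):
            SeedIndex(ref, 15)

    def test_probe_lookup_forward(self, rng):
        seq = random_seq(rng, 400)
        index = SeedIndex(Assembly([SequenceRecord("r", seq)]), 65)
        assert index.occurrences(seq[0:65]) == [(0, 0)]
        assert index.occurrences(seq[10:75]) == [(0, 10)]

    def test_absent_probe_has_no_hits(self, rng):
        index = SeedIndex(Assembly([SequenceRecord("r", "ACGT" * 100)]), 65)
        assert index.occurrences(random_seq(rng, 65)) == []

    def test_n_windows_never_indexed(self, rng):
        seq = random_seq(rng, 100) + "N" * 5 + random_seq(rng, 100)
        index = SeedIndex(Assembly([SequenceRecord("r", seq)]), 20)
        assert index.occurrences(seq[95:115]) == []


class TestFindSeeds:
    def test_identical_sequences_single_full_seed(self, rng):
        seq = random_seq(rng, 200)
        index = SeedIndex(Assembly([SequenceRecord("r", seq)]), 65)
        seeds = find_seeds(SequenceRecord("q", seq), index)
        assert mem_tuples(seeds) == {(0, 200, "r", 0, 200, "+")}

    def test_disjoint_sequences_no_seeds(self, rng):
        ref_seq = random_seq(rng, 500)
        q_seq = random_seq(rng, 500)
        index = SeedIndex(Assembly([SequenceRecord("r", ref_seq)]), 20)
        got = mem_tuples(find_seeds(SequenceRecord("q", q_seq), index))
        assert got == brute_force_mems(q_seq, {"r": ref_seq}, 20, 1)

    def test_mismatch_splits_into_two_seeds(self, rng):
        ref_seq = random_seq(rng, 400)
        q = list(ref_seq[100:300])
        old = q[80]
        q[80] = next(c for c in "ACGT" if c != old)
        q = "".join(q)
        index = SeedIndex(Assembly([SequenceRecord("r", ref_seq)]), 20)
        got = mem_tuples(find_seeds(SequenceRecord("q", q), index))
        assert got == brute_force_mems(q, {"r": ref_seq}, 20, 1)
        assert (0, 80, "r", 100, 180, "+") in got
        assert (81, 200, "r", 181, 300, "+") in got

    def test_reverse_complement_hit(self, rng):
        ref_seq = random_seq(rng, 300)
        q = reverse_complement(ref_seq[10:110])
        index = SeedIndex(Assembly([SequenceRecord("r", ref_seq)]), 20)
        got = mem_tuples(find_seeds(SequenceRecord("q", q), index))
        assert (0, 100, "r", 10, 110, "-") in got

    @pytest.mark.parametrize("trial", range(20))
    def test_matches_brute_force_on_mosaic_pairs(self, trial):
        """Planted-similarity query/reference pairs: exact MEM-set equality."""
        rng = np.random.default_rng(500 + trial)
        k = 20
        ref_seq = random_seq(rng, int(rng.integers(400, 1500)))
        parts = []
        for _ in range(4):
            s = int(rng.integers(0, len(ref_seq) - 100))
            seg = list(ref_seq[s : s + int(rng.integers(40, 180))])
            if rng.random() < 0.5:
                seg = list(reverse_complement("".join(seg)))
            for _ in range(int(rng.integers(0, 3))):
                p = int(rng.integers(0, len(seg)))
                seg[p] = "ACGT"[int(rng.integers(0, 4))]
            parts.append("".join(seg))
            parts.append(random_seq(rng, int(rng.integers(5, 40))))
        q = "".join(parts)
        index = SeedIndex(Assembly([SequenceRecord("r", ref_seq)]), k)
        got = mem_tuples(find_seeds(SequenceRecord("q", q), index, max_occ=1))
        assert got == brute_force_mems(q, {"r": ref_seq}, k, 1)


class TestChaining:
    def test_single_seed_chain(self):
        s = Seed("q", 0, 100, "r", 50, 150, "+")
        (chain,) = chain_seeds([s])
        assert chain.score == 100
        assert chain.seeds == [s]

    def test_two_seed_median_and_score(self):
        seeds = [Seed("q", 0, 100, "r", 0, 100, "+"),
                 Seed("q", 150, 250, "r", 160, 260, "+")]
        (chain,) = chain_seeds(seeds)
        assert chain.score == 200
        # midpoints 50 and 210; even-count median is the floor of their mean
        assert chain.r_median == 130
        assert (chain.q_start, chain.q_end) == (0, 250)
        assert (chain.r_start, chain.r_end) == (0, 260)

    def test_mixed_queries_rejected(self):
        with pytest.raises(ValueError, match="mixed"):
            chain_seeds([Seed("a", 0, 50, "r", 0, 50, "+"),
                         Seed("b", 0, 50, "r", 0, 50, "+")])

    @pytest.mark.parametrize("trial", range(50))
    def test_best_score_matches_exhaustive_enumeration(self, trial):
        rng = np.random.default_rng(900 + trial)
        n = int(rng.integers(1, 13))
        seeds = set()
        for _ in range(n):
            qs = int(rng.integers(0, 300))
            length = int(rng.integers(5, 50))
            rs = int(rng.integers(0, 300))
            strand = "+" if rng.random() < 0.7 else "-"
            seeds.add(Seed("q", qs, qs + length, "r", rs, rs + length, strand))
        seeds = list(seeds)
        best = max(c.score for c in chain_seeds(seeds))
        assert best == best_chain_score_brute(seeds)

    def test_every_seed_in_at_most_one_chain(self, rng):
        seeds = set()
        for _ in range(20):
            qs = int(rng.integers(0, 400))
            length = int(rng.integers(5, 40))
            rs = int(rng.integers(0, 400))
            seeds.add(Seed("q", qs, qs + length, "r", rs, rs + length, "+"))
        chains = chain_seeds(list(seeds))
        assigned = [s for c in chains for s in c.seeds]
        assert len(assigned) == len(set(assigned))
        assert set(assigned) == seeds

    def test_chain_scores_match_definition(self, rng):
        seeds = set()
        for _ in range(15):
            qs = int(rng.integers(0, 300))
            length = int(rng.integers(5, 60))
            rs = int(rng.integers(0, 300))
            seeds.add(Seed("q", qs, qs + length, "r", rs, rs + length, "+"))
        for chain in chain_seeds(list(seeds)):
            assert chain.score == oracle_chain_score(chain.seeds)

    def test_monotone_response_to_added_seed(self):
        """Adding a seed never decreases the best chain score."""
        rng = np.random.default_rng(77)
        base = []
        for _ in range(8):
            qs = int(rng.integers(0, 200))
            length = int(rng.integers(10, 40))
            rs = int(rng.integers(0, 200))
            base.append(Seed("q", qs, qs + length, "r", rs, rs + length, "+"))
        base = list(set(base))
        best_before = max(c.score for c in chain_seeds(base))
        for _ in range(10):
            qs = int(rng.integers(0, 250))
            length = int(rng.integers(10, 40))
            rs = int(rng.integers(0, 250))
            extra = Seed("q", qs, qs + length, "r", rs, rs + length, "+")
            if extra in base:
                continue
            best_after = max(c.score for c in chain_seeds(base + [extra]))
            assert best_after >= best_before

    def test_max_gap_splits_distant_colinear_seeds(self):
        seeds = [Seed("q", 0, 100, "r", 0, 100, "+"),
                 Seed("q", 10_000, 10_100, "r", 10_000, 10_100, "+")]
        joined = chain_seeds(seeds)
        assert len(joined) == 1
        split = chain_seeds(seeds, max_gap=5000)
        assert len(split) == 2


def test_revcomp_symmetry(rng):
    """Chaining the reverse-complemented query mirrors chains with equal scores."""
    ref_seq = random_seq(rng, 800)
    q = ref_seq[100:300] + random_seq(rng, 50) + ref_seq[400:650]
    index = SeedIndex(Assembly([SequenceRecord("r", ref_seq)]), 20)
    fwd = chain_seeds(find_seeds(SequenceRecord("q", q), index))
    rev = chain_seeds(find_seeds(SequenceRecord("q", reverse_complement(q)), index))
    assert sorted(c.score for c in fwd) == sorted(c.score for c in rev)
    strands = {"+": "-", "-": "+"}
    assert sorted((c.r_start, c.r_end, strands[c.strand]) for c in fwd) == \
        sorted((c.r_start, c.r_end, c.strand) for c in rev)
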