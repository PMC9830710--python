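"""Exact-match seed discovery and maximal monotonic chaining.

This is the alignment core shared by pseudo-chromosome anchoring and by the
structural-variant scanner.  A *seed* is a maximal exact match (MEM) between
a query sequence and a reference assembly, at least ``min_seed_len`` long
(the default of 65 reads the classic "larger than 64 bp" rule strictly) and
anchored at a probe k-mer that occurs at most ``max_occ`` times in the
reference, so that chains stay placement-informative in repeats.  A *chain*
is a maximum-score monotonic path over seeds of one (reference, strand)
group: query starts strictly increasing, reference starts strictly
increasing on '+' and strictly decreasing on '-', scored as summed matched
bases with query overlaps counted once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .formats import Assembly, SequenceRecord, reverse_complement

logger = logging.getLogger(__name__)

DEFAULT_MIN_SEED_LEN = 65  # strict reading of "seeds larger than 64 bp"
MIN_INDEXABLE_SEED = 16  # shorter probes are collision-prone


@dataclass(frozen=True, order=True)
class Seed:
    """A maximal exact match between one query and one reference sequence.

    Coordinates are 0-based half-open.  On strand '-', the query substring
    equals the reverse complement of the reference substring.
    """

    q_id: str
    q_start: int
    q_end: int
    r_id: str
    r_start: int
    r_end: int
    strand: str

    @property
    def length(self) -> int:
        return self.q_end - self.q_start

    def r_midpoint(self) -> int:
        return (self.r_start + self.r_end) // 2


@dataclass
class Chain:
    """A strand-consistent monotonic path of seeds from one query sequence."""

    q_id: str
    r_id: str
    strand: str
    seeds: list[Seed]
    score: int
    q_start: int
    q_end: int
    r_start: int
    r_end: int
    r_median: int

    @property
    def q_span_len(self) -> int:
        return self.q_end - self.q_start

    @property
    def r_span_len(self) -> int:
        return self.r_end - self.r_start


def _chain_from_seeds(seeds: list[Seed], score: int) -> Chain:
    mids = sorted(s.r_midpoint() for s in seeds)
    n = len(mids)
    if n % 2 == 1:
        median = mids[n // 2]
    else:
        # even count: floor of the mean of the two central midpoints
        median = (mids[n // 2 - 1] + mids[n // 2]) // 2
    return Chain(
        q_id=seeds[0].q_id,
        r_id=seeds[0].r_id,
        strand=seeds[0].strand,
        seeds=seeds,
        score=score,
        q_start=min(s.q_start for s in seeds),
        q_end=max(s.q_end for s in seeds),
        r_start=min(s.r_start for s in seeds),
        r_end=max(s.r_end for s in seeds),
        r_median=median,
    )


# ---------------------------------------------------------------------------
# seed index
# ---------------------------------------------------------------------------

class SeedIndex:
    """Hash index of every k-mer position of a reference assembly.

    Keys are Python string hashes of the k-mer; hits are verified against the
    reference text at lookup time, so collisions cost time but never
    correctness.  Windows containing N are never indexed.
    """

    def __init__(self, reference: Assembly, min_seed_len: int = DEFAULT_MIN_SEED_LEN):
        if min_seed_len < MIN_INDEXABLE_SEED:
            raise ValueError(
                f"min_seed_len {min_seed_len} < {MIN_INDEXABLE_SEED} is collision-prone"
            )
        if not reference.records:
            raise ValueError("cannot index an empty reference")
        self.reference = reference
        self.k = min_seed_len
        self._seqs: list[str] = [rec.seq for rec in reference.records]
        self._ids: list[str] = [rec.id for rec in reference.records]
        # comparison copies where N is replaced by a sentinel that matches
        # nothing, so exact-match extension can never run through a gap
        self._cmp: list[str] = [s.replace("N", "\x00") for s in self._seqs]
        self._table: dict[int, object] = {}
        k = self.k
        table = self._table
        for si, seq in enumerate(self._seqs):
            n = len(seq)
            next_n = seq.find("N")
            i = 0
            while i <= n - k:
                if next_n != -1 and next_n < i + k:
                    if next_n < i:
                        next_n = seq.find("N", i)
                        continue
                    i = next_n + 1
                    next_n = seq.find("N", i)
                    continue
                h = hash(seq[i : i + k])
                packed = (si << 34) | i  # chromosome index in high bits
                prev = table.get(h)
                if prev is None:
                    table[h] = packed
                elif isinstance(prev, int):
                    table[h] = [prev, packed]
                else:
                    prev.append(packed)
                i += 1

    def occurrences(self, probe: str) -> list[tuple[int, int]]:
        """Verified (sequence index, position) forward occurrences of a k-mer."""
        if len(probe) != self.k or "N" in probe:
            return []
        entry = self._table.get(hash(probe))
        if entry is None:
            return []
        packed = [entry] if isinstance(entry, int) else entry
        hits = []
        for p in packed:
            si, pos = p >> 34, p & ((1 << 34) - 1)
            if self._seqs[si][pos : pos + self.k] == probe:
                hits.append((si, pos))
        return hits

    def occurrence_count(self, probe: str) -> int:
        return len(self.occurrences(probe))


def _extend_match(qcmp: str, rcmp: str, q0: int, q1: int, r0: int, r1: int
                  ) -> tuple[int, int, int, int]:
    """Extend an exact match maximally in both directions.

    Works on the sentinel-substituted comparison strings, comparing slices in
    halving blocks so long extensions cost near O(length) C-level compares.
    """
    # right
    block = 4096
    while True:
        if block == 0:
            break
        b = min(block, len(qcmp) - q1, len(rcmp) - r1)
        if b > 0 and qcmp[q1 : q1 + b] == rcmp[r1 : r1 + b]:
            q1 += b
            r1 += b
        else:
            if block == 1:
                break
            block >>= 1
    # left
    block = 4096
    while True:
        if block == 0:
            break
        b = min(block, q0, r0)
        if b > 0 and qcmp[q0 - b : q0] == rcmp[r0 - b : r0]:
            q0 -= b
            r0 -= b
        else:
            if block == 1:
                break
            block >>= 1
    return q0, q1, r0, r1


def find_seeds(query: SequenceRecord, index: SeedIndex,
               max_occ: int = 1, stride: int = 1) -> list[Seed]:
    """All maximal exact matches of a query against the indexed reference.

    Probes of length ``index.k`` are taken every ``stride`` positions on both
    the query and its reverse complement; each verified unique-enough hit is
    extended to a maximal match.  With stride 1 this enumerates every MEM of
    length >= k that contains at least one probe window occurring at most
    ``max_occ`` times in the reference; a stride s > 1 trades MEMs shorter
    than k + s - 1 for probing speed.
    """
    k = index.k
    results: set[Seed] = set()
    qlen = len(query.seq)
    for strand, qseq in (("+", query.seq), ("-", reverse_complement(query.seq))):
        qcmp = qseq.replace("N", "\x01")
        covered: dict[tuple[int, int], int] = {}  # (seq idx, diagonal) -> probe-space end
        next_n = qseq.find("N")
        i = 0
        while i <= qlen - k:
            if next_n != -1 and next_n < i + k:
                if next_n < i:
                    next_n = qseq.find("N", i)
                    continue
                i = next_n + 1
                next_n = qseq.find("N", i)
                continue
            probe = qseq[i : i + k]
            hits = index.occurrences(probe)
            if hits and len(hits) <= max_occ:
                for si, pos in hits:
                    diag = pos - i
                    if covered.get((si, diag), -1) >= i + k:
                        continue
                    q0, q1, r0, r1 = _extend_match(
                        qcmp, index._cmp[si], i, i + k, pos, pos + k
                    )
                    covered[(si, diag)] = q1
                    if strand == "+":
                        seed = Seed(query.id, q0, q1, index._ids[si], r0, r1, "+")
                    else:
                        seed = Seed(query.id, qlen - q1, qlen - q0,
                                    index._ids[si], r0, r1, "-")
                    results.add(seed)
            i += stride
    return sorted(results, key=lambda s: (s.q_start, s.r_id, s.r_start, s.strand))


def find_seeds_assembly(query: Assembly, index: SeedIndex,
                        max_occ: int = 1, stride: int = 1) -> dict[str, list[Seed]]:
    """find_seeds for every record of an assembly, keyed by query id."""
    return {rec.id: find_seeds(rec, index, max_occ=max_occ, stride=stride)
            for rec in query.records}


# ---------------------------------------------------------------------------
# chaining
# ---------------------------------------------------------------------------

def chain_score_of(seeds: list[Seed]) -> int:
    """Score of an ordered seed list by definition: summed lengths with
    query overlaps between consecutive seeds counted once."""
    score = 0
    prev_end = None
    for s in seeds:
        contrib = s.length
        if prev_end is not None and s.q_start < prev_end:
            contrib -= min(contrib, prev_end - s.q_start)
        score += contrib
        prev_end = s.q_end if prev_end is None else max(prev_end, s.q_end)
    return score


def _best_chain_in_group(seeds: list[Seed], strand: str, gap_penalty: float,
                         max_gap: int | None) -> tuple[list[int], float]:
    """Weighted-LIS dynamic program over one (r_id, strand) seed group.

    Returns the index list of the best monotonic path and its score.  Ties
    prefer the earlier (smaller q_start, then smaller r_start) predecessor,
    which keeps extraction deterministic.
    """
    order = sorted(range(len(seeds)), key=lambda t: (seeds[t].q_start, seeds[t].r_start))
    best: list[float] = [0.0] * len(order)
    back: list[int] = [-1] * len(order)
    for jj, j in enumerate(order):
        sj = seeds[j]
        best[jj] = float(sj.length)
        for ii in range(jj):
            i = order[ii]
            si = seeds[i]
            # q_end must also increase: a seed nested in the running query
            # envelope contributes zero matched bases, so forbidding it loses
            # no score and makes the pairwise overlap trim exact
            if sj.q_start <= si.q_start or sj.q_end <= si.q_end:
                continue
            if strand == "+":
                if sj.r_start <= si.r_start:
                    continue
                r_gap = sj.r_start - si.r_end
            else:
                if sj.r_start >= si.r_start:
                    continue
                r_gap = si.r_start - sj.r_end
            q_gap = sj.q_start - si.q_end
            if max_gap is not None and (max(q_gap, 0) > max_gap or max(r_gap, 0) > max_gap):
                continue
            trimmed = sj.length - min(sj.length, max(0, si.q_end - sj.q_start))
            cand = best[ii] + trimmed - gap_penalty * max(q_gap, 0)
            if cand > best[jj]:
                best[jj] = cand
                back[jj] = ii
    top = max(range(len(order)), key=lambda t: (best[t], -seeds[order[t]].q_start))
    path = []
    t = top
    while t != -1:
        path.append(order[t])
        t = back[t]
    path.reverse()
    return path, best[top]


def chain_seeds(seeds: list[Seed], gap_penalty: float = 0.0,
                max_gap: int | None = None) -> list[Chain]:
    """Greedy extraction of maximal monotonic chains from one query's seeds.

    Per (r_id, strand) group the maximum-score monotonic path is computed by
    weighted longest-increasing-subsequence dynamic programming; the globally
    best chain is extracted, its seeds removed, and the process repeats, so
    each seed belongs to at most one chain.  Chains come back ranked by
    (score desc, r_id, strand, r_start).

    ``max_gap`` optionally forbids adjacent chain seeds separated by more
    than that many bases on query or reference, which keeps chains from
    bridging across rearrangement-scale discontinuities.
    """
    if not seeds:
        return []
    q_ids = {s.q_id for s in seeds}
    if len(q_ids) > 1:
        raise ValueError(f"seeds from mixed query sequences: {sorted(q_ids)}")
    groups: dict[tuple[str, str], list[Seed]] = {}
    for s in seeds:
        groups.setdefault((s.r_id, s.strand), []).append(s)
    chains: list[Chain] = []
    while groups:
        candidates = []
        for (r_id, strand), group in groups.items():
            path, score = _best_chain_in_group(group, strand, gap_penalty, max_gap)
            member = [group[t] for t in path]
            candidates.append((score, r_id, strand, member))
        # tie-breaking: higher score, then r_id, '+' before '-', smaller r_start
        candidates.sort(key=lambda c: (-c[0], c[1], c[2], min(s.r_start for s in c[3])))
        score, r_id, strand, member = candidates[0]
        member_sorted = sorted(member, key=lambda s: s.q_start)
        chains.append(_chain_from_seeds(member_sorted, chain_score_of(member_sorted)))
        remaining = [s for s in groups[(r_id, strand)] if s not in set(member)]
        if remaining:
            groups[(r_id, strand)] = remaining
        else:
            del groups[(r_id, strand)]
    chains.sort(key=lambda c: (-c.score, c.r_id, c.strand, c.r_start))
    return chains


def seeds_to_frame(seeds: list[Seed]):
    """Seed dump as a DataFrame for TSV debugging output."""
    import pandas as pd

    return pd.DataFrame(
        [(s.q_id, s.q_start, s.q_end, s.r_id, s.r_start, s.r_end, s.strand, s.length)
         for s in seeds],
        columns=["q_id", "q_start", "q_end", "r_id", "r_start", "r_end",
                 "strand", "length"],
    )
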