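"""Independent brute-force oracles for the alignment core.

These deliberately share no code path with the package: maximal exact
matches are enumerated from the full query-by-reference equality matrix via
numpy diagonal runs, and the best monotonic chain score is found by
exhaustive recursive enumeration of monotonic seed subsets.
"""

from __future__ import annotations

from collections import Counter

import numpy as np

_ENCODE = {c: i for i, c in enumerate("ACGT", start=3)}


def _encode(seq: str, n_sentinel: int) -> np.ndarray:
    return np.array([n_sentinel if c == "N" else _ENCODE[c] for c in seq],
                    dtype=np.int16)


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def _diagonal_runs(q: np.ndarray, r: np.ndarray, k: int):
    """All maximal equal runs of length >= k along every diagonal.

    Yields (q_start, q_end, r_start, r_end) with 0-based half-open coords.
    """
    nq, nr = len(q), len(r)
    match = q[:, None] == r[None, :]
    # skew rows so each column of the padded array is one diagonal
    skew = np.zeros((nq + 1, nq + nr), dtype=bool)
    for i in range(nq):
        skew[i, nq - 1 - i : nq - 1 - i + nr] = match[i]
    flat = skew.flatten(order="F")
    edges = np.flatnonzero(np.diff(np.concatenate(([False], flat, [False])).astype(np.int8)))
    starts, ends = edges[::2], edges[1::2]
    for s, e in zip(starts, ends):
        if e - s < k:
            continue
        col, i0 = divmod(int(s), nq + 1)
        run = int(e - s)
        d = col - (nq - 1)
        yield i0, i0 + run, i0 + d, i0 + d + run


def reference_kmer_counts(ref_records: dict[str, str], k: int) -> Counter:
    counts: Counter = Counter()
    for seq in ref_records.values():
        for i in range(len(seq) - k + 1):
            w = seq[i : i + k]
            if "N" not in w:
                counts[w] += 1
    return counts


def brute_force_mems(query: str, ref_records: dict[str, str], k: int,
                     max_occ: int = 1) -> set[tuple]:
    """All maximal exact matches of length >= k between query and reference,
    both strands, keeping a MEM only if at least one k-window of its
    reference substring occurs at most ``max_occ`` times in the reference.

    Returns tuples (q_start, q_end, r_id, r_start, r_end, strand).
    """
    counts = reference_kmer_counts(ref_records, k)
    q_arr = _encode(query, 1)
    out: set[tuple] = set()
    for r_id, r_seq in ref_records.items():
        r_arr = _encode(r_seq, 2)
        for q0, q1, r0, r1 in _diagonal_runs(q_arr, r_arr, k):
            sub = r_seq[r0:r1]
            if _anchorable(sub, counts, k, max_occ):
                out.add((q0, q1, r_id, r0, r1, "+"))
        rc = _revcomp(r_seq)
        rc_arr = _encode(rc, 2)
        n_r = len(r_seq)
        for q0, q1, p0, p1 in _diagonal_runs(q_arr, rc_arr, k):
            r0, r1 = n_r - p1, n_r - p0
            sub = r_seq[r0:r1]
            if _anchorable(sub, counts, k, max_occ):
                out.add((q0, q1, r_id, r0, r1, "-"))
    return out


def _anchorable(ref_sub: str, counts: Counter, k: int, max_occ: int) -> bool:
    return any(counts[ref_sub[i : i + k]] <= max_occ
               for i in range(len(ref_sub) - k + 1))


def oracle_chain_score(ordered_seeds) -> int:
    """Score of an ordered seed list by definition: summed lengths, query
    overlap between consecutive members counted once."""
    score, prev_end = 0, None
    for s in ordered_seeds:
        length = s.q_end - s.q_start
        trim = 0 if prev_end is None else min(length, max(0, prev_end - s.q_start))
        score += length - trim
        prev_end = s.q_end if prev_end is None else max(prev_end, s.q_end)
    return score


def best_chain_score_brute(seeds) -> int:
    """Exhaustive enumeration of all monotonic seed subsets, per
    (reference, strand) group; returns the best achievable chain score."""
    groups: dict[tuple, list] = {}
    for s in seeds:
        groups.setdefault((s.r_id, s.strand), []).append(s)
    best_overall = 0
    for (_, strand), group in groups.items():
        group = sorted(group, key=lambda s: (s.q_start, s.r_start))
        n = len(group)
        best = 0

        def rec(idx: int, prev, score: int, prev_end: int):
            nonlocal best
            if score > best:
                best = score
            for j in range(idx, n):
                s = group[j]
                if prev is not None:
                    if s.q_start <= prev.q_start:
                        continue
                    if strand == "+" and s.r_start <= prev.r_start:
                        continue
                    if strand == "-" and s.r_start >= prev.r_start:
                        continue
                length = s.q_end - s.q_start
                trim = 0 if prev_end < 0 else min(length, max(0, prev_end - s.q_start))
                rec(j + 1, s, score + length - trim, max(prev_end, s.q_end))

        rec(0, None, 0, -1)
        best_overall = max(best_overall, best)
    return best_overall


def naive_gap_runs(seq: str):
    """Per-character scan for maximal N-runs."""
    runs, start = [], None
    for i, c in enumerate(seq):
        if c == "N" and start is None:
            start = i
        elif c != "N" and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(seq)))
    return runs
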