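"""Assembly-vs-assembly structural-variant detection from alignment chains.

A deliberately simple block-level caller: per query chromosome, unique-anchor
seed chains are computed against the reference, a dominant colinear backbone
is selected by the same weighted-LIS machinery used for seed chaining, and
every chain is classified against that backbone as syntenic (SYN), inverted
(INV), translocated (TRL), duplicated (DUP) or the inverted flavors INVTL /
INVDP.  There is no base-level variant annotation and no nested-variant
resolution; the output vocabulary is the block palette used in whole-genome
synteny plots, plus the conventional "major SV" length filter (>= 1 Mbp at
genome scale) measured on the reference span.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from intervaltree import IntervalTree

from .formats import Assembly
from .seedchain import (DEFAULT_MIN_SEED_LEN, Chain, SeedIndex, chain_seeds,
                        find_seeds)

logger = logging.getLogger(__name__)

SV_TYPES = ("SYN", "INV", "TRL", "DUP", "INVDP", "INVTL")

MAJOR_SV_MIN_LEN = 1_000_000  # "1 Mbp or longer" at genome scale


@dataclass
class SvScanConfig:
    """Parameters of the chain-based scan.

    ``min_block`` is both the minimum reported block size and the merge /
    chain-break distance; ``dist_thresh`` the displacement beyond which a
    same-chromosome colinear chain counts as translocated (None selects
    10 x min_block).
    """

    min_seed_len: int = DEFAULT_MIN_SEED_LEN
    max_occ: int = 1
    stride: int = 1
    min_block: int = 5000
    dist_thresh: int | None = None

    @property
    def dist_thresh_effective(self) -> int:
        return self.dist_thresh if self.dist_thresh is not None else 10 * self.min_block


@dataclass
class SvCall:
    """One classified block; length is measured on the reference span."""

    type: str
    r_id: str
    r_start: int
    r_end: int
    q_id: str
    q_start: int
    q_end: int
    score: int

    def __post_init__(self) -> None:
        if self.type not in SV_TYPES:
            raise ValueError(f"unknown SV type {self.type}")
        if self.r_end <= self.r_start or self.q_end <= self.q_start:
            raise ValueError("SV intervals must be non-empty")

    @property
    def length(self) -> int:
        return self.r_end - self.r_start


def genome_chains(reference: Assembly, query: Assembly,
                  cfg: SvScanConfig | None = None,
                  index: SeedIndex | None = None) -> list[Chain]:
    """Unique-anchor chains of every query chromosome against the reference.

    Chains never bridge gaps larger than ``min_block`` on either coordinate,
    so rearrangement-scale discontinuities break the colinear backbone into
    separate blocks; chains spanning less than ``min_block`` of reference
    are discarded.
    """
    cfg = cfg or SvScanConfig()
    if index is None:
        index = SeedIndex(reference, cfg.min_seed_len)
    chains: list[Chain] = []
    for rec in query.records:
        seeds = find_seeds(rec, index, max_occ=cfg.max_occ, stride=cfg.stride)
        for ch in chain_seeds(seeds, max_gap=cfg.min_block):
            if ch.r_span_len >= cfg.min_block:
                chains.append(ch)
    chains.sort(key=lambda c: (c.q_id, c.q_start, c.r_id, c.r_start))
    return chains


def _backbone(chains: list[Chain], strand: str, max_ovl: int) -> list[int]:
    """Max-score colinear subset of same-strand chains (LIS over chains).

    Consecutive members must progress on both coordinates with at most
    ``max_ovl`` overlap, so a block re-covering earlier reference (a
    duplication) can never join the backbone.
    """
    idx = [i for i, c in enumerate(chains) if c.strand == strand]
    idx.sort(key=lambda i: (chains[i].q_start, chains[i].r_start))
    best = [0.0] * len(idx)
    back = [-1] * len(idx)
    for jj, j in enumerate(idx):
        cj = chains[j]
        best[jj] = float(cj.score)
        for ii in range(jj):
            ci = chains[idx[ii]]
            if cj.q_start < ci.q_end - max_ovl:
                continue
            if strand == "+":
                if cj.r_start < ci.r_end - max_ovl:
                    continue
            else:
                if cj.r_end > ci.r_start + max_ovl:
                    continue
            cand = best[ii] + cj.score
            if cand > best[jj]:
                best[jj] = cand
                back[jj] = ii
    if not idx:
        return []
    top = max(range(len(idx)), key=lambda t: best[t])
    out = []
    t = top
    while t != -1:
        out.append(idx[t])
        t = back[t]
    return sorted(out)


def call_svs(chains: list[Chain], cfg: SvScanConfig | None = None) -> list[SvCall]:
    """Classify chains against the dominant colinear backbone per query chromosome.

    Backbone members are SYN.  A '-' chain whose reference interval nests
    between its flanking backbone neighbors is an inversion; a chain on a
    non-dominant chromosome, or displaced beyond the distance threshold, is
    a translocation (inverted flavor INVTL); a chain re-covering > 50% of
    already-covered reference is a duplication (DUP / INVDP).  Adjacent
    same-type calls closer than ``min_block`` on both coordinates are
    merged.  Output ordering is deterministic: (q_id, q_start).
    """
    cfg = cfg or SvScanConfig()
    calls: list[SvCall] = []
    by_q: dict[str, list[Chain]] = {}
    for c in chains:
        by_q.setdefault(c.q_id, []).append(c)
    for q_id in sorted(by_q):
        group = by_q[q_id]
        weight: dict[str, int] = {}
        for c in group:
            weight[c.r_id] = weight.get(c.r_id, 0) + c.score
        dominant = min((r for r in weight), key=lambda r: (-weight[r], r))
        dom_chains = [c for c in group if c.r_id == dominant]
        strand_weight = {s: sum(c.score for c in dom_chains if c.strand == s)
                         for s in ("+", "-")}
        dom_strand = "+" if strand_weight["+"] >= strand_weight["-"] else "-"
        bb = set(_backbone(dom_chains, dom_strand, cfg.min_block))
        backbone_chains = sorted((dom_chains[i] for i in bb), key=lambda c: c.q_start)
        covered: dict[str, IntervalTree] = {dominant: IntervalTree()}
        for c in backbone_chains:
            covered[dominant].addi(c.r_start, c.r_end)
            calls.append(SvCall("SYN", c.r_id, c.r_start, c.r_end,
                                c.q_id, c.q_start, c.q_end, c.score))
        others = sorted((c for i, c in enumerate(dom_chains) if i not in bb),
                        key=lambda c: (-c.score, c.q_start)) + \
            sorted((c for c in group if c.r_id != dominant),
                   key=lambda c: (-c.score, c.q_start))
        for c in others:
            tree = covered.setdefault(c.r_id, IntervalTree())
            ovl = sum(min(iv.end, c.r_end) - max(iv.begin, c.r_start)
                      for iv in tree.overlap(c.r_start, c.r_end))
            if ovl > 0.5 * c.r_span_len:
                calls.append(SvCall("INVDP" if c.strand != dom_strand else "DUP",
                                    c.r_id, c.r_start, c.r_end,
                                    c.q_id, c.q_start, c.q_end, c.score))
                continue
            if c.r_id != dominant:
                sv_type = "INVTL" if c.strand != dom_strand else "TRL"
            elif c.strand != dom_strand:
                sv_type = ("INV" if _nests_in_backbone(c, backbone_chains, cfg)
                           else "INVTL")
            else:
                # same strand, same chromosome, off-backbone: displaced block
                sv_type = ("TRL" if not _nests_in_backbone(c, backbone_chains, cfg)
                           else "SYN")
            tree.addi(c.r_start, c.r_end)
            calls.append(SvCall(sv_type, c.r_id, c.r_start, c.r_end,
                                c.q_id, c.q_start, c.q_end, c.score))
    calls = _merge_adjacent(calls, cfg.min_block)
    calls.sort(key=lambda s: (s.q_id, s.q_start, s.r_id, s.r_start))
    return calls


def _nests_in_backbone(c: Chain, backbone: list[Chain], cfg: SvScanConfig) -> bool:
    """True when the chain's reference interval sits where its query position
    predicts: between the reference spans of the flanking backbone chains,
    within the displacement threshold."""
    slack = cfg.dist_thresh_effective
    prev = [b for b in backbone if b.q_end <= c.q_start + cfg.min_block]
    nxt = [b for b in backbone if b.q_start >= c.q_end - cfg.min_block]
    lo = max(b.r_end for b in prev) if prev else None
    hi = min(b.r_start for b in nxt) if nxt else None
    # dominant '-' backbones run reference-descending: swap the bounds
    if backbone and backbone[0].strand == "-":
        lo2 = max(b.r_end for b in nxt) if nxt else None
        hi2 = min(b.r_start for b in prev) if prev else None
        lo, hi = lo2, hi2
    if lo is not None and c.r_start < lo - slack:
        return False
    if hi is not None and c.r_end > hi + slack:
        return False
    return True


def _merge_adjacent(calls: list[SvCall], min_block: int) -> list[SvCall]:
    """Merge same-type calls adjacent on both query and reference."""
    out: list[SvCall] = []
    for call in sorted(calls, key=lambda s: (s.type, s.q_id, s.r_id, s.q_start)):
        if out:
            last = out[-1]
            if (last.type == call.type and last.q_id == call.q_id
                    and last.r_id == call.r_id
                    and 0 <= call.q_start - last.q_end < min_block
                    and (abs(call.r_start - last.r_end) < min_block
                         or abs(last.r_start - call.r_end) < min_block)):
                out[-1] = SvCall(last.type, last.r_id,
                                 min(last.r_start, call.r_start),
                                 max(last.r_end, call.r_end),
                                 last.q_id,
                                 min(last.q_start, call.q_start),
                                 max(last.q_end, call.q_end),
                                 last.score + call.score)
                continue
        out.append(call)
    return out


def filter_major(svs: list[SvCall], min_len: int = MAJOR_SV_MIN_LEN) -> list[SvCall]:
    """Non-syntenic calls at least ``min_len`` long on the reference span."""
    return [s for s in svs if s.type != "SYN" and s.length >= min_len]


def svs_to_frame(svs: list[SvCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.type, s.r_id, s.r_start, s.r_end, s.q_id, s.q_start, s.q_end,
          s.length, s.score) for s in svs],
        columns=["type", "r_id", "r_start", "r_end", "q_id", "q_start", "q_end",
                 "length", "score"],
    )
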