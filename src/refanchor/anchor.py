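"""Reference-guided pseudo-chromosome reconstruction.

The anchoring engine reproduces the classic reference-guided pipeline:
scaffolds are seeded and chained against a reference genome; scaffolds with
more than one significant mapping locus (different chromosomes, or loci
further apart than a distance threshold on one chromosome) are flagged as
suspected chimeras and split, the parts renamed with "-1", "-2", ...
suffixes; the split scaffolds are re-chained and placed greedily, best chain
first, onto still-vacant reference intervals; and per reference chromosome
the placed scaffolds are ordered by the median reference midpoint of their
supporting chain, reverse-complemented where placed on '-', and joined with
fixed-length N gaps (100 bp by default) into pseudo-chromosomes with full
AGP provenance.

This placement logic is exactly the mechanism by which reference structure
can be inherited: a rearrangement whose breakpoints no scaffold spans is
silently erased, because its fragments are re-ordered to match the
reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from intervaltree import IntervalTree

from .formats import (AgpRecord, Assembly, GapMap, SequenceRecord, gap_map,
                      reverse_complement, sequence_gap_runs)
from .seedchain import (DEFAULT_MIN_SEED_LEN, Chain, SeedIndex, chain_seeds,
                        find_seeds)

logger = logging.getLogger(__name__)


@dataclass
class AnchorConfig:
    """Tunable parameters of the anchoring engine.

    ``sig_abs``/``sig_frac`` define chain significance (score at least
    max(sig_abs, sig_frac x scaffold's best score)); ``dist_thresh`` is the
    same-chromosome distance beyond which two mapping loci count as distinct
    (None selects max(dist_base, 2 x scaffold length) per scaffold);
    ``ovl_frac`` is the tolerated fractional overlap with already-occupied
    reference intervals; ``gap_len`` the reconstruction gap inserted between
    consecutive placed scaffolds.
    """

    min_seed_len: int = DEFAULT_MIN_SEED_LEN
    max_occ: int = 1
    stride: int = 1
    sig_abs: int | None = None  # None -> 5 * min_seed_len
    sig_frac: float = 0.25
    dist_thresh: int | None = None  # None -> max(dist_base, 2 * scaffold length)
    dist_base: int = 1_000_000
    ovl_frac: float = 0.2
    gap_len: int = 100

    @property
    def sig_abs_effective(self) -> int:
        return self.sig_abs if self.sig_abs is not None else 5 * self.min_seed_len

    def dist_thresh_for(self, scaffold_len: int) -> int:
        if self.dist_thresh is not None:
            return self.dist_thresh
        return max(self.dist_base, 2 * scaffold_len)


@dataclass
class BreakDirective:
    """Suspected chimera: where to cut a scaffold and why."""

    scaffold_id: str
    positions: list[int]  # strictly inside the scaffold, sorted
    reasons: list[str]  # one per position
    chain_ids: list[int] = field(default_factory=list)


@dataclass
class Placement:
    """One scaffold's (possibly unplaced) assignment to a reference slot."""

    scaffold_id: str
    r_id: str | None
    r_median: int | None
    orientation: str | None
    status: str  # placed | unplaced
    chain: Chain | None = None


@dataclass
class PseudoChromosomeSet:
    """Emitted pseudo-chromosomes plus the unplaced bin and AGP provenance."""

    assembly: Assembly
    unplaced: Assembly
    agp: list[AgpRecord]
    placements: list[Placement]

    def placement_frame(self) -> pd.DataFrame:
        rows = [
            (p.scaffold_id, p.status, p.r_id or "-",
             p.r_median if p.r_median is not None else -1,
             p.orientation or "-",
             p.chain.score if p.chain else 0)
            for p in self.placements
        ]
        return pd.DataFrame(rows, columns=["scaffold", "status", "chromosome",
                                           "order_key", "orientation", "score"])


def significant_chains(chains: list[Chain], sig_abs: int, sig_frac: float) -> list[Chain]:
    if not chains:
        return []
    best = max(c.score for c in chains)
    floor = max(sig_abs, sig_frac * best)
    return [c for c in chains if c.score >= floor]


# ---------------------------------------------------------------------------
# chimera detection and splitting
# ---------------------------------------------------------------------------

def detect_chimeras(chains_by_scaffold: dict[str, list[Chain]], cfg: AnchorConfig,
                    scaffolds: Assembly | None = None,
                    gapmap: GapMap | None = None) -> list[BreakDirective]:
    """Flag scaffolds whose significant chains indicate more than one locus.

    Significant chains are clustered into mapping loci (same chromosome and
    reference gap <= dist_thresh); two or more loci make the scaffold a
    suspected chimera.  Each break lands at the midpoint of the query
    interval between adjacent loci, snapped to an N-run inside that interval
    when one exists (mis-joins tend to sit at scaffolding gaps).
    """
    directives: list[BreakDirective] = []
    for scf_id in sorted(chains_by_scaffold):
        chains = chains_by_scaffold[scf_id]
        scf_len = len(scaffolds[scf_id].seq) if scaffolds and scf_id in scaffolds else None
        dist = cfg.dist_thresh_for(scf_len if scf_len else 0)
        sig = significant_chains(chains, cfg.sig_abs_effective, cfg.sig_frac)
        if len(sig) < 2:
            continue
        loci = _cluster_loci(sig, dist)
        if len(loci) < 2:
            continue
        loci.sort(key=lambda group: min(c.q_start for c in group))
        positions, reasons = [], []
        runs = gapmap[scf_id] if gapmap is not None else (
            sequence_gap_runs(scaffolds[scf_id].seq) if scaffolds and scf_id in scaffolds else []
        )
        for left, right in zip(loci, loci[1:]):
            left_end = max(c.q_end for c in left)
            right_start = min(c.q_start for c in right)
            lo, hi = sorted((left_end, right_start))
            mid = (lo + hi) // 2
            inside = [r for r in runs if r[0] >= lo and r[1] <= hi]
            if inside:
                # snap to the N-run nearest the midpoint; break at run start
                mid = min(inside, key=lambda r: abs((r[0] + r[1]) // 2 - mid))[0]
            reason = ("different_chromosomes"
                      if left[0].r_id != right[0].r_id else "distant_same_chromosome")
            if scf_len is not None:
                mid = max(1, min(mid, scf_len - 1))
            positions.append(mid)
            reasons.append(reason)
        # drop degenerate duplicates from overlapping query spans
        seen, pos_u, rea_u = set(), [], []
        for p, r in zip(positions, reasons):
            if p not in seen:
                seen.add(p)
                pos_u.append(p)
                rea_u.append(r)
        order = sorted(range(len(pos_u)), key=lambda t: pos_u[t])
        directives.append(BreakDirective(scf_id, [pos_u[t] for t in order],
                                         [rea_u[t] for t in order]))
    return directives


def _cluster_loci(chains: list[Chain], dist_thresh: int) -> list[list[Chain]]:
    """Group chains into mapping loci: same chromosome, reference gap <= dist."""
    by_chrom: dict[str, list[Chain]] = {}
    for c in chains:
        by_chrom.setdefault(c.r_id, []).append(c)
    loci = []
    for chrom in sorted(by_chrom):
        group = sorted(by_chrom[chrom], key=lambda c: c.r_start)
        current = [group[0]]
        for c in group[1:]:
            if c.r_start - max(x.r_end for x in current) <= dist_thresh:
                current.append(c)
            else:
                loci.append(current)
                current = [c]
        loci.append(current)
    return loci


def split_scaffold(scaffold: SequenceRecord,
                   directive: BreakDirective | None) -> list[SequenceRecord]:
    """Cut a scaffold at the directive's positions.

    Parts are renamed "<id>-1", "<id>-2", ... in coordinate order and their
    concatenation reproduces the original sequence.  A cut aimed at (or
    inside) an N-run is moved to the run's end, so the run stays with the
    left part.
    """
    if directive is None or not directive.positions:
        return [scaffold]
    n = len(scaffold.seq)
    runs = sequence_gap_runs(scaffold.seq)
    cuts = []
    for pos in directive.positions:
        if not 0 < pos < n:
            raise ValueError(f"break position {pos} outside scaffold {scaffold.id}")
        for s, e in runs:
            if s <= pos < e:
                pos = e  # keep the N-run in the left part
                break
        if 0 < pos < n:
            cuts.append(pos)
    cuts = sorted(set(cuts))
    bounds = [0] + cuts + [n]
    if len(bounds) < 3:
        return [scaffold]
    return [
        SequenceRecord(f"{scaffold.id}-{k + 1}", scaffold.seq[s:e])
        for k, (s, e) in enumerate(zip(bounds, bounds[1:]))
    ]


# ---------------------------------------------------------------------------
# placement
# ---------------------------------------------------------------------------

def place_scaffolds(chains_by_scaffold: dict[str, list[Chain]],
                    reference: Assembly | None, cfg: AnchorConfig) -> list[Placement]:
    """Greedy best-first assignment of scaffolds to vacant reference intervals.

    All significant chains are ranked by score; a chain is accepted when its
    scaffold is still unplaced and its reference span overlaps the occupied
    intervals of that chromosome by at most ``ovl_frac`` of its own span.
    Lower-scored chains of a scaffold stay in the queue and can win later
    iterations, so a scaffold outcompeted at one locus can still land at its
    second-best locus.
    """
    candidates: list[tuple[Chain, str]] = []
    for scf_id, chains in chains_by_scaffold.items():
        for c in significant_chains(chains, cfg.sig_abs_effective, cfg.sig_frac):
            candidates.append((c, scf_id))
    candidates.sort(key=lambda t: (-t[0].score, t[0].q_id, t[0].r_start, t[0].strand))
    occupied: dict[str, IntervalTree] = {}
    placements: list[Placement] = []
    placed: set[str] = set()
    for chain, scf_id in candidates:
        if scf_id in placed:
            continue
        tree = occupied.setdefault(chain.r_id, IntervalTree())
        span = chain.r_span_len
        ovl = 0
        for iv in tree.overlap(chain.r_start, chain.r_end):
            ovl += min(iv.end, chain.r_end) - max(iv.begin, chain.r_start)
        if span == 0 or ovl > cfg.ovl_frac * span:
            continue
        tree.addi(chain.r_start, chain.r_end)
        placed.add(scf_id)
        placements.append(Placement(scf_id, chain.r_id, chain.r_median,
                                    chain.strand, "placed", chain))
    for scf_id in sorted(chains_by_scaffold):
        if scf_id not in placed:
            placements.append(Placement(scf_id, None, None, None, "unplaced"))
    return placements


def build_pseudochromosomes(placements: list[Placement], scaffolds: Assembly,
                            gap_len: int = 100,
                            name: str = "pseudo") -> PseudoChromosomeSet:
    """Emit gapped pseudo-chromosomes from placements.

    Placed scaffolds are sorted by the chain's reference-median order key
    (ties by scaffold id), '-' placements reverse-complemented, and joined
    with ``gap_len`` N between consecutive components.  Chromosomes without
    any placement are omitted; unplaced scaffolds are copied unchanged into
    the unplaced bin.
    """
    seen: set[str] = set()
    for p in placements:
        if p.status != "placed":
            continue
        if p.scaffold_id in seen:
            raise ValueError(f"duplicate placement of scaffold {p.scaffold_id}")
        seen.add(p.scaffold_id)
    by_chrom: dict[str, list[Placement]] = {}
    for p in placements:
        if p.status == "placed":
            by_chrom.setdefault(p.r_id, []).append(p)
    assembly = Assembly(name=name)
    agp: list[AgpRecord] = []
    for chrom in sorted(by_chrom):
        ordered = sorted(by_chrom[chrom], key=lambda p: (p.r_median, p.scaffold_id))
        parts = []
        pos1 = 1
        part_no = 0
        for k, p in enumerate(ordered):
            if k > 0:
                part_no += 1
                agp.append(AgpRecord(chrom, pos1, pos1 + gap_len - 1, part_no, "N",
                                     gap_length=gap_len, gap_type="scaffold",
                                     linkage="no", linkage_evidence="na"))
                parts.append("N" * gap_len)
                pos1 += gap_len
            seq = scaffolds[p.scaffold_id].seq
            part_no += 1
            agp.append(AgpRecord(chrom, pos1, pos1 + len(seq) - 1, part_no, "W",
                                 component_id=p.scaffold_id, component_beg=1,
                                 component_end=len(seq), orientation=p.orientation))
            parts.append(seq if p.orientation == "+" else reverse_complement(seq))
            pos1 += len(seq)
        assembly.add(SequenceRecord(chrom, "".join(parts)))
    unplaced = Assembly(name=f"{name}_unplaced")
    for p in placements:
        if p.status == "unplaced" and p.scaffold_id in scaffolds:
            rec = scaffolds[p.scaffold_id]
            unplaced.add(SequenceRecord(rec.id, rec.seq))
    return PseudoChromosomeSet(assembly, unplaced, agp, placements)


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------

def scaffold_chains(query: Assembly, index: SeedIndex, cfg: AnchorConfig
                    ) -> dict[str, list[Chain]]:
    """Seeds and chains per scaffold; chains never bridge gaps beyond the
    scaffold's own distance threshold, so distant loci stay separate."""
    out: dict[str, list[Chain]] = {}
    for rec in query.records:
        seeds = find_seeds(rec, index, max_occ=cfg.max_occ, stride=cfg.stride)
        out[rec.id] = chain_seeds(seeds, max_gap=cfg.dist_thresh_for(len(rec.seq)))
    return out


def anchor_pipeline(query: Assembly, reference: Assembly, cfg: AnchorConfig | None = None,
                    index: SeedIndex | None = None,
                    name: str = "pseudo") -> PseudoChromosomeSet:
    """Full anchoring run: chain, split chimeras, re-chain, place, build.

    A prebuilt :class:`SeedIndex` of the reference may be passed to amortize
    indexing across runs against the same reference.
    """
    cfg = cfg or AnchorConfig()
    if not query.records:
        logger.warning("anchoring an empty query assembly")
        return PseudoChromosomeSet(Assembly(name=name),
                                   Assembly(name=f"{name}_unplaced"), [], [])
    if index is None:
        index = SeedIndex(reference, cfg.min_seed_len)
    chains = scaffold_chains(query, index, cfg)
    directives = {d.scaffold_id: d for d in
                  detect_chimeras(chains, cfg, scaffolds=query, gapmap=gap_map(query))}
    post_split = Assembly(name=f"{query.name}_split")
    for rec in query.records:
        for part in split_scaffold(rec, directives.get(rec.id)):
            post_split.add(part)
    if directives:
        logger.info("split %d suspected chimeric scaffold(s)", len(directives))
        # re-chain only the new split parts; intact scaffolds keep their chains
        parts_only = Assembly(
            [rec for rec in post_split.records if rec.id not in chains],
            name="split_parts")
        chains = {k: v for k, v in chains.items() if k not in directives}
        chains.update(scaffold_chains(parts_only, index, cfg))
    placements = place_scaffolds(chains, reference, cfg)
    return build_pseudochromosomes(placements, post_split, gap_len=cfg.gap_len, name=name)
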