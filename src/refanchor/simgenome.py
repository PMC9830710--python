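"""Truth-tracked synthetic genomes with planted rearrangements.

The simulator stands in for the real multi-chromosome assemblies: it
produces a random reference genome, a derived genome carrying planted
inversions / translocations / duplications, a fragmentation of the derived
genome into gapped scaffolds (optionally chimeric), and long-insert mate
pairs, while recording every event in a :class:`SimTruth` registry so that
downstream calls can be scored against ground truth.

Derived chromosomes are represented internally as lists of *blocks*
(source chromosome, interval, strand, event tags).  Rearrangements are block
operations in original reference coordinates, which keeps the truth
bookkeeping exact even when several length-changing events land on one
chromosome.  Events must be non-overlapping by construction; nested
rearrangements are rejected.

All randomness flows from a single integer seed through a
``numpy.random.default_rng`` generator owned by the caller or derived from
the config; no global state is touched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .formats import AgpRecord, Assembly, SequenceRecord, reverse_complement

logger = logging.getLogger(__name__)

MIN_CONTIG_LEN = 200

SV_KINDS = ("INV", "TRL", "DUP")


@dataclass
class SvSpec:
    """A planted rearrangement in original reference coordinates.

    ``start``/``length`` delimit the source segment on ``chrom``; TRL and
    DUP additionally name an insertion point (``dest_chrom``, ``dest_pos``),
    which must not fall inside any other spec's segment.
    """

    kind: str
    chrom: str
    start: int
    length: int
    dest_chrom: str | None = None
    dest_pos: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in SV_KINDS:
            raise ValueError(f"unknown SV kind {self.kind!r}")
        if self.length <= 0 or self.start < 0:
            raise ValueError("SV interval must be positive-length and in bounds")
        if self.kind in ("TRL", "DUP") and (self.dest_chrom is None or self.dest_pos is None):
            raise ValueError(f"{self.kind} spec needs dest_chrom and dest_pos")

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass
class SimConfig:
    """Study conditions for one simulated dataset.

    Defaults follow the scales the package is exercised at: two 1-Mb
    chromosomes, ~40 kb contigs grouped into small scaffolds with 1,000 bp
    intra-scaffold N gaps, and 2–5 kbp mate-pair inserts.
    """

    n_chrom: int = 2
    chrom_len: int = 1_000_000
    gc: float = 0.5
    sv_specs: list[SvSpec] = field(default_factory=list)
    frag_mean: int = 40_000
    frag_sd: int = 10_000
    scaffold_gap_len: int = 1000
    contigs_per_scaffold: float = 3.0
    chimera_rate: float = 0.0
    insert_min: int = 2000
    insert_max: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chrom < 1 or self.chrom_len < 1:
            raise ValueError("n_chrom and chrom_len must be positive")
        if not 0.0 < self.gc < 1.0:
            raise ValueError("gc must be in (0,1)")
        if self.frag_mean <= 0 or self.frag_sd < 0 or self.scaffold_gap_len <= 0:
            raise ValueError("fragmentation parameters must be positive")
        if not 0.0 <= self.chimera_rate <= 1.0:
            raise ValueError("chimera_rate must be in [0,1]")
        if not 0 < self.insert_min <= self.insert_max:
            raise ValueError("need 0 < insert_min <= insert_max")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class PlantedSv:
    """One realized rearrangement in both coordinate systems."""

    kind: str
    ref_chrom: str
    ref_start: int
    ref_end: int
    derived_chrom: str
    derived_start: int
    derived_end: int
    inverted: bool


@dataclass
class SimTruth:
    """Ground-truth registry: planted events, fragmentation map, chimera joins."""

    planted_svs: list[PlantedSv] = field(default_factory=list)
    # contig id -> (derived chromosome, start, end); fragmentation never flips
    frag_map: dict[str, tuple[str, int, int]] = field(default_factory=dict)
    # scaffold id -> ordered member contig ids
    scaffold_members: dict[str, list[str]] = field(default_factory=dict)
    # chimeric scaffold id -> list of (join position on scaffold, left contig, right contig)
    chimera_joins: dict[str, list[tuple[int, str, str]]] = field(default_factory=dict)
    seed: int = 0

    def inversions(self) -> list[PlantedSv]:
        return [s for s in self.planted_svs if s.kind == "INV"]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("sv", s.kind, s.ref_chrom, s.ref_start, s.ref_end,
             s.derived_chrom, s.derived_start, s.derived_end, int(s.inverted))
            for s in self.planted_svs
        ] + [
            ("contig", "-", chrom, start, end, cid, -1, -1, 0)
            for cid, (chrom, start, end) in sorted(self.frag_map.items())
        ] + [
            ("chimera_join", "-", scf, pos, pos, f"{left}|{right}", -1, -1, 0)
            for scf, joins in sorted(self.chimera_joins.items())
            for pos, left, right in joins
        ]
        return pd.DataFrame(
            rows, columns=["record", "kind", "chrom_or_source", "start", "end",
                           "name", "derived_start", "derived_end", "inverted"],
        )


# ---------------------------------------------------------------------------
# reference simulation
# ---------------------------------------------------------------------------

def simulate_reference(cfg: SimConfig, rng: np.random.Generator | None = None,
                       name: str = "ref") -> Assembly:
    """I.i.d. random chromosomes with the configured GC fraction."""
    rng = cfg.rng() if rng is None else rng
    p = np.array([(1 - cfg.gc) / 2, cfg.gc / 2, cfg.gc / 2, (1 - cfg.gc) / 2])
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    records = []
    for c in range(cfg.n_chrom):
        draws = rng.choice(bases, size=cfg.chrom_len, p=p)
        records.append(SequenceRecord(f"chr{c + 1}", draws.tobytes().decode("ascii")))
    return Assembly(records, name=name)


# ---------------------------------------------------------------------------
# rearrangements
# ---------------------------------------------------------------------------

@dataclass
class _Block:
    src_chrom: str
    start: int
    end: int
    strand: str
    tags: frozenset

    def __len__(self) -> int:
        return self.end - self.start


def _split_original(blocks: list[_Block], chrom: str, pos: int) -> list[_Block]:
    """Split any block holding original coordinate ``pos`` of ``chrom``.

    Because event segments never overlap, the coordinate can only sit inside
    an untouched forward block of its own chromosome; the defensive '-'
    branch keeps display order correct regardless.
    """
    out: list[_Block] = []
    for b in blocks:
        if b.src_chrom == chrom and b.start < pos < b.end:
            left = replace(b, end=pos)
            right = replace(b, start=pos)
            out.extend([left, right] if b.strand == "+" else [right, left])
        else:
            out.append(b)
    return out


def _segment_indices(blocks: list[_Block], spec: SvSpec) -> list[int]:
    """Display indices of the (contiguous) blocks covering a spec's segment."""
    idx = [i for i, b in enumerate(blocks)
           if b.src_chrom == spec.chrom and spec.start <= b.start and b.end <= spec.end]
    if not idx or idx != list(range(idx[0], idx[-1] + 1)):
        raise AssertionError(f"segment of {spec} is not contiguous in block list")
    if sum(len(blocks[i]) for i in idx) != spec.length:
        raise AssertionError(f"segment of {spec} does not tile its interval")
    return idx


def _insert_index(blocks: list[_Block], chrom: str, pos: int) -> int:
    """Display index at which original coordinate ``pos`` of ``chrom`` is a boundary."""
    for i, b in enumerate(blocks):
        if b.src_chrom == chrom and b.strand == "+" and b.start == pos:
            return i
    for i in range(len(blocks) - 1, -1, -1):
        b = blocks[i]
        if b.src_chrom == chrom and b.strand == "+" and b.end == pos:
            return i + 1
    raise AssertionError(f"no block boundary at {chrom}:{pos}")


def _flip(block: _Block) -> _Block:
    return replace(block, strand="-" if block.strand == "+" else "+")


def apply_svs(ref: Assembly, sv_specs: Sequence[SvSpec], seed: int = 0,
              name: str = "derived") -> tuple[Assembly, SimTruth]:
    """Apply planted rearrangements to a reference genome.

    INV replaces a segment with its reverse complement in place; TRL excises
    a segment and reinserts it at the stated point (possibly on another
    chromosome); DUP inserts a copy of a segment at the stated point.  All
    spec coordinates are original reference coordinates and segments must be
    pairwise non-overlapping, with insertion points outside every segment.
    """
    _validate_specs(ref, sv_specs)
    blocks: dict[str, list[_Block]] = {
        rec.id: [_Block(rec.id, 0, len(rec.seq), "+", frozenset())]
        for rec in ref.records
    }
    for event_idx, spec in enumerate(sv_specs):
        tag = frozenset([event_idx])
        ch = _split_original(blocks[spec.chrom], spec.chrom, spec.start)
        ch = _split_original(ch, spec.chrom, spec.end)
        blocks[spec.chrom] = ch
        idx = _segment_indices(ch, spec)
        i0, i1 = idx[0], idx[-1] + 1
        segment = [replace(b, tags=b.tags | tag) for b in ch[i0:i1]]
        if spec.kind == "INV":
            blocks[spec.chrom] = ch[:i0] + [_flip(b) for b in reversed(segment)] + ch[i1:]
            continue
        if spec.kind == "TRL":
            blocks[spec.chrom] = ch[:i0] + ch[i1:]
        # DUP keeps the source untagged in place; the inserted copy is tagged
        dest = _split_original(blocks[spec.dest_chrom], spec.dest_chrom, spec.dest_pos)
        j = _insert_index(dest, spec.dest_chrom, spec.dest_pos)
        blocks[spec.dest_chrom] = dest[:j] + segment + dest[j:]

    derived = Assembly(name=name)
    truth = SimTruth(seed=seed)
    locate: dict[int, tuple[str, int, int, bool]] = {}
    for chrom_id in ref.ids():
        parts = []
        offset = 0
        spans: dict[int, list[int]] = {}
        flips: dict[int, bool] = {}
        for b in blocks[chrom_id]:
            seg = ref[b.src_chrom].seq[b.start : b.end]
            parts.append(seg if b.strand == "+" else reverse_complement(seg))
            for t in b.tags:
                spans.setdefault(t, []).extend([offset, offset + len(b)])
                flips[t] = flips.get(t, False) or (b.strand == "-")
            offset += len(b)
        if parts:
            derived.add(SequenceRecord(chrom_id, "".join(parts)))
        for t, coords in spans.items():
            locate[t] = (chrom_id, min(coords), max(coords), flips[t])
    for event_idx, spec in enumerate(sv_specs):
        d_chrom, d_start, d_end, inverted = locate[event_idx]
        truth.planted_svs.append(
            PlantedSv(spec.kind, spec.chrom, spec.start, spec.end,
                      d_chrom, d_start, d_end, inverted)
        )
    return derived, truth


def _validate_specs(ref: Assembly, sv_specs: Sequence[SvSpec]) -> None:
    intervals: dict[str, list[tuple[int, int]]] = {}
    for spec in sv_specs:
        if spec.chrom not in ref:
            raise ValueError(f"SV names unknown chromosome {spec.chrom}")
        if spec.end > len(ref[spec.chrom].seq):
            raise ValueError(f"SV interval out of bounds on {spec.chrom}")
        intervals.setdefault(spec.chrom, []).append((spec.start, spec.end))
        if spec.dest_chrom is not None:
            if spec.dest_chrom not in ref:
                raise ValueError(f"SV destination names unknown chromosome {spec.dest_chrom}")
            if not 0 <= spec.dest_pos <= len(ref[spec.dest_chrom].seq):
                raise ValueError("SV destination out of bounds")
    for chrom, ivs in intervals.items():
        ivs.sort()
        for (s0, e0), (s1, e1) in zip(ivs, ivs[1:]):
            if s1 < e0:
                raise ValueError(f"overlapping SV specs on {chrom}: [{s0},{e0}) and [{s1},{e1})")
    for spec in sv_specs:
        if spec.dest_pos is None:
            continue
        for s, e in intervals.get(spec.dest_chrom, []):
            if s < spec.dest_pos < e:
                raise ValueError("SV insertion point falls inside another SV segment")


def random_sv_specs(ref: Assembly, rng: np.random.Generator, count: int,
                    kind: str = "INV", length_range: tuple[int, int] = (50_000, 200_000),
                    margin: int = 20_000, max_tries: int = 1000) -> list[SvSpec]:
    """Randomly place non-overlapping SV specs with chromosome-end margins."""
    specs: list[SvSpec] = []
    taken: dict[str, list[tuple[int, int]]] = {}
    chrom_ids = ref.ids()
    tries = 0
    while len(specs) < count and tries < max_tries:
        tries += 1
        chrom = chrom_ids[int(rng.integers(len(chrom_ids)))]
        clen = len(ref[chrom].seq)
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        if clen < length + 2 * margin:
            continue
        start = int(rng.integers(margin, clen - margin - length + 1))
        padded = (start - margin, start + length + margin)
        if any(s < padded[1] and padded[0] < e for s, e in taken.get(chrom, [])):
            continue
        dest = None, None
        if kind in ("TRL", "DUP"):
            dchrom = chrom_ids[int(rng.integers(len(chrom_ids)))]
            dpos = int(rng.integers(margin, len(ref[dchrom].seq) - margin))
            if any(s <= dpos < e for s, e in taken.get(dchrom, [])):
                continue
            dest = dchrom, dpos
        specs.append(SvSpec(kind, chrom, start, length, dest[0], dest[1]))
        taken.setdefault(chrom, []).append(padded)
    if len(specs) < count:
        raise RuntimeError(f"could not place {count} non-overlapping SVs")
    return specs


# ---------------------------------------------------------------------------
# fragmentation
# ---------------------------------------------------------------------------

def _cut_positions(length: int, cfg: SimConfig, rng: np.random.Generator,
                   force: Sequence[int] = (), avoid: Sequence[tuple[int, int]] = ()
                   ) -> list[int]:
    """Internal cut points for one chromosome.

    Random cuts follow Normal(frag_mean, frag_sd) truncated at MIN_CONTIG_LEN;
    ``force`` cuts are always kept, ``avoid`` intervals never receive a
    random cut, and random cuts closer than MIN_CONTIG_LEN to a kept cut are
    dropped so every contig stays at least that long.
    """
    cuts: list[int] = []
    pos = 0
    while True:
        step = int(rng.normal(cfg.frag_mean, cfg.frag_sd))
        step = max(step, MIN_CONTIG_LEN)
        pos += step
        if pos >= length:
            break
        cuts.append(pos)
    cuts = [c for c in cuts if not any(s < c < e for s, e in avoid)]
    keep = sorted(set(c for c in force if 0 < c < length))
    for c in cuts:
        if all(abs(c - f) >= MIN_CONTIG_LEN for f in keep):
            keep.append(c)
            keep.sort()
    return keep


def fragment_assembly(genome: Assembly, cfg: SimConfig,
                      rng: np.random.Generator | None = None,
                      force_cuts: dict[str, Sequence[int]] | None = None,
                      avoid_intervals: dict[str, Sequence[tuple[int, int]]] | None = None,
                      truth: SimTruth | None = None,
                      ) -> tuple[Assembly, list[AgpRecord], SimTruth]:
    """Fragment a genome into contigs and gapped scaffolds with known provenance.

    Contigs are consecutive chromosome slices (never flipped); consecutive
    contigs are grouped into scaffolds of ~``contigs_per_scaffold`` members
    joined by ``scaffold_gap_len`` N runs.  With probability ``chimera_rate``
    a scaffold is fused with a scaffold from a different chromosome (or a
    locus > 10x frag_mean away), producing a chimeric join that the anchoring
    stage is expected to detect and undo.  ``force_cuts`` pins cut points
    (e.g. at rearrangement breakpoints); ``avoid_intervals`` keeps random
    cuts out of stated regions (e.g. to make contigs span breakpoints).
    """
    rng = cfg.rng() if rng is None else rng
    truth = truth if truth is not None else SimTruth(seed=cfg.seed)
    force_cuts = force_cuts or {}
    avoid_intervals = avoid_intervals or {}

    contig_info: list[tuple[str, str, int, int]] = []  # id, chrom, start, end
    n_ctg = 0
    for rec in genome.records:
        cuts = _cut_positions(len(rec.seq), cfg, rng,
                              force=force_cuts.get(rec.id, ()),
                              avoid=avoid_intervals.get(rec.id, ()))
        bounds = [0] + cuts + [len(rec.seq)]
        for s, e in zip(bounds, bounds[1:]):
            n_ctg += 1
            cid = f"{genome.name}_ctg{n_ctg:05d}"
            contig_info.append((cid, rec.id, s, e))
            truth.frag_map[cid] = (rec.id, s, e)

    # group consecutive same-chromosome contigs into scaffolds; forced cut
    # points are hard boundaries (a scaffold spanning one would re-join what
    # the cut was meant to keep apart)
    hard = {(chrom, pos) for chrom, positions in force_cuts.items()
            for pos in positions}
    scaffold_groups: list[list[tuple[str, str, int, int]]] = []
    i = 0
    while i < len(contig_info):
        chrom = contig_info[i][1]
        size = max(1, int(rng.poisson(max(cfg.contigs_per_scaffold - 1.0, 0.0))) + 1)
        group = []
        while i < len(contig_info) and len(group) < size and contig_info[i][1] == chrom:
            if group and (chrom, contig_info[i][2]) in hard:
                break
            group.append(contig_info[i])
            i += 1
        scaffold_groups.append(group)

    # chimera construction: fuse a scaffold with one from a distant locus
    chimera_of: dict[int, int] = {}
    if cfg.chimera_rate > 0 and len(scaffold_groups) > 1:
        flags = rng.random(len(scaffold_groups)) < cfg.chimera_rate
        for gi, flagged in enumerate(flags):
            if not flagged or gi in chimera_of or gi in chimera_of.values():
                continue
            partners = [
                gj for gj in range(len(scaffold_groups))
                if gj != gi and gj not in chimera_of and gj not in chimera_of.values()
                and _distant(scaffold_groups[gi], scaffold_groups[gj], cfg)
            ]
            if partners:
                chimera_of[gi] = partners[int(rng.integers(len(partners)))]

    scaffolds = Assembly(name=f"{genome.name}_scaffolds")
    agp: list[AgpRecord] = []
    consumed = set(chimera_of.values())
    n_scf = 0
    for gi, group in enumerate(scaffold_groups):
        if gi in consumed:
            continue
        members = list(group)
        join_records = []
        if gi in chimera_of:
            left_len = sum(e - s for _, _, s, e in members) + cfg.scaffold_gap_len * (len(members) - 1)
            partner = scaffold_groups[chimera_of[gi]]
            join_records.append((left_len + cfg.scaffold_gap_len,
                                 members[-1][0], partner[0][0]))
            members = members + partner
        n_scf += 1
        scf_id = f"{genome.name}_scf{n_scf:05d}"
        seq_parts = []
        pos1 = 1  # AGP object coordinate, 1-based
        part = 0
        for k, (cid, chrom, s, e) in enumerate(members):
            if k > 0:
                part += 1
                agp.append(AgpRecord(scf_id, pos1, pos1 + cfg.scaffold_gap_len - 1, part,
                                     "N", gap_length=cfg.scaffold_gap_len,
                                     gap_type="scaffold", linkage="yes",
                                     linkage_evidence="paired-ends"))
                seq_parts.append("N" * cfg.scaffold_gap_len)
                pos1 += cfg.scaffold_gap_len
            part += 1
            clen = e - s
            agp.append(AgpRecord(scf_id, pos1, pos1 + clen - 1, part, "W",
                                 component_id=cid, component_beg=1,
                                 component_end=clen, orientation="+"))
            seq_parts.append(genome[chrom].seq[s:e])
            pos1 += clen
        scaffolds.add(SequenceRecord(scf_id, "".join(seq_parts)))
        truth.scaffold_members[scf_id] = [m[0] for m in members]
        if join_records:
            truth.chimera_joins[scf_id] = join_records
    return scaffolds, agp, truth


def _distant(group_a, group_b, cfg: SimConfig) -> bool:
    """Eligible chimera partners: distant loci of comparable scale.

    Distant means different chromosomes or more than 10x frag_mean apart on
    the same one.  The pieces must also be within a 3:1 size ratio — a
    junction between a fragment and a vastly larger scaffold leaves the
    minor locus below any relative mapping-significance floor, so such
    joins are not an identifiable detection target.
    """
    len_a = sum(g[3] - g[2] for g in group_a)
    len_b = sum(g[3] - g[2] for g in group_b)
    if max(len_a, len_b) > 3 * min(len_a, len_b):
        return False
    if group_a[0][1] != group_b[0][1]:
        return True
    a_lo, a_hi = min(g[2] for g in group_a), max(g[3] for g in group_a)
    b_lo, b_hi = min(g[2] for g in group_b), max(g[3] for g in group_b)
    gap = max(b_lo - a_hi, a_lo - b_hi)
    return gap > 10 * cfg.frag_mean


def contigs_of(scaffolds_or_genome: Assembly, truth: SimTruth,
               genome: Assembly) -> Assembly:
    """Materialize the contig sequences recorded in the fragmentation map."""
    out = Assembly(name=f"{genome.name}_contigs")
    for cid, (chrom, s, e) in sorted(truth.frag_map.items()):
        out.add(SequenceRecord(cid, genome[chrom].seq[s:e]))
    return out


# ---------------------------------------------------------------------------
# mate pairs
# ---------------------------------------------------------------------------

PAIR_COLUMNS = ["pair_id", "seq1", "pos1", "strand1", "seq2", "pos2", "strand2",
                "unique", "duplicate"]


def simulate_mate_pairs(genome: Assembly, n: int, cfg: SimConfig,
                        rng: np.random.Generator | None = None,
                        nonunique_fraction: float = 0.0,
                        duplicate_fraction: float = 0.0) -> pd.DataFrame:
    """Long-insert mate pairs placed uniformly over the given assembly.

    Inserts are uniform in [insert_min, insert_max] (2–5 kbp by default);
    mate positions are the insert's two ends on the assembly the pairs were
    drawn from.  Stated fractions of pairs are flagged non-unique or
    duplicate so the diagnostic filters have something to reject.  Sequences
    shorter than the maximum insert are skipped with a warning.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rng = cfg.rng() if rng is None else rng
    eligible = [rec for rec in genome.records if len(rec.seq) > cfg.insert_max]
    skipped = [rec.id for rec in genome.records if len(rec.seq) <= cfg.insert_max]
    if skipped:
        logger.warning("skipping %d sequence(s) shorter than insert_max: %s",
                       len(skipped), ", ".join(skipped[:5]))
    if not eligible:
        return pd.DataFrame(columns=PAIR_COLUMNS)
    lengths = np.array([len(rec.seq) for rec in eligible], dtype=float)
    weights = lengths / lengths.sum()
    seq_idx = rng.choice(len(eligible), size=n, p=weights)
    inserts = rng.integers(cfg.insert_min, cfg.insert_max + 1, size=n)
    unique = rng.random(n) >= nonunique_fraction
    duplicate = rng.random(n) < duplicate_fraction
    rows = []
    for i in range(n):
        rec = eligible[int(seq_idx[i])]
        ins = int(inserts[i])
        start = int(rng.integers(0, len(rec.seq) - ins))
        rows.append((f"pair{i:06d}", rec.id, start, "+", rec.id, start + ins, "-",
                     bool(unique[i]), bool(duplicate[i])))
    return pd.DataFrame(rows, columns=PAIR_COLUMNS)
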