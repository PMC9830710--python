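"""Readers, writers and coordinate bookkeeping for external formats.

Every representation the pipeline touches on disk goes through this module:
FASTA assemblies, AGP v2.1 component maps, PAF alignment lines and TSV
reports.  Internal coordinates are 0-based half-open everywhere; AGP is
1-based inclusive and PAF 0-based half-open, and the conversions happen only
here so that no other module ever does off-by-one arithmetic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio.SeqIO.FastaIO import SimpleFastaParser

logger = logging.getLogger(__name__)

ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# sequence containers
# ---------------------------------------------------------------------------

@dataclass
class SequenceRecord:
    """A named nucleotide sequence over {A,C,G,T,N}.

    Lowercase input is folded to uppercase; anything outside the alphabet is
    rejected with the offending position named.
    """

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"invalid sequence id {self.id!r}")
        if not self.seq:
            raise ValueError(f"empty sequence for id {self.id!r}")
        seq = self.seq.upper()
        bad = set(seq) - ALPHABET
        if bad:
            pos = next(i for i, c in enumerate(seq) if c in bad)
            raise ValueError(
                f"illegal character {seq[pos]!r} at position {pos} in sequence {self.id!r}"
            )
        self.seq = seq

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class Assembly:
    """An ordered collection of uniquely named sequences."""

    records: list[SequenceRecord] = field(default_factory=list)
    name: str = "assembly"

    def __post_init__(self) -> None:
        self._index: dict[str, SequenceRecord] = {}
        for rec in self.records:
            if rec.id in self._index:
                raise ValueError(f"duplicate id {rec.id}")
            self._index[rec.id] = rec

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self._index

    def __getitem__(self, seq_id: str) -> SequenceRecord:
        return self._index[seq_id]

    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def lengths(self) -> dict[str, int]:
        return {r.id: len(r.seq) for r in self.records}

    def add(self, rec: SequenceRecord) -> None:
        if rec.id in self._index:
            raise ValueError(f"duplicate id {rec.id}")
        self.records.append(rec)
        self._index[rec.id] = rec

    def total_length(self) -> int:
        return sum(len(r.seq) for r in self.records)


def read_fasta(path: str | Path, name: str | None = None) -> Assembly:
    """Read a FASTA file into an :class:`Assembly`.

    Record ids are the header truncated at the first whitespace; the full
    header is retained as the record description.  Duplicate ids, empty
    sequences and characters outside {A,C,G,T,N} are hard errors.
    """
    path = Path(path)
    records = []
    with open(path) as handle:
        for header, seq in SimpleFastaParser(handle):
            rec_id = header.split()[0] if header.split() else ""
            records.append(SequenceRecord(rec_id, seq, description=header))
    return Assembly(records, name=name or path.stem)


def write_fasta(asm: Assembly, path: str | Path, wrap: int = 60) -> None:
    """Write an assembly as FASTA with lines wrapped at ``wrap`` columns."""
    path = Path(path)
    if not asm.records:
        logger.warning("writing empty FASTA %s", path)
    with open(path, "w") as out:
        for rec in asm.records:
            out.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), wrap):
                out.write(rec.seq[i : i + wrap] + "\n")


# ---------------------------------------------------------------------------
# gap maps
# ---------------------------------------------------------------------------

GapRuns = list[tuple[int, int]]


@dataclass
class GapMap:
    """Per-sequence maximal N-run intervals, 0-based half-open."""

    runs: dict[str, GapRuns] = field(default_factory=dict)

    def __getitem__(self, seq_id: str) -> GapRuns:
        return self.runs.get(seq_id, [])

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self.runs


def sequence_gap_runs(seq: str) -> GapRuns:
    """Maximal runs of N in one sequence, found by scanning with str.find."""
    runs: GapRuns = []
    i = seq.find("N")
    n = len(seq)
    while i != -1:
        j = i
        while j < n and seq[j] == "N":
            j += 1
        runs.append((i, j))
        i = seq.find("N", j)
    return runs


def gap_map(asm: Assembly) -> GapMap:
    """Extract the maximal N-run intervals of every sequence."""
    return GapMap({rec.id: sequence_gap_runs(rec.seq) for rec in asm.records})


# ---------------------------------------------------------------------------
# AGP v2.1
# ---------------------------------------------------------------------------

@dataclass
class AgpRecord:
    """One AGP v2.1 row, stored with the file's own 1-based inclusive coordinates.

    ``component_type`` "W" rows carry a sequence component with orientation,
    "N" rows a gap of known length.  Helper properties expose the 0-based
    half-open object interval used everywhere else in the package.
    """

    object_id: str
    object_beg: int  # 1-based inclusive
    object_end: int  # 1-based inclusive
    part_number: int
    component_type: str  # W or N
    component_id: str | None = None
    component_beg: int | None = None  # 1-based inclusive
    component_end: int | None = None  # 1-based inclusive
    orientation: str | None = None  # + or -
    gap_length: int | None = None
    gap_type: str | None = None
    linkage: str | None = None
    linkage_evidence: str = "na"

    def __post_init__(self) -> None:
        if self.component_type not in ("W", "N"):
            raise ValueError(f"unsupported AGP component type {self.component_type!r}")
        if self.object_beg < 1 or self.object_end < self.object_beg:
            raise ValueError(
                f"bad object interval {self.object_beg}-{self.object_end} in {self.object_id}"
            )
        span = self.object_end - self.object_beg + 1
        if self.component_type == "W":
            if None in (self.component_id, self.component_beg, self.component_end):
                raise ValueError(f"W row of {self.object_id} missing component fields")
            if self.orientation not in ("+", "-"):
                raise ValueError(f"bad orientation {self.orientation!r} in {self.object_id}")
            if self.component_end - self.component_beg + 1 != span:
                raise ValueError(
                    f"object span {span} != component span for {self.object_id} part {self.part_number}"
                )
        else:
            if self.gap_length is None or self.gap_length < 1:
                raise ValueError(f"N row of {self.object_id} missing gap_length")
            if self.gap_length != span:
                raise ValueError(
                    f"object span {span} != gap_length {self.gap_length} for {self.object_id}"
                )
            self.gap_type = self.gap_type or "scaffold"
            self.linkage = self.linkage or "no"

    @property
    def object_interval(self) -> tuple[int, int]:
        """0-based half-open interval on the object."""
        return self.object_beg - 1, self.object_end

    @property
    def component_interval(self) -> tuple[int, int]:
        """0-based half-open interval on the component (W rows only)."""
        assert self.component_beg is not None and self.component_end is not None
        return self.component_beg - 1, self.component_end


def validate_agp(records: Sequence[AgpRecord]) -> None:
    """Check that the parts of every object tile it contiguously."""
    by_object: dict[str, list[AgpRecord]] = {}
    for rec in records:
        by_object.setdefault(rec.object_id, []).append(rec)
    for object_id, rows in by_object.items():
        rows = sorted(rows, key=lambda r: r.part_number)
        expect_beg = 1
        for k, row in enumerate(rows, start=1):
            if row.part_number != k:
                raise ValueError(
                    f"part_number gap in object {object_id}: expected {k}, got {row.part_number}"
                )
            if row.object_beg != expect_beg:
                if row.object_beg > expect_beg:
                    raise ValueError(
                        f"gap at object coordinates {expect_beg}–{row.object_beg - 1} "
                        f"in {object_id} (part {row.part_number})"
                    )
                raise ValueError(
                    f"overlapping parts at object coordinate {row.object_beg} "
                    f"in {object_id} (part {row.part_number})"
                )
            expect_beg = row.object_end + 1


def read_agp(path: str | Path) -> list[AgpRecord]:
    """Read an AGP v2.1 file; the tiling invariant is validated on read."""
    records: list[AgpRecord] = []
    with open(path) as handle:
        for line_no, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 8:
                raise ValueError(f"AGP line {line_no}: expected >=8 columns, got {len(f)}")
            if f[4] == "W":
                records.append(
                    AgpRecord(
                        object_id=f[0], object_beg=int(f[1]), object_end=int(f[2]),
                        part_number=int(f[3]), component_type="W",
                        component_id=f[5], component_beg=int(f[6]),
                        component_end=int(f[7]),
                        orientation=f[8] if len(f) > 8 else "+",
                    )
                )
            elif f[4] in ("N", "U"):
                records.append(
                    AgpRecord(
                        object_id=f[0], object_beg=int(f[1]), object_end=int(f[2]),
                        part_number=int(f[3]), component_type="N",
                        gap_length=int(f[5]), gap_type=f[6], linkage=f[7],
                        linkage_evidence=f[8] if len(f) > 8 else "na",
                    )
                )
            else:
                raise ValueError(f"AGP line {line_no}: unsupported component type {f[4]!r}")
    validate_agp(records)
    return records


def write_agp(records: Sequence[AgpRecord], path: str | Path,
              header_comments: Iterable[str] = ()) -> None:
    """Write AGP v2.1; rows are validated before writing."""
    validate_agp(records)
    with open(path, "w") as out:
        out.write("##agp-version\t2.1\n")
        for comment in header_comments:
            out.write(f"# {comment}\n")
        for r in records:
            if r.component_type == "W":
                fields = [r.object_id, r.object_beg, r.object_end, r.part_number,
                          "W", r.component_id, r.component_beg, r.component_end,
                          r.orientation]
            else:
                fields = [r.object_id, r.object_beg, r.object_end, r.part_number,
                          "N", r.gap_length, r.gap_type, r.linkage,
                          r.linkage_evidence]
            out.write("\t".join(str(x) for x in fields) + "\n")


def assemble_from_agp(records: Sequence[AgpRecord], components: Assembly,
                      name: str = "agp_objects") -> Assembly:
    """Rebuild object sequences from AGP rows plus their component sequences.

    Used both to emit pseudo-chromosomes and as the independent check that an
    emitted FASTA/AGP pair is coherent byte-for-byte.
    """
    validate_agp(records)
    by_object: dict[str, list[AgpRecord]] = {}
    for rec in records:
        by_object.setdefault(rec.object_id, []).append(rec)
    out = Assembly(name=name)
    for object_id, rows in by_object.items():
        parts = []
        for row in sorted(rows, key=lambda r: r.part_number):
            if row.component_type == "N":
                parts.append("N" * row.gap_length)
            else:
                if row.component_id not in components:
                    raise ValueError(f"unknown component {row.component_id} in {object_id}")
                beg, end = row.component_interval
                seg = components[row.component_id].seq[beg:end]
                if end > len(components[row.component_id].seq):
                    raise ValueError(
                        f"component interval out of bounds for {row.component_id}"
                    )
                parts.append(seg if row.orientation == "+" else reverse_complement(seg))
        out.add(SequenceRecord(object_id, "".join(parts)))
    return out


# ---------------------------------------------------------------------------
# PAF
# ---------------------------------------------------------------------------

def write_paf(chains, path: str | Path,
              query_lengths: Mapping[str, int] | Assembly,
              target_lengths: Mapping[str, int] | Assembly) -> None:
    """Write chains as 12-column PAF for dot-plot viewers.

    Column 10 is the summed matched seed length of the chain, column 11 the
    chain span on the query, column 12 a constant mapping quality of 255.
    A chain naming a sequence absent from either assembly is a hard error.
    """
    if isinstance(query_lengths, Assembly):
        query_lengths = query_lengths.lengths()
    if isinstance(target_lengths, Assembly):
        target_lengths = target_lengths.lengths()
    with open(path, "w") as out:
        for ch in chains:
            if ch.q_id not in query_lengths:
                raise ValueError(f"chain references unknown query sequence {ch.q_id}")
            if ch.r_id not in target_lengths:
                raise ValueError(f"chain references unknown target sequence {ch.r_id}")
            fields = [
                ch.q_id, query_lengths[ch.q_id], ch.q_start, ch.q_end, ch.strand,
                ch.r_id, target_lengths[ch.r_id], ch.r_start, ch.r_end,
                ch.score, ch.q_end - ch.q_start, 255,
            ]
            out.write("\t".join(str(x) for x in fields) + "\n")


# ---------------------------------------------------------------------------
# TSV reports
# ---------------------------------------------------------------------------

def write_tsv(frame, path: str | Path, header_comments: Iterable[str] = ()) -> None:
    """Write a DataFrame as TSV with '#'-prefixed provenance comments on top."""
    with open(path, "w") as out:
        for comment in header_comments:
            out.write(f"# {comment}\n")
        frame.to_csv(out, sep="\t", index=False)


def read_tsv(path: str | Path):
    import pandas as pd

    return pd.read_csv(path, sep="\t", comment="#")
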