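"""Breakpoint-provenance diagnosis and the reference-bias experiment.

The validation logic for calling an apparent rearrangement real versus a
placement artifact: a structural-variant endpoint that falls inside an
unambiguously assembled region supports a real event, while an endpoint at
an assembly gap (N-run) or at the end of a placed component is exactly
where a reference-guided reconstruction would have created the event out of
thin air.  Gap-adjacent endpoints can be rescued by long-insert mate pairs
whose two mates bracket the gap — uniquely aligned, non-duplicate pairs
only, mirroring the usual secondary-alignment-null and deduplication
filters.

The reference-bias experiment anchors one contig set onto two different
references and compares the resulting major-SV sets against a common
comparison genome; the recapitulation fraction measures how much of each
reference's own structure the anchoring imported into the contigs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import pandas as pd

from .anchor import AnchorConfig, PseudoChromosomeSet, anchor_pipeline
from .formats import AgpRecord, Assembly, GapMap, gap_map
from .svscan import SvCall, SvScanConfig, call_svs, filter_major, genome_chains

logger = logging.getLogger(__name__)

DEFAULT_PROXIMITY = 1000  # bp window for "at a gap / component end"
DEFAULT_MIN_PAIRS = 3
RECIPROCAL_OVERLAP = 0.5

PAIR_COLUMNS = ["pair_id", "seq1", "pos1", "strand1", "seq2", "pos2", "strand2",
                "unique", "duplicate"]


@dataclass
class BreakpointVerdict:
    """Provenance of one SV endpoint on the assembly under scrutiny."""

    seq_id: str
    position: int
    dist_to_gap: float  # inf when the sequence has no N-runs
    dist_to_component_end: float  # inf when no AGP is available
    klass: str  # internal | gap_adjacent | component_end


@dataclass
class SvVerdict:
    """Endpoint classification plus mate-pair rescue for one SV call."""

    sv: SvCall
    start_verdict: BreakpointVerdict
    end_verdict: BreakpointVerdict
    pair_support: dict[str, int] = field(default_factory=dict)  # per endpoint label
    verdict: str = "ambiguous"  # supported | suspect_artifact | ambiguous


@dataclass
class BiasReport:
    """Outcome of anchoring one contig set on two references."""

    svs_anchored_a: list[SvCall]
    svs_anchored_b: list[SvCall]
    svs_direct_a: list[SvCall]  # ref_a vs compare_to
    svs_direct_b: list[SvCall]
    recapitulation_a: float  # share of direct-A major SVs present after anchoring on A
    recapitulation_b: float
    matches_a: list[tuple[SvCall, SvCall]] = field(default_factory=list)
    matches_b: list[tuple[SvCall, SvCall]] = field(default_factory=list)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [("A", len(self.svs_direct_a), len(self.svs_anchored_a),
              len(self.matches_a), self.recapitulation_a),
             ("B", len(self.svs_direct_b), len(self.svs_anchored_b),
              len(self.matches_b), self.recapitulation_b)],
            columns=["reference", "direct_major_svs", "anchored_major_svs",
                     "recapitulated", "recapitulation_fraction"],
        )


# ---------------------------------------------------------------------------
# endpoint classification
# ---------------------------------------------------------------------------

def classify_breakpoint(seq_id: str, pos: int, gapmap: GapMap,
                        agp: list[AgpRecord] | None = None,
                        d: int = DEFAULT_PROXIMITY,
                        seq_len: int | None = None) -> BreakpointVerdict:
    """Distance of a position to the nearest N-run edge and component boundary.

    Class is ``internal`` when both distances exceed ``d``; within ``d`` of
    a component boundary the endpoint is ``component_end`` (which wins over
    ``gap_adjacent`` when both apply, since a component end is the stronger
    placement-artifact signal).
    """
    if seq_len is not None and not 0 <= pos <= seq_len:
        raise ValueError(f"position {pos} outside sequence {seq_id}")
    dist_gap = math.inf
    for s, e in gapmap[seq_id]:
        if s <= pos < e:
            dist_gap = 0
            break
        dist_gap = min(dist_gap, abs(pos - s), abs(pos - e))
    dist_comp = math.inf
    if agp:
        for row in agp:
            if row.object_id != seq_id or row.component_type != "W":
                continue
            ob, oe = row.object_interval
            dist_comp = min(dist_comp, abs(pos - ob), abs(pos - oe))
    if dist_comp <= d:
        klass = "component_end"
    elif dist_gap <= d:
        klass = "gap_adjacent"
    else:
        klass = "internal"
    return BreakpointVerdict(seq_id, pos, dist_gap, dist_comp, klass)


def naive_gap_distance(seq: str, pos: int) -> float:
    """Linear-scan oracle for the distance to the nearest N-run edge."""
    if "N" not in seq:
        return math.inf
    best = math.inf
    in_run = False
    for i, c in enumerate(seq):
        if c == "N":
            if not in_run:
                in_run = True
                best = min(best, abs(pos - i))
            if i == pos:
                return 0.0
        else:
            if in_run:
                best = min(best, abs(pos - i))
            in_run = False
    if in_run:
        best = min(best, abs(pos - len(seq)))
    return best


# ---------------------------------------------------------------------------
# mate-pair support
# ---------------------------------------------------------------------------

def spanning_pair_support(pairs: pd.DataFrame, seq_id: str,
                          interval: tuple[int, int], min_offset: int = 1000,
                          window: int | None = None) -> int:
    """Unique, non-duplicate pairs bracketing an interval on one sequence.

    A pair counts when both mates lie on ``seq_id``, one mate at least
    ``min_offset`` left of the interval start and the other at least
    ``min_offset`` right of the interval end; each pair id counts once.
    ``window`` optionally restricts both mates to within that many bases of
    the interval.
    """
    if pairs is None or pairs.empty:
        return 0
    start, end = interval
    df = pairs[(pairs["unique"]) & (~pairs["duplicate"])
               & (pairs["seq1"] == seq_id) & (pairs["seq2"] == seq_id)]
    if df.empty:
        return 0
    left = df[["pos1", "pos2"]].min(axis=1)
    right = df[["pos1", "pos2"]].max(axis=1)
    ok = (left <= start - min_offset) & (right >= end + min_offset)
    if window is not None:
        ok &= (left >= start - window) & (right <= end + window)
    return int(df.loc[ok, "pair_id"].nunique())


# ---------------------------------------------------------------------------
# verdicts
# ---------------------------------------------------------------------------

def sv_verdicts(svs: list[SvCall], assembly: Assembly,
                agp: list[AgpRecord] | None = None,
                pairs: pd.DataFrame | None = None,
                d: int = DEFAULT_PROXIMITY,
                min_pairs: int = DEFAULT_MIN_PAIRS,
                insert_max: int = 5000) -> list[SvVerdict]:
    """Classify both endpoints of every SV and render a verdict.

    Endpoints are taken on whichever side of the call lives in ``assembly``
    (query side preferred).  Both endpoints internal means supported.  A
    non-internal endpoint demotes the call to suspected placement artifact
    unless mate pairs spanning the nearby gap/boundary — both mates within
    ``insert_max`` of the endpoint — reach ``min_pairs``; when some
    non-internal endpoints are rescued and others are not, the call is
    ambiguous.
    """
    gm = gap_map(assembly)
    out: list[SvVerdict] = []
    for sv in svs:
        if sv.q_id in assembly:
            seq_id, lo, hi = sv.q_id, sv.q_start, sv.q_end
        elif sv.r_id in assembly:
            seq_id, lo, hi = sv.r_id, sv.r_start, sv.r_end
        else:
            raise ValueError(
                f"SV coordinates ({sv.q_id}/{sv.r_id}) match no sequence in "
                f"assembly {assembly.name}: coordinate mismatch"
            )
        seq_len = len(assembly[seq_id].seq)
        verdicts = {
            "start": classify_breakpoint(seq_id, lo, gm, agp, d, seq_len),
            "end": classify_breakpoint(seq_id, min(hi, seq_len), gm, agp, d, seq_len),
        }
        support: dict[str, int] = {}
        rescued, failed = 0, 0
        for label, v in verdicts.items():
            if v.klass == "internal":
                continue
            if pairs is None:
                failed += 1
                continue
            interval = _nearby_feature(v, gm, agp, d)
            n = spanning_pair_support(pairs, seq_id, interval,
                                      min_offset=d, window=insert_max)
            support[label] = n
            if n >= min_pairs:
                rescued += 1
            else:
                failed += 1
        if failed == 0:
            verdict = "supported"
        elif rescued == 0:
            verdict = "suspect_artifact"
        else:
            verdict = "ambiguous"
        out.append(SvVerdict(sv, verdicts["start"], verdicts["end"], support, verdict))
    return out


def _nearby_feature(v: BreakpointVerdict, gm: GapMap,
                    agp: list[AgpRecord] | None, d: int) -> tuple[int, int]:
    """The interval the mate pairs must bracket: the nearest N-run for a
    gap-adjacent endpoint, else the nearest component boundary point."""
    if v.klass == "gap_adjacent" or (v.klass == "component_end"
                                     and v.dist_to_gap <= v.dist_to_component_end):
        runs = gm[v.seq_id]
        best = min(runs, key=lambda r: 0 if r[0] <= v.position < r[1]
                   else min(abs(v.position - r[0]), abs(v.position - r[1])))
        return best
    best_pos = v.position
    best_dist = math.inf
    for row in agp or []:
        if row.object_id != v.seq_id or row.component_type != "W":
            continue
        for edge in row.object_interval:
            if abs(v.position - edge) < best_dist:
                best_dist = abs(v.position - edge)
                best_pos = edge
    return best_pos, best_pos


def verdicts_to_frame(verdicts: list[SvVerdict]) -> pd.DataFrame:
    rows = []
    for v in verdicts:
        rows.append((v.sv.type, v.start_verdict.seq_id, v.sv.q_start, v.sv.q_end,
                     v.sv.length, v.start_verdict.klass, v.end_verdict.klass,
                     v.pair_support.get("start", -1), v.pair_support.get("end", -1),
                     v.verdict))
    return pd.DataFrame(rows, columns=["type", "seq", "start", "end", "length",
                                       "start_class", "end_class",
                                       "start_pairs", "end_pairs", "verdict"])


# ---------------------------------------------------------------------------
# reference-bias experiment
# ---------------------------------------------------------------------------

def match_sv_sets(set_a: list[SvCall], set_b: list[SvCall],
                  reciprocal: float = RECIPROCAL_OVERLAP) -> list[tuple[SvCall, SvCall]]:
    """Same-type calls with >= reciprocal overlap on the reference, greedily paired."""
    matches = []
    used: set[int] = set()
    for sa in set_a:
        for j, sb in enumerate(set_b):
            if j in used or sa.type != sb.type or sa.r_id != sb.r_id:
                continue
            ov = min(sa.r_end, sb.r_end) - max(sa.r_start, sb.r_start)
            if ov > 0 and ov >= reciprocal * sa.length and ov >= reciprocal * sb.length:
                matches.append((sa, sb))
                used.add(j)
                break
    return matches


def reference_bias_report(contigs: Assembly, ref_a: Assembly, ref_b: Assembly,
                          compare_to: Assembly,
                          anchor_cfg: AnchorConfig | None = None,
                          scan_cfg: SvScanConfig | None = None,
                          min_len: int | None = None,
                          ) -> tuple[BiasReport, PseudoChromosomeSet, PseudoChromosomeSet]:
    """Anchor one contig set independently on two references and compare.

    Both anchorings are scanned for major SVs against ``compare_to``, as are
    the two references themselves; the recapitulation fraction of reference
    X is the share of the (X vs compare_to) major SVs that the
    anchored-on-X assembly reproduces (same type, >= 50% reciprocal
    overlap).  A fraction of 1.0 says the anchoring imported the
    reference's structure wholesale; NaN is reported when a reference has
    no major SVs against the comparison genome.
    """
    anchor_cfg = anchor_cfg or AnchorConfig()
    scan_cfg = scan_cfg or SvScanConfig(min_seed_len=anchor_cfg.min_seed_len,
                                        stride=anchor_cfg.stride)
    min_len = min_len if min_len is not None else 10 * scan_cfg.min_block
    anchored_a = anchor_pipeline(contigs, ref_a, anchor_cfg, name="anchored_a")
    anchored_b = anchor_pipeline(contigs, ref_b, anchor_cfg, name="anchored_b")

    from .seedchain import SeedIndex

    index_cmp = SeedIndex(compare_to, scan_cfg.min_seed_len)

    def major(query: Assembly) -> list[SvCall]:
        chains = genome_chains(compare_to, query, scan_cfg, index=index_cmp)
        return filter_major(call_svs(chains, scan_cfg), min_len=min_len)

    svs_anchored_a = major(anchored_a.assembly)
    svs_anchored_b = major(anchored_b.assembly)
    svs_direct_a = major(ref_a)
    svs_direct_b = major(ref_b)
    matches_a = match_sv_sets(svs_direct_a, svs_anchored_a)
    matches_b = match_sv_sets(svs_direct_b, svs_anchored_b)
    recap_a = len(matches_a) / len(svs_direct_a) if svs_direct_a else math.nan
    recap_b = len(matches_b) / len(svs_direct_b) if svs_direct_b else math.nan
    report = BiasReport(svs_anchored_a, svs_anchored_b, svs_direct_a, svs_direct_b,
                        recap_a, recap_b, matches_a, matches_b)
    return report, anchored_a, anchored_b


# ---------------------------------------------------------------------------
# pairs TSV
# ---------------------------------------------------------------------------

def read_pairs(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(PAIR_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"pair table missing columns: {sorted(missing)}")
    df["unique"] = df["unique"].astype(bool)
    df["duplicate"] = df["duplicate"].astype(bool)
    return df


def write_pairs(pairs: pd.DataFrame, path, header_comments=()) -> None:
    from .formats import write_tsv

    write_tsv(pairs[PAIR_COLUMNS], path, header_comments)
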