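"""Orchestration: configuration, provenance, replicate experiments, replay.

The replicate helpers in this module are the package's experiments-in-a-box:
each one simulates a truth-tracked dataset, runs the relevant stages and
returns the measurements, so the test suite, the acceptance script and the
``replay`` CLI subcommand all execute exactly the same code paths.

``replay_synthetic`` strings the whole story together on one synthetic
dataset: a reference genome A, a derived genome B with planted inversions,
two fragmentations of B (breakpoint-avoiding and breakpoint-spanning),
anchoring of both onto A, SV scans of the results, endpoint-provenance
classification, and the reference-bias experiment against a third genome C
that is A plus one extra inversion.  Every emitted file carries a
provenance header and is checksummed (comment lines excluded) into a
manifest, so a fixed seed reproduces the manifest bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import shutil
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .anchor import AnchorConfig, PseudoChromosomeSet, anchor_pipeline
from .diagnose import (classify_breakpoint, reference_bias_report, sv_verdicts,
                       verdicts_to_frame, write_pairs)
from .formats import (AgpRecord, gap_map, write_agp, write_fasta, write_paf,
                      write_tsv)
from .seedchain import SeedIndex
from .simgenome import (SimConfig, SimTruth, apply_svs, fragment_assembly,
                        random_sv_specs, simulate_mate_pairs, simulate_reference)
from .svscan import SvScanConfig, call_svs, filter_major, genome_chains, svs_to_frame

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# configuration and provenance
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Full configuration of a replay run; all defaults are materialized and
    echoed to disk before any computation."""

    outdir: str = "replay_out"
    seed: int = 0
    log_level: str = "INFO"
    n_inversions: int = 2
    inv_length_range: tuple[int, int] = (40_000, 100_000)
    breakpoint_margin: int = 8000
    pair_density: float = 0.01  # mate pairs per base of the anchored assembly
    d: int = 1000
    min_pairs: int = 3
    sim: SimConfig = field(default_factory=lambda: SimConfig(chrom_len=500_000))
    anchor: AnchorConfig = field(default_factory=lambda: AnchorConfig(
        stride=4, dist_base=200_000))
    svscan: SvScanConfig = field(default_factory=lambda: SvScanConfig(stride=4))
    major_min_len: int = 10_000  # toy-scale "major SV" threshold

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        for key, sub in (("sim", SimConfig), ("anchor", AnchorConfig),
                         ("svscan", SvScanConfig)):
            if key in data and isinstance(data[key], dict):
                data[key] = _build(sub, data[key])
        return _build(cls, data)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _build(cls, data: dict):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = dict(data)
    if "inv_length_range" in kwargs and isinstance(kwargs["inv_length_range"], list):
        kwargs["inv_length_range"] = tuple(kwargs["inv_length_range"])
    return cls(**kwargs)


def config_hash(cfg: RunConfig) -> str:
    """Hash of the scientific configuration; where outputs go and how loudly
    the run logs are not part of the experiment's identity."""
    payload = {k: v for k, v in cfg.to_dict().items()
               if k not in ("outdir", "log_level")}
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def version_and_provenance(cfg: RunConfig) -> dict:
    """Metadata block embedded in every report header."""
    return {
        "tool": f"refanchor {__version__}",
        "config_hash": config_hash(cfg),
        "seed": cfg.seed,
        "timestamp": datetime.now(timezone.utc).isoformat(timespec="seconds"),
    }


def provenance_comments(meta: dict) -> list[str]:
    return [f"{k}: {v}" for k, v in meta.items()]


# ---------------------------------------------------------------------------
# coordinate mapping: derived genome -> anchored pseudo-chromosomes
# ---------------------------------------------------------------------------

def derived_to_object(chrom: str, pos: int, truth: SimTruth,
                      scaffold_agp: list[AgpRecord],
                      pseudo: PseudoChromosomeSet) -> tuple[str, int] | None:
    """Map a derived-genome coordinate through fragmentation, scaffolding and
    placement into anchored-object coordinates; None when the position lands
    in an unplaced scaffold."""
    contig = None
    for cid, (c_chrom, s, e) in truth.frag_map.items():
        if c_chrom == chrom and s <= pos <= e:
            contig = (cid, s, e)
            if pos < e:
                break
    if contig is None:
        raise ValueError(f"position {chrom}:{pos} not covered by the fragmentation map")
    cid, c_start, _ = contig
    scf_pos = None
    scf_id = None
    for row in scaffold_agp:
        if row.component_type == "W" and row.component_id == cid:
            ob, _ = row.object_interval
            scf_id = row.object_id
            scf_pos = ob + (pos - c_start)
            break
    if scf_id is None:
        raise ValueError(f"contig {cid} not present in the scaffold AGP")
    # split parts: "<scf>-<k>" tile the scaffold in order
    placed_rows = [r for r in pseudo.agp if r.component_type == "W"]
    part_ids = sorted(
        (r.component_id for r in placed_rows
         if r.component_id == scf_id or r.component_id.startswith(scf_id + "-")),
        key=lambda p: (len(p), p),
    )
    part_lengths = {}
    for r in placed_rows:
        if r.component_id in part_ids:
            part_lengths[r.component_id] = r.component_interval[1]
    for rec in pseudo.unplaced.records:
        if rec.id == scf_id or rec.id.startswith(scf_id + "-"):
            part_ids.append(rec.id)
            part_lengths[rec.id] = len(rec.seq)
    part_ids = sorted(set(part_ids), key=_part_sort_key)
    offset = 0
    target_part, part_pos = None, None
    for pid in part_ids:
        plen = part_lengths[pid]
        if offset <= scf_pos <= offset + plen:
            target_part, part_pos = pid, scf_pos - offset
            if scf_pos < offset + plen:
                break
        offset += plen
    if target_part is None:
        raise ValueError(f"scaffold position {scf_id}:{scf_pos} beyond its parts")
    for row in placed_rows:
        if row.component_id == target_part:
            ob, oe = row.object_interval
            if row.orientation == "+":
                return row.object_id, ob + part_pos
            return row.object_id, oe - part_pos
    return None  # unplaced


def _part_sort_key(pid: str):
    if "-" in pid and pid.rsplit("-", 1)[1].isdigit():
        return (0, int(pid.rsplit("-", 1)[1]))
    return (0, 0)


# ---------------------------------------------------------------------------
# replicate experiments
# ---------------------------------------------------------------------------

def inversion_recovery_replicate(seed: int, n_inversions: int,
                                 chrom_len: int = 1_000_000, n_chrom: int = 2,
                                 inv_length_range: tuple[int, int] = (50_000, 200_000),
                                 scan_cfg: SvScanConfig | None = None) -> dict:
    """Plant inversions, scan derived vs reference, compare calls to truth.

    Returns planted/called interval lists, per-boundary errors for matched
    inversions, and the number of spurious INV calls.
    """
    scan_cfg = scan_cfg or SvScanConfig(stride=4)
    sim = SimConfig(n_chrom=n_chrom, chrom_len=chrom_len, seed=seed)
    rng = sim.rng()
    ref = simulate_reference(sim, rng, name=f"refA_s{seed}")
    specs = random_sv_specs(ref, rng, n_inversions, "INV", inv_length_range,
                            margin=4 * scan_cfg.min_block) if n_inversions else []
    derived, truth = apply_svs(ref, specs, seed=seed, name=f"derB_s{seed}")
    chains = genome_chains(ref, derived, scan_cfg)
    calls = call_svs(chains, scan_cfg)
    inv_calls = [c for c in calls if c.type == "INV"]
    matched, errors = 0, []
    for planted in truth.inversions():
        hits = [c for c in inv_calls if c.r_id == planted.ref_chrom
                and min(c.r_end, planted.ref_end) - max(c.r_start, planted.ref_start)
                > 0.5 * (planted.ref_end - planted.ref_start)]
        if hits:
            matched += 1
            best = hits[0]
            errors.append(abs(best.r_start - planted.ref_start))
            errors.append(abs(best.r_end - planted.ref_end))
    return {
        "n_planted": len(truth.inversions()),
        "n_inv_calls": len(inv_calls),
        "n_matched": matched,
        "boundary_errors": errors,
        "false_inv": len(inv_calls) - matched,
    }


def self_anchor_replicate(seed: int, chrom_len: int = 1_000_000, n_chrom: int = 2,
                          frag_mean: int = 40_000,
                          anchor_cfg: AnchorConfig | None = None) -> dict:
    """Fragment a reference cleanly and anchor it back onto itself.

    The fixpoint check: every contig placed, all on '+', and each
    pseudo-chromosome byte-identical to its reference chromosome once the
    inserted reconstruction gaps are removed.
    """
    anchor_cfg = anchor_cfg or AnchorConfig(stride=4, dist_base=200_000)
    sim = SimConfig(n_chrom=n_chrom, chrom_len=chrom_len, frag_mean=frag_mean,
                    frag_sd=frag_mean // 4, contigs_per_scaffold=1.0, seed=seed)
    rng = sim.rng()
    ref = simulate_reference(sim, rng, name=f"ref_s{seed}")
    scaffolds, _, truth = fragment_assembly(ref, sim, rng)
    pseudo = anchor_pipeline(scaffolds, ref, anchor_cfg, name="self")
    placed = [p for p in pseudo.placements if p.status == "placed"]
    n_total = len(scaffolds.records)
    identical = all(
        chrom in pseudo.assembly
        and _strip_reconstruction_gaps(pseudo, chrom) == ref[chrom].seq
        for chrom in ref.ids()
    )
    return {
        "n_scaffolds": n_total,
        "placed_fraction": len(placed) / n_total if n_total else 0.0,
        "forward_fraction": (sum(p.orientation == "+" for p in placed) / len(placed)
                             if placed else 0.0),
        "sequences_identical": identical,
        "pseudo": pseudo,
        "reference": ref,
        "truth": truth,
    }


def _strip_reconstruction_gaps(pseudo: PseudoChromosomeSet, chrom: str) -> str:
    seq = pseudo.assembly[chrom].seq
    parts = []
    for row in sorted((r for r in pseudo.agp if r.object_id == chrom),
                      key=lambda r: r.part_number):
        if row.component_type == "W":
            ob, oe = row.object_interval
            parts.append(seq[ob:oe])
    return "".join(parts)


def inheritance_replicate(seed: int, chrom_len: int = 500_000, n_chrom: int = 2,
                          n_inversions: int = 2,
                          inv_length_range: tuple[int, int] = (40_000, 80_000),
                          breakpoint_margin: int = 8000,
                          anchor_cfg: AnchorConfig | None = None,
                          scan_cfg: SvScanConfig | None = None,
                          major_min_len: int = 10_000,
                          d: int = 1000,
                          pair_density: float = 0.01,
                          min_pairs: int = 3) -> dict:
    """One replicate of the reference-structure-inheritance experiment.

    A derived genome with planted inversions is fragmented two ways —
    breakpoint-avoiding (cut exactly at every inversion boundary) and
    breakpoint-spanning (no cut within ``breakpoint_margin`` of a boundary)
    — and both fragmentations are anchored onto the original reference.

    Measured outcomes: the breakpoint-avoiding anchoring should carry zero
    major SVs against the reference (inversions erased by placement) with
    every erased boundary mapping to a non-internal endpoint; the
    breakpoint-spanning anchoring should retain every inversion as an INV
    call whose endpoints are internal, yielding a supported verdict.
    """
    anchor_cfg = anchor_cfg or AnchorConfig(stride=4, dist_base=200_000)
    scan_cfg = scan_cfg or SvScanConfig(stride=4)
    sim = SimConfig(n_chrom=n_chrom, chrom_len=chrom_len, seed=seed)
    rng = sim.rng()
    ref = simulate_reference(sim, rng, name=f"refA_s{seed}")
    # chromosome-end margin must leave room for the spanning flanks below
    margin = int(0.75 * inv_length_range[1]) + breakpoint_margin + 2000
    specs = random_sv_specs(ref, rng, n_inversions, "INV", inv_length_range,
                            margin=margin)
    derived, truth = apply_svs(ref, specs, seed=seed, name=f"derB_s{seed}")

    # breakpoint-avoiding: cut exactly at every inversion boundary.
    # breakpoint-spanning: each inversion sits inside one contig with flanks
    # of 0.75x its own length on both sides, so the contig's dominant
    # orientation is set by the flanks, not by the inverted interior.
    force_avoid: dict[str, list[int]] = {}
    force_span: dict[str, list[int]] = {}
    protect_span: dict[str, list[tuple[int, int]]] = {}
    for sv in truth.planted_svs:
        force_avoid.setdefault(sv.derived_chrom, []).extend(
            [sv.derived_start, sv.derived_end])
        flank = int(0.75 * (sv.derived_end - sv.derived_start))
        lo = sv.derived_start - flank
        hi = sv.derived_end + flank
        force_span.setdefault(sv.derived_chrom, []).extend([lo, hi])
        protect_span.setdefault(sv.derived_chrom, []).append((lo, hi))
    scf_avoid, agp_avoid, truth_avoid = fragment_assembly(
        derived, sim, np.random.default_rng(seed + 1_000_003),
        force_cuts=force_avoid,
        truth=SimTruth(planted_svs=list(truth.planted_svs), seed=seed))
    scf_span, agp_span, truth_span = fragment_assembly(
        derived, sim, np.random.default_rng(seed + 2_000_003),
        force_cuts=force_span, avoid_intervals=protect_span,
        truth=SimTruth(planted_svs=list(truth.planted_svs), seed=seed))

    index = SeedIndex(ref, anchor_cfg.min_seed_len)
    pseudo_avoid = anchor_pipeline(scf_avoid, ref, anchor_cfg, index=index,
                                   name="anchored_avoid")
    pseudo_span = anchor_pipeline(scf_span, ref, anchor_cfg, index=index,
                                  name="anchored_span")

    major_avoid = filter_major(
        call_svs(genome_chains(ref, pseudo_avoid.assembly, scan_cfg, index=index),
                 scan_cfg), min_len=major_min_len)
    calls_span = call_svs(
        genome_chains(ref, pseudo_span.assembly, scan_cfg, index=index), scan_cfg)
    inv_span = [c for c in calls_span if c.type == "INV"]
    major_span = filter_major(calls_span, min_len=major_min_len)

    # erased inversions: classify the mapped breakpoints on the avoid anchoring
    gm_avoid = gap_map(pseudo_avoid.assembly)
    erased_classes = []
    for sv in truth.planted_svs:
        for bp in (sv.derived_start, sv.derived_end):
            mapped = derived_to_object(sv.derived_chrom, bp, truth_avoid,
                                       agp_avoid, pseudo_avoid)
            if mapped is None:
                erased_classes.append("unplaced")
                continue
            obj, opos = mapped
            v = classify_breakpoint(obj, opos, gm_avoid, pseudo_avoid.agp, d=d,
                                    seq_len=len(pseudo_avoid.assembly[obj].seq))
            erased_classes.append(v.klass)

    # surviving inversions: verdicts with mate-pair evidence on the span anchoring
    n_pairs = max(1000, int(pair_density * pseudo_span.assembly.total_length()))
    pairs = simulate_mate_pairs(pseudo_span.assembly, n_pairs, sim,
                                np.random.default_rng(seed + 3_000_003))
    verdicts = sv_verdicts(inv_span, pseudo_span.assembly, pseudo_span.agp,
                           pairs=pairs, d=d, min_pairs=min_pairs,
                           insert_max=sim.insert_max)

    matched_span = 0
    for planted in truth.inversions():
        if any(c.r_id == planted.ref_chrom
               and min(c.r_end, planted.ref_end) - max(c.r_start, planted.ref_start)
               > 0.5 * (planted.ref_end - planted.ref_start) for c in inv_span):
            matched_span += 1
    return {
        "truth": truth,
        "reference": ref,
        "n_planted": len(truth.planted_svs),
        "major_avoid": major_avoid,
        "n_major_avoid": len(major_avoid),
        "erased_endpoint_classes": erased_classes,
        "erased_noninternal_fraction": (
            sum(k != "internal" for k in erased_classes) / len(erased_classes)
            if erased_classes else 1.0),
        "inv_span": inv_span,
        "n_inv_span_matched": matched_span,
        "major_span": major_span,
        "span_verdicts": verdicts,
        "span_supported_fraction": (
            sum(v.verdict == "supported" for v in verdicts) / len(verdicts)
            if verdicts else 0.0),
        "span_internal_fraction": (
            sum(v.start_verdict.klass == "internal"
                and v.end_verdict.klass == "internal" for v in verdicts) / len(verdicts)
            if verdicts else 0.0),
        "pseudo_avoid": pseudo_avoid,
        "pseudo_span": pseudo_span,
        "pairs": pairs,
        "scaffold_agp": {"avoid": agp_avoid, "span": agp_span},
    }


def bias_replicate(seed: int, chrom_len: int = 500_000, n_chrom: int = 2,
                   inv_length: int | None = None,
                   anchor_cfg: AnchorConfig | None = None,
                   scan_cfg: SvScanConfig | None = None,
                   major_min_len: int = 10_000) -> dict:
    """Anchor one contig set on reference A and on C = A plus one inversion.

    The contigs are a clean fragmentation of A cut exactly at the boundaries
    of C's inversion, so no contig spans them; anchoring on C should then
    import the inversion (recapitulation fraction 1.0 against A), while
    anchoring on A imports nothing.
    """
    anchor_cfg = anchor_cfg or AnchorConfig(stride=4, dist_base=200_000)
    scan_cfg = scan_cfg or SvScanConfig(stride=4)
    if inv_length is None:
        # one planted inversion, comfortably "major" yet fitting the chromosome
        inv_length = max(2 * major_min_len, chrom_len // 5)
    sim = SimConfig(n_chrom=n_chrom, chrom_len=chrom_len, seed=seed,
                    contigs_per_scaffold=1.0)
    rng = sim.rng()
    ref_a = simulate_reference(sim, rng, name=f"refA_s{seed}")
    spec = random_sv_specs(ref_a, rng, 1, "INV",
                           (inv_length, inv_length), margin=chrom_len // 8)
    ref_c, truth_c = apply_svs(ref_a, spec, seed=seed, name=f"refC_s{seed}")
    sv = truth_c.planted_svs[0]
    force = {sv.ref_chrom: [sv.ref_start, sv.ref_end]}
    contigs, _, _ = fragment_assembly(ref_a, sim, rng, force_cuts=force)
    report, anchored_a, anchored_c = reference_bias_report(
        contigs, ref_a, ref_c, ref_a, anchor_cfg, scan_cfg, min_len=major_min_len)
    return {"report": report, "truth_c": truth_c,
            "anchored_a": anchored_a, "anchored_c": anchored_c}


def chimera_replicate(seed: int, chrom_len: int = 300_000, n_chrom: int = 2,
                      chimera_rate: float = 0.35, frag_mean: int = 30_000,
                      anchor_cfg: AnchorConfig | None = None) -> dict:
    """Fragment a genome with chimeric scaffold joins and anchor it back.

    For every chimeric scaffold the anchoring should produce a break,
    "-1"/"-2"-suffixed parts, and place parts on both source chromosomes.
    """
    anchor_cfg = anchor_cfg or AnchorConfig(stride=4, dist_base=150_000)
    sim = SimConfig(n_chrom=n_chrom, chrom_len=chrom_len, frag_mean=frag_mean,
                    frag_sd=frag_mean // 4, contigs_per_scaffold=2.0,
                    chimera_rate=chimera_rate, seed=seed)
    rng = sim.rng()
    ref = simulate_reference(sim, rng, name=f"ref_s{seed}")
    scaffolds, scf_agp, truth = fragment_assembly(ref, sim, rng)
    pseudo = anchor_pipeline(scaffolds, ref, anchor_cfg, name="dechimera")
    placement_of = {p.scaffold_id: p for p in pseudo.placements}
    n_chimeras, n_success = 0, 0
    for scf_id in truth.chimera_joins:
        n_chimeras += 1
        parts = [pid for pid in placement_of if pid == scf_id or
                 pid.startswith(scf_id + "-")]
        if not any("-" in p[len(scf_id):] for p in parts if p != scf_id):
            continue  # never split
        members = truth.scaffold_members[scf_id]
        chrom_first = truth.frag_map[members[0]][0]
        chrom_last = truth.frag_map[members[-1]][0]
        placed_chroms = {placement_of[p].r_id for p in parts
                         if placement_of[p].status == "placed"}
        if chrom_first in placed_chroms and chrom_last in placed_chroms:
            n_success += 1
    return {"n_chimeras": n_chimeras, "n_success": n_success,
            "truth": truth, "pseudo": pseudo}


# ---------------------------------------------------------------------------
# end-to-end replay
# ---------------------------------------------------------------------------

def replay_synthetic(cfg: RunConfig) -> Path:
    """Run the whole synthetic study and write a checksummed report directory."""
    outdir = Path(cfg.outdir)
    created = not outdir.exists()
    outdir.mkdir(parents=True, exist_ok=True)
    meta = version_and_provenance(cfg)
    comments = provenance_comments(meta)
    try:
        with open(outdir / "config.yaml", "w") as fh:
            yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)

        rep = inheritance_replicate(
            cfg.seed, chrom_len=cfg.sim.chrom_len, n_chrom=cfg.sim.n_chrom,
            n_inversions=cfg.n_inversions, inv_length_range=cfg.inv_length_range,
            breakpoint_margin=cfg.breakpoint_margin, anchor_cfg=cfg.anchor,
            scan_cfg=cfg.svscan, major_min_len=cfg.major_min_len, d=cfg.d,
            pair_density=cfg.pair_density, min_pairs=cfg.min_pairs)
        bias = bias_replicate(cfg.seed, chrom_len=cfg.sim.chrom_len,
                              n_chrom=cfg.sim.n_chrom, anchor_cfg=cfg.anchor,
                              scan_cfg=cfg.svscan, major_min_len=cfg.major_min_len)

        truth: SimTruth = rep["truth"]
        write_tsv(truth.to_frame(), outdir / "truth.tsv", comments)
        for tag in ("avoid", "span"):
            pseudo: PseudoChromosomeSet = rep[f"pseudo_{tag}"]
            write_fasta(pseudo.assembly, outdir / f"pseudo_{tag}.fa")
            write_fasta(pseudo.unplaced, outdir / f"unplaced_{tag}.fa")
            write_agp(pseudo.agp, outdir / f"pseudo_{tag}.agp", comments)
            write_tsv(pseudo.placement_frame(), outdir / f"placements_{tag}.tsv",
                      comments)
        write_tsv(svs_to_frame(rep["major_avoid"]), outdir / "major_svs_avoid.tsv",
                  comments)
        write_tsv(svs_to_frame(rep["inv_span"]), outdir / "inversions_span.tsv",
                  comments)
        write_tsv(verdicts_to_frame(rep["span_verdicts"]),
                  outdir / "verdicts_span.tsv", comments)
        write_tsv(pd.DataFrame({"endpoint_class": rep["erased_endpoint_classes"]}),
                  outdir / "erased_endpoints_avoid.tsv", comments)
        write_pairs(rep["pairs"], outdir / "pairs_span.tsv", comments)
        write_tsv(bias["report"].summary_frame(), outdir / "bias_summary.tsv",
                  comments)
        chains = [p.chain for p in rep["pseudo_span"].placements
                  if p.chain is not None]
        # the chains map (post-split) scaffolds onto the reference genome
        scf_lengths = rep["pseudo_span"].unplaced.lengths()
        scf_lengths.update(_component_lengths(rep["pseudo_span"]))
        write_paf(chains, outdir / "chains_span.paf", scf_lengths,
                  rep["reference"].lengths())

        summary = pd.DataFrame([
            ("planted_inversions", rep["n_planted"]),
            ("major_svs_after_breakpoint_avoiding_anchoring", rep["n_major_avoid"]),
            ("erased_noninternal_fraction", rep["erased_noninternal_fraction"]),
            ("inversions_recovered_after_spanning_anchoring", rep["n_inv_span_matched"]),
            ("span_supported_fraction", rep["span_supported_fraction"]),
            ("bias_recapitulation_fraction", bias["report"].recapitulation_b),
        ], columns=["quantity", "value"])
        write_tsv(summary, outdir / "summary.tsv", comments)

        manifest = []
        for path in sorted(outdir.iterdir()):
            # the manifest covers computed outputs; the config echo and log
            # carry run-specific paths/timestamps by design
            if path.name in ("manifest.tsv", "run.log", "config.yaml"):
                continue
            manifest.append((path.name, _content_checksum(path)))
        write_tsv(pd.DataFrame(manifest, columns=["file", "sha256"]),
                  outdir / "manifest.tsv", comments)
        with open(outdir / "run.log", "w") as log:
            for k, v in meta.items():
                log.write(f"{k}: {v}\n")
            log.write("status: ok\n")
    except Exception:
        if created:
            shutil.rmtree(outdir, ignore_errors=True)
        else:
            for path in outdir.iterdir():
                path.unlink()
        raise
    return outdir


def _component_lengths(pseudo: PseudoChromosomeSet) -> dict[str, int]:
    return {r.component_id: r.component_interval[1]
            for r in pseudo.agp if r.component_type == "W"}


def _content_checksum(path: Path) -> str:
    """Checksum over non-comment lines, so provenance timestamps in headers
    do not break run-to-run determinism."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for line in fh:
            if line.startswith(b"#"):
                continue
            h.update(line)
    return h.hexdigest()
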