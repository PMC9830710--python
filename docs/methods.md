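# Methods

## The problem being modeled

Reference-guided pseudo-chromosome construction assigns each assembly
scaffold a position and orientation on an existing reference genome. The
procedure has a structural blind spot: scaffold placement can only preserve
rearrangements that are *physically contained* in a scaffold. A
rearrangement whose breakpoints coincide with scaffold boundaries
contributes no conflicting linkage evidence, so the placement stage freely
re-orders and re-orients the fragments to match the reference — erasing a
real rearrangement, or importing one that exists only in the reference.
`refanchor` implements the reconstruction procedure itself, a chain-based
structural-variant caller, and the two diagnostics that separate real from
imported structure: breakpoint provenance (does an SV endpoint fall inside
contiguously assembled sequence?) and the two-reference anchoring
experiment.

## Alignment core

**Seeds.** A seed is a maximal exact match (MEM) between a query sequence
and the reference, on either strand, of length ≥ `min_seed_len`
(default 65 — the "larger than 64 bp" rule read strictly). Matching never
crosses an N. Discovery probes `min_seed_len`-mers of the query (and of its
reverse complement) against a hash index of every reference k-mer position;
hits are verified textually, then extended maximally with block-halving
slice comparisons. A probe whose k-mer occurs more than `max_occ` (default
1) times in the reference is not extended: repeat-anchored seeds carry no
placement information. A MEM is therefore reported iff at least one of its
k-windows is sufficiently unique — the exact semantics mirrored by the
brute-force oracle in the test suite. The optional probe `stride`
(default 1; the pipeline presets use 2–4) skips probe positions; it can
only lose MEMs shorter than `k + stride − 1` and never affects the
boundaries of a found MEM, because extension is maximal regardless of which
window anchored it.

**Chains.** Per (reference sequence, strand), the maximum-score monotonic
path — query starts strictly increasing, reference starts increasing on
`+` / decreasing on `-` — is computed by weighted-LIS dynamic programming.
The score is summed matched bases with query overlap counted once. The DP
additionally requires strictly increasing query *ends*: a seed nested in
the running query envelope contributes zero matched bases under this score,
so the restriction is lossless and makes the pairwise overlap trim exact
(this is verified against exhaustive subset enumeration). Chains are
extracted greedily (best chain, remove its seeds, repeat), so each seed
belongs to at most one chain. The order key of a chain is the median of its
seeds' reference midpoints; an even count takes the floor of the mean of
the two central values. Ties everywhere break by (score, query id,
reference start), making every downstream stage deterministic.
`max_gap` optionally forbids adjacent chain seeds separated by more than a
given distance on either coordinate; the anchoring stage sets it to its
locus-distance threshold and the SV scanner to `min_block`, so chains never
bridge rearrangement-scale discontinuities.

## Anchoring engine

1. **Chimera detection.** Chains with score ≥ max(`sig_abs`, `sig_frac` ×
   scaffold's best score) are significant (`sig_abs` = 5 × seed length,
   `sig_frac` = 0.25). Significant chains are clustered into loci — same
   chromosome and reference gap ≤ `dist_thresh` (default max(1 Mb, 2 ×
   scaffold length); the toy presets scale this down). Two or more loci
   flag a suspected chimera. Each break lands at the midpoint of the query
   interval between adjacent loci, snapped to an N-run inside that interval
   when one exists, since mis-joins typically sit at scaffolding gaps.
2. **Splitting.** Parts are renamed `<id>-1`, `<id>-2`, … in coordinate
   order; concatenating the parts reproduces the scaffold byte-for-byte. A
   cut aimed at or into an N-run moves to the run's end so the run stays
   with the left part. Split parts are re-seeded and re-chained.
3. **Placement.** All significant chains are ranked by score; a chain is
   accepted when its scaffold is still unplaced and its reference span
   overlaps already-occupied intervals of that chromosome by at most
   `ovl_frac` (default 0.2) of its own span. Rejected scaffolds keep their
   lower-scored chains in the queue, so a scaffold outcompeted at one locus
   can land at its second-best locus. One placement per scaffold: scaffolds
   are physical units and are never split implicitly.
4. **Emission.** Per chromosome, placed scaffolds are sorted by the chain
   median (ties by scaffold id), `-` placements reverse-complemented, and
   joined with `gap_len` = 100 bp N runs — deliberately distinct from the
   simulator's 1000 bp intra-scaffold gaps so gap provenance stays
   distinguishable. AGP rows (v2.1; gap rows `scaffold`/`no`) are emitted
   for every component and gap and reconstruct the FASTA exactly.
   Chromosomes with no placements are omitted; unplaced scaffolds go to an
   unplaced bin unchanged.

## SV scanning

Chains between two assemblies (gap-bounded by `min_block`, spans ≥
`min_block`; default 5 kb at toy scale, 50 kb for full genomes) are
classified per query chromosome against a dominant colinear backbone — the
maximum-score strand-consistent chain-of-chains, computed with the same LIS
machinery, in which consecutive members may overlap by at most `min_block`
on both coordinates (so a block re-covering earlier reference can never be
backbone). Backbone members are SYN; a `-` chain nesting between its
flanking backbone neighbors is INV; a chain on a non-dominant chromosome or
displaced beyond `dist_thresh` is TRL (INVTL when inverted); a chain whose
reference interval is already > 50 % covered is DUP (INVDP). Adjacent
same-type calls closer than `min_block` on both coordinates merge. SV
length is the reference span, and the "major" filter keeps non-SYN calls ≥
`min_len` (1 Mbp at genome scale, 10 kb in the toy presets). This is a
deliberately simple block-level caller: no base-level variants, no nested
rearrangement resolution — the categories match what whole-genome synteny
plots display, which is all the downstream analyses need.

## Breakpoint provenance and mate-pair rescue

An endpoint's distances to the nearest N-run edge and the nearest AGP
component boundary are compared to the proximity window `d` (default
1000 bp, the scale of the diagnostic N stretches that motivate the
analysis). Within `d` of a component boundary the class is `component_end`
(the stronger artifact signal, taking priority), else within `d` of a gap
`gap_adjacent`, else `internal`. A call with both endpoints internal is
`supported`. A non-internal endpoint demotes the call to
`suspect_artifact` unless mate pairs rescue it: unique, non-duplicate
pairs with one mate ≥ `min_offset` left of the gap/boundary and the other
≥ `min_offset` right of it, both within `insert_max` of the endpoint, and
at least `min_pairs` = 3 distinct pair ids (the count is a declared
default; the evidence threshold is inherently a judgment call). When some
non-internal endpoints are rescued and others are not, the verdict is
`ambiguous`.

The bias experiment anchors one contig set independently on references A
and B, scans both results against a comparison genome, and matches major
SVs by type and ≥ 50 % reciprocal overlap. The recapitulation fraction of
reference X is the share of (X vs comparison) major SVs reproduced by
(anchored-on-X vs comparison); 1.0 means the anchoring imported the
reference's structure wholesale. When a reference has no major SVs against
the comparison genome the fraction is undefined and reported as NaN.

## Synthetic data: what it emulates and what it does not

The simulator emulates the *structural* features the analyses reason
about: multi-chromosome genomes (i.i.d. bases at a configurable GC),
planted non-overlapping inversions / translocations / duplications tracked
in both coordinate systems, fragmentation into ≥ 200 bp contigs (Normal
length, default 40 ± 10 kb), grouping into scaffolds joined by 1000 bp N
runs, chimeric joins between distant loci at a configurable rate, and
uniform mate pairs with 2–5 kbp inserts plus non-unique/duplicate flags.
Directives can pin cut points at stated positions or keep cuts out of
stated intervals, which is how the experiments control whether breakpoints
fall inside contigs.

It does **not** emulate sequencing error, repeat families, heterozygosity,
or polyploid subgenome similarity. Passing tests therefore demonstrate the
*logic* of anchoring-induced rearrangement artifacts and their diagnosis —
not robustness to repeat-rich or error-prone real data, where seed
uniqueness filtering and chain significance would be under far more
pressure. Derived chromosomes are represented internally as block lists in
original reference coordinates, which keeps truth bookkeeping exact under
any mix of events; nested/overlapping rearrangements are rejected by
design so the registry stays unambiguous.

Two generator choices are identifiability conditions rather than free
parameters. Chimeric joins form only between pieces within a 3:1 size
ratio: under the declared significance rule a junction whose minor side is
below a quarter of the scaffold's best score is invisible to any
relative-threshold detector, so such joins are not a meaningful detection
target. In the breakpoint-*spanning* experiments, each inversion is given
forced flanks of 0.75 × its own length inside its contig: a contig
dominated by its inverted interior is legitimately placed in the inverted
orientation (flipping the flanks instead), which is the anchoring
mechanism acting on the wrong dominant signal, not a failed recovery.
Forced cut points are also hard scaffold boundaries — a scaffold spanning
a forced cut would re-join what the cut was meant to separate.

## Numerical and scale choices

All randomness flows from one integer seed through explicit
`numpy.random.Generator` objects; no global state. Identical configurations
give byte-identical outputs, and the replay manifest checksums every output
(comment headers excluded, since they carry timestamps). The config hash
excludes only the output directory and log level.

The replicate experiments run at desk scale: 2 × 1 Mb genomes for the
self-anchoring fixpoint and inversion recovery, 2 × 500 kb for the 20-
replicate inheritance experiment, 2 × 300 kb for chimera batches, with the
"major SV" threshold scaled to 10 kb accordingly. These sizes exercise
every code path (the algorithms are scale-free; thresholds are explicit
parameters) while keeping a full run in minutes on one CPU. Pipeline
presets use a probe stride of 2–4; seed-level tests and oracles always use
stride 1.

## Known limitations

- The SYN/INV/TRL/DUP classifier resolves conflicts greedily against a
  single backbone; deeply nested or overlapping rearrangements are out of
  scope.
- Repeat handling is a hard unique-anchor filter (`max_occ` = 1), not a
  repeat-graph model; on repeat-dense genomes it simply yields no seeds in
  repeats.
- Mate-pair rescue assumes pair coordinates on the same assembly as the SV
  calls; importing real alignments requires mapping them first and treating
  "unique" as no-secondary-hit with mapping quality ≥ 30.
- Chain quality is summed matched bases; coverage-weighted or
  dispersion-penalized scores are plausible alternatives and exposed as
  hooks (`gap_penalty`), but off by default.
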