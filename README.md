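# refanchor

**When two genome assemblies disagree about chromosome structure, which one
is wrong — or is the disagreement an artifact of how the chromosomes were
built?** Reference-guided pseudo-chromosome reconstruction orders and
orients assembly scaffolds along an existing reference genome. Wherever a
scaffold does not itself span a rearrangement breakpoint, the placement
step silently inherits the *reference's* structure: a real inversion whose
breakpoints fall between scaffolds is erased, and a rearrangement private
to the reference can be imported into the new assembly. Apparent
large-scale inversions and translocations between assemblies of closely
related genomes can therefore be anchoring artifacts rather than biology.

`refanchor` is a compact, fully tested toolkit for studying exactly this
failure mode on synthetic genomes with planted, truth-tracked
rearrangements:

- **simgenome** — a deterministic simulator producing a reference genome, a
  derived genome with planted inversions / translocations / duplications,
  fragmentations into gapped (optionally chimeric) scaffolds with AGP
  component maps, and 2–5 kbp-insert mate pairs, all registered in a
  ground-truth table.
- **seedchain** — the alignment core: maximal exact matches (> 64 bp by
  default, unique-anchor filtered) and maximum-score monotonic chains via
  weighted longest-increasing-subsequence dynamic programming.
- **anchor** — reference-guided reconstruction: chimeric scaffolds
  (two significant mapping loci) are split with `-1`/`-2` suffixes,
  scaffolds are placed greedily best-chain-first onto vacant reference
  intervals, ordered by the median reference midpoint of their chain, and
  joined with 100 bp N gaps into pseudo-chromosomes with AGP provenance.
- **svscan** — a block-level structural-variant caller on alignment chains:
  syntenic / inverted / translocated / duplicated (plus inverted flavors),
  with the conventional "major SV" length filter (≥ 1 Mbp at genome scale)
  measured on the reference span.
- **diagnose** — the validation logic: classify each SV endpoint as
  *internal* (inside unambiguously assembled sequence), *gap-adjacent* or
  *component-end*; count unique, non-duplicate mate pairs bracketing a gap;
  and run the two-reference anchoring-bias experiment.

## The core quantities

For a query scaffold with seeds \(s_1, \dots, s_n\) against a reference, a
chain is a subset with strictly increasing query coordinates and reference
starts increasing (strand `+`) or decreasing (strand `-`), scored as

\[ S = \sum_i \ell_i - \text{(query overlap counted once)} , \]

maximized by weighted-LIS dynamic programming. A scaffold is *chimeric* if
it has ≥ 2 chains with score ≥ max(5·k, 0.25·best) at distinct loci
(different chromosomes, or further apart than a distance threshold).
Placement order along a chromosome is the median of the chain's seed
midpoints on the reference. An SV endpoint is *internal* when it lies more
than *d* (default 1000 bp) from every N-run edge and AGP component
boundary; a non-internal endpoint marks a suspected placement artifact
unless ≥ 3 unique spanning mate pairs rescue it. The *recapitulation
fraction* of the bias experiment is the share of (reference X vs comparison
genome) major SVs reproduced by (anchored-on-X vs comparison genome).

## Worked example

```bash
refanchor replay --out replay_demo --seed 4
cat replay_demo/summary.tsv
```

```
quantity	value
planted_inversions	2.0
major_svs_after_breakpoint_avoiding_anchoring	0.0
erased_noninternal_fraction	1.0
inversions_recovered_after_spanning_anchoring	2.0
span_supported_fraction	1.0
bias_recapitulation_fraction	1.0
```

Reading this top to bottom: two inversions were planted in a derived genome.
When the genome was fragmented so that no contig spans an inversion
breakpoint, anchoring back onto the original reference produced **zero**
major SVs — both inversions were erased by placement — and every erased
breakpoint mapped to a gap or component end in the reconstruction
(`erased_noninternal_fraction = 1.0`), which is precisely the diagnostic
signature of a placement artifact. When contigs *did* span the breakpoints,
both inversions survived anchoring, were called `INV` with internal
endpoints, and were confirmed by spanning mate pairs
(`span_supported_fraction = 1.0`). Finally, anchoring a contig set that is
colinear with genome A onto a reference carrying one extra inversion
imported that inversion wholesale (`bias_recapitulation_fraction = 1.0`) —
the reference, not the data, dictated the chromosome structure.

Each stage is also available standalone (`refanchor simulate / anchor /
svscan / diagnose`); `anchor` emits `pseudo.fa`, `pseudo.agp`,
`placements.tsv` and a PAF of the supporting chains for external dot-plot
viewers.

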