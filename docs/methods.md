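# Methods

This note documents the statistical definitions, the numerical choices,
and the design of the synthetic-data generator. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Definitions and conventions

**Capture success.** For one (accession, locus) cell,
`min(recovered_length / target_length, 1)`; recoveries longer than the
target (e.g. flanking sequence read through) are capped at 1 with a
warning. Target lengths must be positive.

**Parsimony-informative columns.** A column is informative when, counting
only the unambiguous states A/C/G/T (case-insensitive), at least two
distinct states each occur in at least two sequences. Gaps, `?`, `N` and
partial IUPAC codes never count as states. P_PIC is the informative
fraction of columns. The missing-data fraction counts cells in
`{-, ?, N}`; partial ambiguity codes are *not* missing by default because
they still carry state information — a flag
(`ambiguous_as_missing=True`) folds them in, since summary tools differ
on this point. Sample (n−1) standard deviations are used throughout the
per-class summaries.

**Gap-threshold trimming.** `trim_at_threshold(aln, gt)` keeps exactly
the columns whose non-gap fraction is ≥ gt (only `-` is a gap; `?`/`N`
count as present). The optimiser sweeps a grid (default 0.0–1.0 in steps
of 0.1), computes the trimmed P_PIC and the data loss at each threshold,
and picks the P_PIC-maximising threshold among those within the data-loss
budget (default 0.30), breaking ties toward the lowest threshold to
retain more sequence. Data loss is residue-based by default — the
fraction of non-gap characters removed — because the concern is sequence
content, not column count; a column-based variant is selectable
(`loss_metric="columns"`). A locus is discarded when no threshold is
within budget or the best attainable P_PIC is zero. Note that with a
grid containing 0 (whose data loss is always 0), the only reachable
discard path on the default grid is an alignment with no informative
columns at all; stricter grids or budgets make the loss-based discard
reachable, and both paths are tested.

**Coverage score.** For an accession over m loci:
representativeness r = (# loci with any recovery)/m; completeness
c = mean capture success over *recovered* loci (absence is already
penalised by r; averaging zeros in would double-count missingness — the
alternative is available via `completeness="total"`); evenness
e = H′/ln m where H′ is the Shannon entropy of the normalised capture
fractions, with e = 0 when ≤ 1 locus is recovered and e = 1 in the
degenerate m = 1 case. Evenness is computed on capture *fractions*
rather than raw recovered lengths: with heterogeneous target lengths,
full recovery of every locus must score e = 1, which length-weighted
entropy would not satisfy. The locus axis is the transpose of the same
definition. The score is the product r·c·e; the retention cutoff
defaults to 0.5 and is inclusive (score ≥ cutoff).

**Tree QC.** The diameter is the maximum leaf-to-leaf path length.
Outlier flagging is greedy: compute the diameter D, find the leaf whose
removal minimises the reduced diameter D₋ℓ, flag it if
(D − D₋ℓ)/D₋ℓ exceeds the bound (default 0.20), remove it, repeat; the
loop never prunes below three leaves (warning instead). This per-leaf
rule is a deliberate simplification of per-species signature tests in
dedicated tools; it is calibrated on planted rogues in the test suite.
Support contraction collapses internal edges with support ≤ cutoff
(default 10) — the boundary is inclusive, matching the `i & b ≤ 10`
convention, although prose descriptions often say "below" — and leaves
edges with *unknown* support untouched (unknown is distinct from 0).

**Clock statistics.** Root-to-tip variance is the sample (n−1) variance
of root-to-tip path lengths after rooting. Rooting is midpoint by
default; outgroup rooting and "keep" (tree already rooted) are
available, and the variance convention is documented because the
published 0.024 threshold does not state one. Tree length is the sum of
branch lengths. Concordance is the fraction of internal bipartitions of
the species tree — after pruning it to the gene tree's taxa — that occur
in the gene tree (1.0 when no bipartition is testable). The four
retention criteria are concordance > 0.1, root-to-tip variance < 0.024,
tree length > 0.1 (all strict) and taxon count ≥ 25 (inclusive).

**Concordance pies.** For each species-tree bipartition B and gene tree
g: restrict B to g's taxa; if either side has < 2 taxa, g is
uninformative. Otherwise g is concordant if the restricted split occurs
among g's splits on that taxon set, conflicting if g contains a split
incompatible with it (all four cross-intersections non-empty), else
uninformative. Polytomies therefore count as uninformative, never as
conflict.

## Pipeline order

Accessions are filtered exactly once (coverage score, before trimming);
after that the locus is the unit of filtering, and a locus discarded at
any stage is excluded downstream. Outlier leaves flagged on the gene
tree are removed from the corresponding alignment rows rather than
triggering realignment — realignment is outside this toolkit's scope and
the divergence is deliberate. Gene trees are pruned to the retained
accessions; loci dropping below four taxa are excluded. All default
thresholds (0.5 coverage; 30% data loss; 20% diameter; support ≤ 10;
concordance > 0.1; rtt variance < 0.024; length > 0.1; ≥ 25 taxa) are
echoed into the run manifest. The pipeline contains no randomness:
identical inputs and config give byte-identical reports.

## Synthetic-data generator

The generator emulates the statistical structure of a capture-based
herbariomics dataset; one integer seed drives every draw and the same
`SimSpec` always reproduces the dataset byte for byte.

* **Species tree** — pure birth, scaled to root-to-tip depth
  `subst_rate` (default 0.4 substitutions/site, with tiny edges floored
  at 1e-4). The stem edge is excluded from depth scaling.
* **Gene trees** — the species topology with i.i.d. lognormal
  multiplicative branch jitter (σ = 0.08), so clock-like loci have
  root-to-tip variances orders of magnitude below the 0.024 threshold.
* **Clock violators** (default 30 of 150 loci) — lineage-specific rate
  accelerations: the stem edges of *two disjoint nested clades* (each
  roughly 1/6–1/3 of the taxa, not children of the root, with enough
  taxa outside them on their own root side) are elongated so each
  clade's tips gain 1–2 substitutions/site of extra depth. This design
  is deliberate: i.i.d. per-branch rate noise largely cancels along
  root-to-tip paths, and any *single* depth contrast is absorbed by
  midpoint rooting (the root simply slides onto the burst edge), so
  neither produces planted violations that reliably exceed an absolute
  variance threshold. Two bursts in different directions cannot both be
  absorbed. Because every tip of a burst clade gains the same extra
  depth, no single leaf looks like an outlier — the violation survives
  diameter-based pruning, which is exactly the division of labour
  between the two filters.
* **Rogue taxa** (default 1) — the planted rogue's terminal branch is
  rebuilt as `rogue_multiplier` (default 10) times the tree's mean
  branch length on every gene tree, emulating a contaminant or paralog
  whose divergence is unrelated to its true placement. (Multiplying the
  taxon's own pendant edge instead fails in recent radiations, where a
  near-zero pendant times ten is still not a long branch.)
* **Sequences** — Jukes–Cantor along each gene tree, with branch lengths
  scaled by `seq_rate_scale` (default 0.05) during evolution only. This
  decouples tree-statistic realism (depths the clock filter can
  threshold) from alignment realism: at the defaults the alignments show
  on the order of 10–15% informative columns and ~30% missing data,
  the regime of real capture datasets, rather than saturation.
* **Recovery** — each accession draws a quality q from a Beta around its
  expected recovered fraction; herbarium accessions (70% of samples,
  collection years 1900–2015) decay linearly with age
  (`AgeDecay`: base 0.9 at 2020, slope 0.004/yr, floor 0.05), DNA-bank
  and silica accessions sit near 0.95. The accession-level Beta
  concentration (2.0) is deliberately small: historical collections show
  huge between-specimen variance, and at these defaults the age
  regression lands in the weak-effect regime (R² ≈ 0.1–0.2) while the
  planted negative age effect is still recovered at n = 60 in ≥ 90% of
  seeds — both properties are asserted in the tests. Per-locus fractions
  add Beta noise (concentration 10); fractions below 0.05 become zero
  (missing taxon at that locus). Fragmentation is realised as a
  contiguous recovered window per row, plus a fraction (default 0.10) of
  gap-rich columns. Locus lengths are Normal(613, 368) floored at
  120 bp, the scale of typical capture targets.
* **Truth manifest** — planted rogues, violator loci and their burst
  clades, per-accession quality, low-coverage accessions, per-column
  informativeness (computed by direct enumeration inside the generator,
  independent of the metrics module), and the expected coverage-filter
  retention computed with the generator's own inline arithmetic.

What the generator does **not** emulate: indels and alignment error
(fragmentation is clean windows, so trimming signals are milder than in
real flanking regions), paralogy at the sequence level, rate variation
across sites, base-composition bias, and gene-tree/species-tree
discordance from incomplete lineage sorting (gene trees share the
species topology, so concordance deviates from 1 only through missing
taxa and planted edits). Passing tests therefore demonstrate the
correctness and calibration of the QC computations, not the behaviour of
assemblers or aligners on real reads.

## Problem sizes

The test suite exercises the oracles at 100–200 random instances, the
rogue plant at 100 seeds (12 taxa), the clock filter at 50 seeds of the
default 40 taxa × 150 loci (tree-level simulation only, which is why the
generator can skip sequence evolution), and the end-to-end pipeline on a
40 × 150 fixture run twice for byte-identical outputs. The acceptance
script uses 30 seeds for the clock-recovery rates and one 74-accession
simulation for the capture-effect statistics, mirroring a realistic
sample count.

## Known limitations

* The outlier-leaf rule is greedy and per-leaf; a clade of jointly long
  branches is intentionally left to the clock filter.
* Concordance treats unresolved gene-tree regions as uninformative,
  which slightly favours poorly resolved trees in the `> 0.1` criterion.
* The coverage-score components are one concretisation of
  "representativeness × completeness × evenness"; both completeness
  variants are implemented, but reproducing exact retention counts from
  other implementations may require matching their (undocumented)
  choices.
* With the default trimming grid containing gt = 0, the loss-based
  discard rule can only trigger on stricter grids; the informativeness-
  based discard (P_PIC = 0) is the operative rule at defaults.
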