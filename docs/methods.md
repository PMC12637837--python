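# Methods

## Differential methylation model

A β-value is the methylation fraction β = M/(M+U) of one CpG in one sample.
For a two-group contrast the package compares the *group means* of β per CpG
(medians are not used) and tests location with the two-sided Wilcoxon
rank-sum (Mann–Whitney) statistic. A CpG is a DMS when both conditions hold
strictly:

- |Δβ| > `delta_beta` (default 0.15), Δβ = mean(target) − mean(reference);
- p < `p_value` (default 0.05; 0.1 is the conventional choice for small
  pairwise runs and is a config key).

Boundary values fail by design ("greater than", "less than"). Significance
uses the raw p by default; Benjamini–Hochberg q-values are always computed
and can replace p via `use_q`. Hyper/hypo direction is defined only for
called DMS.

**Exact vs approximate p.** When the pooled data are tie-free, the smaller
group has ≤ 8 usable values and the tabulated U distribution has ≤ 10,001
entries, the p-value is exact: the full null distribution of U is built by
the standard counting recurrence f(i, j, u) = f(i−1, j, u−j) + f(i, j−1, u)
and the two-sided p sums all arrangements whose folded statistic
min(U, n₁n₂−U) is at least as extreme as observed. Otherwise a normal
approximation with midranks, tie variance correction
σ² = (n₁n₂/12)·[(N+1) − Σ(t³−t)/(N(N−1))] and a 0.5 continuity correction is
used, clipped to (0, 1]. The exact path is guaranteed only tie-free; β drawn
from continuous distributions makes ties measure-zero, and real EPIC β are
effectively continuous.

**Missing values** ("NA" in TSV) are masked, never imputed: a probe where
either group retains fewer than two usable values is skipped and counted in
the run log rather than raising. This masking policy is a repository
decision; upstream array pipelines usually remove failed probes before
export.

## Promoter windows and per-gene counting

Promoters are the 2,000 bases immediately upstream of each protein-coding
transcript's TSS, 1-based inclusive and strand-aware: `[tss−2000, tss−1]` on
`+`, `[tss+1, tss+2000]` on `−`. Two declared conventions, both of which a
user should know:

- the TSS base itself is **excluded** from the window;
- windows are clipped at chromosome position 1, so a window near the start
  of a chromosome may be shorter than 2,000 bases.

Per-gene DMS counts use unique CpGs: a probe inside the windows of several
transcripts of one gene counts once for that gene; a probe inside promoters
of two distinct genes counts once for each (no unique-mapping filter — the
counting makes no exclusivity claim). Genes need ≥ 2 promoter DMS for a
class: all-hyper → `hyper`, all-hypo → `hypo`, both → `mixed`, otherwise
`none`.

Chromatin states are taken from a summarised segmentation (promoter,
enhancer, insulator, heterochromatin, active transcription, other; BED input,
converted to 1-based inclusive on read). A probe overlapping no interval is
`unassigned`; a probe on a segment boundary takes the interval with the lower
start — a safety rule only, since segmentations are non-overlapping. CpG
context (island/shore/shelf/open sea) is read from the manifest, never
recomputed from sequence.

## Cross-cohort concordance and integration

Genes classified (class ≠ none) in both cohorts are concordant iff the labels
are identical; `mixed` must match `mixed` — mixed-vs-hypo counts as
discordant. Strict label equality is the reproducible reading of a
concordance defined only by example; the alternative (dropping mixed genes
before comparison) is noted as an open choice. Discordant genes are removed;
genes classified in one cohort only are reported as `unshared`.

A concordant gene is flagged *epigenetically regulated* iff its expression
moves against its promoter methylation: hypo + up or hyper + down, with
expression direction from |log2FC| > 1 and p < 0.05 (strict) after discarding
genes with base mean ≤ 20. The default wiring takes methylation evidence from
both cohorts and expression evidence from the designated expression cohort
(the second cohort unless configured otherwise). Whether DE significance uses
raw or adjusted p is adopted literally as raw p.

Expression utilities: median-of-ratios size factors (reference = per-gene
geometric mean across samples, genes with any zero excluded from the
reference, factor = per-sample median of count/reference — note the median is
taken on the ratio scale; implementations taking it in log space differ in
the 4th decimal when the gene count is even), log2(count/factor + 1)
transform, and a **stand-in DE test** — Welch's t on the log-normalised
values — used only so synthetic end-to-end runs need no external fitter. The
stand-in labels itself in the output metadata and is bypassed whenever an
external DE table is supplied. It is not a negative-binomial Wald test and
should not be used for real inference.

## Enrichment statistics

All enrichments are 2×2 tables against the probe (or gene) universe:

- odds ratio: sample cross-product (a·d)/(b·c); ∞ or 0 at zero cells;
- p: Fisher's exact test, two-sided by the "probability ≤ observed"
  summation rule (two-sided exact conventions vary; this is the common one
  and the one verified against exact rational enumeration in the tests);
- CI: Woolf interval exp(ln OR ± z·√(1/a+1/b+1/c+1/d)), with
  Haldane–Anscombe +0.5 on all cells when any cell is zero (row flagged
  `degenerate`);
- BH correction applied separately within each family (chromosomes,
  contexts, states, gene sets).

Chromosome enrichment also reports the expected DMS count under the
probe-density null, total DMS × (chromosome probes / total probes).
Direction-specific context enrichment compares hyper (or hypo) DMS against
all non-DMS probes; DMS of the opposite direction are excluded from the
universe of that table. The ORA universe defaults to genes with at least one
promoter probe on the manifest — array coverage defines the testable space,
not the whole genome.

## Distance trees

d(i, j) = 1 − ρ(i, j), Spearman correlation over the selected top-k most
variable CpGs (k default 5,000; variance with missing masked, ties broken by
probe id). The transform to a distance is a declared choice; its range
[0, 2] is documented. Missing values are handled pairwise-complete; a pair
sharing fewer than 3 probes is an error.

The tree builder is plain agglomerative clustering (average linkage by
default, complete available); a neighbour-joining construction would be a
defensible alternative, so the linkage is exposed rather than hidden. Merge
heights equal the linkage distance; Newick branch length of a child is
parent height − child height with leaves at height 0. Equidistant merge
candidates are resolved by the pair whose smallest member label sorts first,
making fully tied inputs reproducible. Heatmap ordering uses Euclidean
hierarchical clustering with optional per-CpG mean centering (the display
normalisation); NaNs are filled with the row mean for ordering only.

## Synthetic cohorts

The generator emulates a two-cohort design (xenograft-like + patient-like)
with PT/LN/LU groups and a planted lung-specific methylation program. What it
does:

- baseline β per probe from a bimodal mixture (low mode 0.15, high mode
  0.85, weight 0.5), per-sample draws from Beta(mβ·c, (1−m)·c) with
  concentration c = 50 — giving within-group β SD ≈ 0.07, a realistic
  array-scale noise level;
- planted effects shift the Beta mean by Δβ (default 0.30) in the LU group
  only, then clip to [0.02, 0.98] — never by adding constants to drawn
  values, so no truncation artifacts;
- planted genes (default 60 of 1,200) receive ≥ 2 planted promoter probes by
  construction, so the ≥2-DMS rule is satisfiable; isolated planted probes
  (default 100) sit outside promoters and exercise the rule's rejection side;
- direction mix 90% hypo (matching the strongly hypo-dominant landscape of
  distant metastases), cross-cohort concordance 90%, discordant genes
  flipped in the second cohort with mid-range baselines so both directions
  stay reachable;
- RNA counts are negative-binomial (mean 200, dispersion 0.1) for the second
  cohort, with planted |log2FC| = 2 in the LU group for a coupled fraction
  (default 30%) of concordant planted genes, direction opposing methylation.
  The exported DE table is *computed* by the stand-in test on those counts;
  the planted directions live in the ground-truth tables;
- identical config + seed ⇒ bit-identical outputs.

The coupled fraction is deliberately higher than the small fraction typical
of real integrations so that the planted positive set is large enough to be
meaningfully recoverable at desk scale.

What it does **not** emulate: probe-type chemistry bias, cell-type
composition, copy-number effects on β, correlated probes within islands, and
batch structure. Hypermethylation enrichment in open-sea/heterochromatin is
planted only on the isolated probes; planted *promoter* probes necessarily
carry island-biased context, so a default-conditions context enrichment is
dominated by the promoter geometry rather than the configured bias. Passing
tests therefore demonstrate correctness of the statistics and the plumbing
under idealised independence assumptions, not performance on real arrays.

## Problem sizes and calibration checks

The default synthetic conditions are 20,000 probes / 1,200 genes / 4 samples
per group per cohort — large enough for stable statistics, small enough for
interactive use. The calibration and recovery checks use: a 10,000-probe
zero-effect cohort with a 6-vs-6 contrast (caller rejection rate at p < 0.05
stays ≤ 0.06; the exact rank-sum test is conservative at small n), a
50,000-probe cohort with 200 planted Δβ = 0.30 probes (probe-level
sensitivity ≥ 0.90; in practice 1.0), and 200 uniform-thinning replicates on
a 10,000-probe manifest for the chromosome-enrichment false-positive rate
(declared band 0.02–0.08 around the nominal 5%, since Fisher's exact test is
conservative on discrete tables).

## Known limitations

- Samples are treated as exchangeable within groups; no pairing of lesions
  from the same animal/patient and no covariate adjustment.
- No region-level (DMR) smoothing; each CpG is tested independently.
- Promoter-only: gene-body and enhancer methylation are out of scope.
- The stand-in DE test ignores count overdispersion structure beyond what
  log-normalisation absorbs.
- Woolf CIs are asymptotic; with very sparse tables the Haldane correction
  keeps them finite but approximate.
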