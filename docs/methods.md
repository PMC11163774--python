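# Methods

This note documents the statistical machinery, the synthetic-data design,
and the numerical and design choices behind `occmeth`.

## Scales and transforms

Methylation arrives as β-values (methylated-intensity fraction per CpG,
in [0,1]). All testing is done on M-values, M = log2((β+α)/(1−β+α)), which
roughly stabilizes variance and unbounds the scale. The offset α defaults
to 0 because the simulator clips β into [10⁻⁶, 1−10⁻⁶], keeping M finite;
with real data where β can be exactly 0 or 1, set a small positive α
(`TransformConfig(m_offset=...)`). The transform is strictly monotone and
exactly invertible for any α ≥ 0. A consequence worth knowing: for probes
whose β sits within noise reach of a boundary, M-scale noise is heavy-tailed
(dM/dβ ~ 1/β near 0), so occasional large spurious M fold changes at such
probes are expected behavior at α = 0, not a defect; the dual DM cutoff and
the multi-set consensus absorb them.

## Probe filtration

`filter_probes` applies ordered rules — detection-failure fraction (default:
drop a probe failing in > 5% of samples), missingness (default 0% after
masking), then arbitrary named drop-lists (sex-chromosome, SNP-overlapping,
cross-reactive probes). Rules are applied in declared order and each probe
is counted under the first rule that removes it, so reports are reproducible
and filtering is idempotent. Raw IDAT handling is out of scope; the
contract starts at a β matrix.

## Moderated differential methylation

Each sample set (primary tumors mt vs wt; cell lines mt vs wt; each
isogenic knockout pair, ko vs parental, duplicates) is tested per probe
with a two-group linear model on M. The pooled residual variance s²_g
(d_g = n₁+n₂−2 df) is shrunk toward a prior:

    s̃²_g = (d₀ s₀² + d_g s²_g) / (d₀ + d_g)

with (d₀, s₀²) fitted by method of moments on z = log s²_g: the mean and
excess variance of z beyond the chi-square sampling term (trigamma(d_g/2))
identify the prior through digamma/trigamma matching; the trigamma inverse
is solved by a monotone Newton iteration. Non-positive excess variance
means a common variance fits, giving d₀ = ∞ and complete shrinkage. The
moderated t = Δmean / (s̃_g √(1/n₁+1/n₂)) is referred to t with d₀+d_g df;
forcing d₀ = 0 recovers the ordinary pooled t exactly and d₀ = ∞ the
s₀-pooled z statistic — both are tested as identities, and the whole
machinery is cross-checked against the reference R implementation on a
fixture. BH adjustment is applied within each sample set independently
(the sets differ in size and composition).

A probe is called DM at adj. p ≤ 0.05 **and** |M log2FC| ≥ 1 (both
config-exposed; the dual volcano cutoff). The consensus keeps probes called
in ≥ 2 of the 4 sets whose flagged directions all agree; direction
conflicts are reported as ambiguous and excluded. Consensus probes are
annotated to promoter / alternative-promoter / gene-body CpG-island classes
taken from the annotation table (never recomputed from coordinates;
coordinates, when present, are 0-based half-open).

## Methylation–expression integration

Expression (log2, cell-line panel) is batch-corrected per gene by a
location-scale adjustment: each batch is centered to the gene's grand mean
and rescaled to the pooled within-batch SD. This is transparent, exactly
testable (post-correction batch means agree to 1e-8; within-batch rankings
are preserved), and sufficient for a mean-shift batch structure; an
empirical-Bayes variant is deliberately out of scope. Zero-variance batches
are shifted but not rescaled; single-sample batches are an error.

Each retained consensus probe in a promoter/alt-promoter/gene-body CGI is
linked to its target gene; the link's ρ is the Spearman correlation
(average ranks on ties, pairwise-complete) between probe M and gene
expression across shared cell lines, computed against M, not β. Patterns
are the fold-change quadrants (hyper/hypo × up/down) gated on |ρ| ≥ 0.25;
links on a quadrant boundary (a fold change exactly 0) stay unclassified.
The scatter highlight rule takes absolute values on all three conditions
(|meth log2FC| > 2, |expr log2FC| > 2, |ρ| > 0.75, all strict).

## Pre-ranked GSEA

Three rankings are built over the genes with consensus DM evidence: the
gene's methylation log2FC and its ρ come from the gene's *representative
link* — the consensus probe with the largest |M log2FC| in the cell-line
set (the comparison the integration plots use) — and the expression log2FC
is the gene's own. Genes missing any score are dropped so the three
rankings share one universe. Ties in ranking order are broken
lexicographically by gene symbol for determinism.

The enrichment score uses the weighted KS running sum with weight exponent
p = 1 ("classic weighted"): hits advance by |score|^p normalized over the
set's hit-weight total, misses retreat by 1/(N−N_hits); ES is the signed
extreme of the profile. At p = 0 this reduces to the classical KS statistic
and is invariant under monotone score transforms. The null is gene-label
permutation (the only option for pre-ranked input), 1000 draws by default,
each set seeded from (seed, hash(set name)) so results do not depend on
collection order. NES divides ES by the mean |null ES| of the same sign;
nominal p is the same-sign tail fraction with +1 smoothing; FDR q follows
the pooled-null convention (same-sign pooled null NES tail over observed
NES tail, clipped to [0,1]). Sets are size-filtered to [5, 500] after
universe intersection. Leading edges are the members at/before a positive
peak (at/after a negative one). The triple consensus requires FDR ≤ 0.25
and |NES| ≥ 2 under every metric; the consensus leading edge is the
intersection across metrics of the per-metric unions over significant sets.

## Selection

Dependency scores (gene × cell line, CRISPR and RNAi kept separate, never
averaged together) are summarized as arithmetic means per ARID1A status
group; genes absent from the table are reported missing, never zero. The
"mt-specific dependency" flag is sign-based — mt mean < 0 ≤ wt mean — with
no magnitude cutoff. A gene passes the consistency filter when at least one
of its retained consensus probes is DM in both the primary-tumor and the
cell-line sets with equal direction (gene-level evidence; a stricter
probe-level variant would require the same probe, which is what this is).
The candidate table is the intersection of the consensus leading edge with
the consistency filter, one row per gene populated from the integration and
dependency outputs without recomputation. The published study followed this
table with a manual genome-browser curation step; that visual step is not
computation and is out of scope — the pipeline ends at the programmatic
table.

## Validation statistics

BSP semi-quantification: clone×CpG calls (1 methylated, 0.5 hemi, 0
unmethylated, missing excluded from numerator and denominator) are averaged
per CpG and per region. BSP-vs-array concordance is a Spearman correlation
with an exact permutation p for n ≤ 9 (all n! permutations enumerated) and
the t approximation above. RT-qPCR uses 2^−ΔΔCt with a single reference
gene (multi-reference geometric means out of scope); DAC induction is a
two-sided pooled-variance Student t on replicate ΔCt values (Welch by
flag), with the conventional star mapping. Zero pooled variance with equal
means gives p = 1; with unequal means, p is reported as 0 (below the
machine floor).

## The synthetic-data generator

The generator emulates the study design: tumor mt/wt groups, a cell-line
panel, and two knockout pairs run in duplicate (default cohort shape
11/24/10/3/2+2+2+2). Background probe baselines come from an equal-weight
Beta(1,9)/Beta(9,1) mixture — bimodal with the printed low/high β bins
heavy. Per-sample values add Gaussian β noise (default SD 0.01, the
technical-replicate scale of EPIC arrays) and are clipped to
[10⁻⁶, 1−10⁻⁶].

DM structure: `frac_dm` fixes both the DM probe count (frac_dm·n_probes)
and DM gene count (frac_dm·n_genes), so a random decoy set's expected DM
overlap is size·frac_dm. Each DM gene is region-coherent — all its DM
probes in one class (70% promoter, 20% gene-body, 10% alt-promoter by
default), because same-sign promoter and gene-body changes would cancel in
the coupling model. Directions split 50/50 hyper/hypo. DM baselines start
clearly inside the mode opposite their direction (Beta(2,8)/Beta(8,2),
rescaled into [0.02, 0.98] so no DM probe saturates at the clip boundary)
and shift by ±delta_beta in the mutant/knockout arms.

Expression couples only for *coupled* genes (planted genes always; every
other gene with probability `coupled_fraction`, default 0.5 — methylation
change does not universally translate into expression change, and without
this heterogeneity the ρ ranking would carry no set-level contrast at all):
expression = baseline − c·mean(promoter M) + c·mean(gene-body M) + batch +
noise. Batches alternate across samples so correction cannot erase the
group signal.

The planted gene set is drawn from hypomethylated promoter-DM genes, so
under repressive coupling its consensus sign pattern is (−, +, −) —
negative methylation NES, positive expression NES, negative ρ NES.
`n_candidates` planted genes are engineered as recoverable ground truth:
they alone among planted genes are also DM in tumors (mirroring the
observation that most EZH2-target leading-edge genes fail tumor/cell-line
consistency), and they carry the strongest signature — baselines deeper in
the opposite mode (Beta(16,2)) and 1.5× coupling — as the study's validated
genes were its clearest cases. The dependency table gives candidates a
negative mean shift in mutant lines only.

What the generator does **not** emulate: tumor purity and cell-type
heterogeneity (tumor noise is as clean as cell-line noise), probe
cross-hybridization, spatial/chromosomal autocorrelation of methylation,
realistic MSigDB set-size distributions, and survival structure. Passing
tests therefore demonstrate the correctness and calibration of the
machinery under the assumed generative structure, not performance on real
tumor arrays.

## Problem sizes and determinism

The recovery experiments run at 10,000 probes / 2,000 genes with 10v10
tumor and cell groups and 2v2 knockout pairs, 1,000 permutations, 50 decoy
sets — the whole funnel completes in seconds, and the type-I experiments
use 20 null replicates and 250 decoy sets. One integer seed drives every
stream (simulation arms, expression, gene sets, dependency, permutations)
through independently derived generators, so every stage is bit-reproducible
and stage outputs are order-invariant where the contract says so.

## Known limitations

- FDR q from the pooled permutation null is conservative for very small
  collections and exactly 0 when no null NES reaches the observed one.
- The consistency filter needs tumor evidence by construction; effects
  present only in the knockout pairs can never produce candidates.
- With α = 0, probes saturating the β clip bound can show extreme M fold
  changes; on real data either set α > 0 or add an extreme-β drop-list to
  the filter rules.
- The location-scale batch correction assumes batch effects are additive
  per gene on the log2 scale.
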