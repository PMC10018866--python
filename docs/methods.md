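# Methods

## Cytosine contexts

Every reference cytosine is classified, per strand, by its immediate
neighbours: GCH (G-C-notG) reports exogenous *M.CviPI* GpC
methyltransferase activity, i.e. chromatin accessibility; HCG
(notG-C-G) reports endogenous CpG methylation and is partitioned into
WCG (A/T before) and CCG (C before), since residual CpC
methyltransferase activity can contaminate CCG; GCG mixes both signals
and is excluded from all GCH and HCG summaries; WCH should be fully
bisulfite-converted, so apparent methylation there flags conversion
failure.  Minus-strand cytosines (forward-strand Gs) are classified on
the reverse complement and reported at the forward coordinate with
strand "−", matching pileup convention.  N-flanked and chromosome-edge
cytosines are UNCLASSIFIED and never counted.  Coordinates are 0-based
half-open internally; 1-based only at SAM/VCF boundaries.

Context densities are reported as bp-per-site over both strands by
default (a `both_strands` flag selects one strand); CCG can be excluded
from HCG summaries by passing the atomic label sets explicitly.

Compartment-eigenvector orientation follows the GC convention: the
first eigenvector of a Hi-C observed/expected correlation matrix has an
arbitrary sign, so it is flipped, when its Pearson correlation with
per-bin GC content is negative, to make the high-GC A compartment
positive.  NaN bins are excluded from the correlation but preserved.

## Methylation calling and pair filters

A read's conversion strand (OT/OB) is taken from the aligner tag
(default `XG`, values CT/GA), falling back to mismatch-pattern
inference against the reference.  OT reads report forward-strand
cytosines (read C = methylated, T = unmethylated, other bases skipped);
OB reads report minus-strand cytosines as G/A at forward G positions.
Filters: base quality > 5 per call; mapping quality > 30 on both ends
(this is also the uniqueness criterion — secondary/supplementary
records are ignored); PCR-duplicate flags trusted and dropped; reads
with ≥3 apparently methylated WCH calls dropped as incompletely
converted (the count threshold is configurable; CCH is not counted
because of residual CpC methyltransferase activity).  Pair separation
is the outermost span of the two ends ("insertion size"); cis pairs
above 20 kb are long-range.  A pair is assigned to a loop-anchor pair
(BEDPE row) when one end overlaps each anchor, in either orientation.

## Long-range concordance

Each qualifying read pair (≥3 GCH calls on both ends; the threshold is
the `min_sites` parameter, default 3) contributes one point (f₁, f₂) of
per-read methylated fractions; points are pooled across anchor pairs —
each dot is a molecule, not an anchor average.  Reported statistics:
Pearson r; phi (Pearson on fractions binarized at 0.5, with ≥0.5 → 1);
and the tetrachoric correlation — the ML estimate of the latent
bivariate-normal correlation given the thresholds implied by the 2×2
margins, computed by bounded scalar minimization of the multinomial
negative log-likelihood with cell probabilities from the bivariate
normal CDF (any zero cell gets a +0.5 continuity correction; the cos-π
closed form r = cos(π/(1+√(ad/bc))) is available as a cheap fallback).

The null permutes, within each anchor-pair group, the end-2 summaries
among the group's molecules (end-1 fixed; singleton groups pass
through), 100 replicates, seeded.  This is the tightest null preserving
both per-anchor mean fractions exactly in every replicate.  An
alternative whole-anchor grouping is obtained by grouping pairs by
anchor rather than anchor pair before calling the shuffle.

Observed vs null is tested with Fisher's (1925) z.  r₂ is the mean of
the per-replicate shuffled correlations; its effective sample size is
n₂ = n₁ × n_shuffles by default ("pooled" mode), because a mean over
100 near-independent replicates carries ~1/100 the sampling variance of
a single correlation — with n₂ = n₁ ("single" mode, available as
configuration) the null z is ~N(0, 0.5) and p-values are conservative
by about √2 in the z scale.  Under the pooled default the null p-value
distribution is approximately uniform (verified over 20 simulated null
seeds).

The local control selects pairs whose two ends lie in the same single
anchor within 1 kb, sampling at most 100 pairs per anchor (seeded), and
runs the identical statistics.

## Allele-specific footprints

Reads covering a heterozygous SNP are assigned REF/ALT by base, with
two bisulfite guards: C/T SNPs are unassignable from OT reads and G/A
SNPs from OB reads (conversion makes the alleles indistinguishable);
bases matching neither allele, or below base quality, are unassignable.
Per SNP, pooled GCH methylated/unmethylated counts by allele at the
SNP-overlapping ends form the SNP-anchor table, and at the mate ends
(required > 20 kb from the SNP, same chromosome) the non-SNP-anchor
table; loci need ≥2 assigned reads per allele and ≥1 GCH call per end
(the `min_gch_per_end` default is deliberately 1 here, vs 3 in the
concordance module, to keep sparse distal ends).  Fisher's exact
two-sided test per table; BH FDR applied separately to the SNP-anchor
and non-SNP-anchor p-value vectors across all tested loci (zero
p-values are floored at the smallest positive float first).  Group
rules: Group 1 = FDR<0.05 at both anchors; Group 2 = FDR<0.05 at the
SNP anchor and FDR>0.95 at the distal anchor; Group 3 = the mirror
image; anything else NONE.

The Fisher unit is the pooled GCH call.  Calls on one read share the
molecule's state, so pooling across reads pseudo-replicates whenever
per-read states are dichotomous; the simulator therefore plants allelic
effects as per-site emission probabilities (below), under which the
pooled test is correctly calibrated.  On real data with strong
molecule-level bimodality the pooled test is anti-conservative; this is
inherited from the method being reproduced and is the main caveat for
interpreting the FDR scale.

A known property of the Group 2/3 rule: "FDR>0.95 at the insignificant
anchor" selects only the extreme upper tail of the null.  BH-adjusted
values of continuous null p-values concentrate well below 1 (roughly
m·p/rank along the upper tail), so with well-powered tables most
genuinely-null anchors land between 0.05 and 0.95 and the locus falls
into NONE rather than Group 2/3.  The rule behaves as intended mainly
for sparse tables, where the two-sided Fisher p has a large point mass
at exactly 1 — the regime of low-coverage real data (2 reads per allele
minimum) rather than of well-powered simulations.  The classifier
implements the rule as stated; `fdr_null` is configurable.

## Variant post-filtering

Rules, each annotated independently into FILTER (PASS iff none fail):
GQ ≤ 20; depth > 250; caller strand-bias score > −0.02 (the score is
consumed, not recomputed: the upstream caller's convention is more
negative = less biased); depth > 40 with MQ0 fraction > 0.1;
GQ/depth < 1; another SNP within ±10 bp (all members of a cluster
fail).  Records missing an annotation skip that rule with a counted
warning.  The post-imputation gate keeps biallelic SNPs with MAF > 0.01
and imputation R² > 0.3.  Ti/Tv counts A↔G and C↔T as transitions over
biallelic SNVs only.  Genotype concordance matches sites on
(chrom, pos, ref, alts) and compares unordered genotypes; sensitivity
is truth variant sites recovered with matching genotype over truth
variant sites, precision the analogue over test variant sites; an
optional confident-region mask restricts the comparison.

## The simulator

The generative model per molecule: latent open/closed states (S₁, S₂)
at the two anchors from a bivariate Bernoulli with marginal `pi_open`
(default 0.5) and correlation `rho_latent` (default 0.6; feasibility of
the joint pmf is checked); each GCH site on end i methylated with
probability `p_open` (0.8) if open else `p_closed` (0.2); HCG — and
GCG, which mixes signals — methylated at `endo_hcg_meth` (0.75);
WCH/CCH unmethylated.  Bisulfite chemistry on the molecule's
equiprobable OT/OB strand: unmethylated cytosines convert (C→T on OT,
G→A on OB) except with probability `conversion_failure` (0.005);
sequencing errors substitute a uniformly different base at
`sequencing_error` (0.001).  Reads (150 bp, base quality 40, mapQ 60)
are emitted as aligned gapless SAM records with XG conversion tags —
the toolkit's scope starts after alignment, so no aligner is involved.
References are i.i.d. with P(G)=P(C)=gc/2 at gc=0.42 (human-like
overall GC).  Anchor pairs (1 kb anchors, >20 kb apart) tile the
chromosome one pair per block with seeded jitter, re-jittered if an
anchor lacks 3 GCH sites on either strand.  Optional local molecules
place both ends in one anchor with a single shared state, emulating the
highly concordant short-range regime.  Defaults give 20 anchor pairs ×
100 molecules = 2,000 long-range pairs.

Planted allele-specific loci put an A/T heterozygous SNP (assignable on
either conversion strand) inside one anchor; the effect is the per-site
GCH emission probability itself — 0.9 vs 0.1 per allele at affected
anchors (both anchors for Group 1, SNP-only for Group 2, distal-only
for Group 3), with the unaffected anchor emitting i.i.d. at the
marginal accessibility pi_open·p_open + (1−pi_open)·p_closed (0.5 at
defaults).  Using emission probabilities rather than per-read latent
states at these loci keeps null-anchor Fisher p-values uniform, which
is what the pooled-call test assumes.  Everything is deterministic
under the config seed, and truth tables record per-molecule states,
alleles, conversion-failure counts and planted locus labels.

What the simulator does **not** emulate — and hence what passing tests
cannot show about real data: CpG-island structure and CpG depletion
(i.i.d. sequence makes HCG as dense as GCH, unlike the ~1-in-83 bp vs
~1-in-13 bp contrast in the human genome), indels and mapping error,
non-uniform coverage and PCR duplication structure, within-read
dependence of accessibility beyond the single molecule state,
cell-type mixtures, and genuinely bimodal molecule populations at
allelic loci (see the calibration caveat above).

## Problem sizes and numerical choices

Desk-scale defaults keep every analysis in seconds-to-minutes:
megabase references, thousands of molecules, hundreds of planted loci.
The tetrachoric optimizer is bounded to |ρ| ≤ 0.9999 with xatol 1e-6;
cell probabilities are clipped at 1e-12 before the log.  Degenerate
inputs (zero variance, empty margins, |r| = 1, all-identical shuffles)
raise explicit errors and are excluded from summaries rather than
propagated as NaN; shuffle replicates that degenerate are counted in
the result.  Pair separation uses outermost coordinates; mate distance
for allelic loci is measured from the SNP position to the nearer mate
edge.  BH inputs are floored at the smallest positive float.  All
random draws flow from `numpy.random.default_rng` seeded from the
config or function argument; identical seeds give byte-identical SAM
output.
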