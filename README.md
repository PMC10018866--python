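# nomehic

Downstream analysis of **bisulfite-converted Hi-C with GpC
methyltransferase footprinting (NOMe-HiC)**: a single sequencing library
that reports, per DNA molecule, chromatin accessibility (exogenous GCH
methylation), endogenous CpG methylation (HCG/WCG), genotype, and
long-range 3D genome contacts.  The package takes *aligned,
duplicate-marked* bisulfite read pairs and answers three questions:

1. **Are chromatin accessibility states coordinated across chromatin
   loops?**  Read pairs from one molecule whose ends fall in two loop
   anchors >20 kb apart give paired per-read GCH methylation fractions
   (x, y).  Their Pearson correlation r (also phi after binarizing at
   0.5, and the tetrachoric correlation) is compared to a
   *mean-preserving shuffle null*: within each anchor pair, end-2
   summaries are permuted across molecules 100×, keeping every anchor's
   average accessibility fixed while destroying molecule identity.
   Significance comes from Fisher's (1925) z for two independent
   correlations, z = (atanh r₁ − atanh r₂)/√(1/(n₁−3) + 1/(n₂−3)).
2. **Are footprints allele-specific over large distances?**  Read pairs
   with one end on a heterozygous SNP are split by allele; pooled GCH
   methylated/unmethylated counts per allele at the SNP end and at the
   distal (>20 kb) mate end form two 2×2 tables per SNP, tested with
   Fisher's exact test and Benjamini–Hochberg FDR.  Loci are classed
   Group 1 (allelic at both anchors, FDR<0.05), Group 2 (SNP anchor
   only; distal FDR>0.95) or Group 3 (distal anchor only).
3. **Which bisulfite genotype calls are trustworthy?**  Post-filters on
   raw calls (GQ≤20, depth>250×, strand bias>−0.02, depth>40× with >10%
   MQ0 reads, GQ/depth<1, SNP cluster within ±10 bp), the
   post-imputation gate (biallelic, MAF>1%, R²>0.3), Ti/Tv and genotype
   concordance summaries.

A fully seeded simulator (`nomehic.simulate`) generates references,
loop anchors, linked bisulfite read pairs with a planted within-molecule
accessibility correlation ρ, allele-specific loci with known group
labels, and crafted variant tables — so every stage is testable at desk
scale with known truth.

## Worked example

```python
from nomehic import simulate, bsreads, concordance

# 20 anchor pairs x 100 molecules, latent accessibility correlation 0.6
cfg = simulate.SimulationConfig(seed=1, rho_latent=0.6)
ds = simulate.simulate_linked_readpairs(cfg)

pairs = bsreads.load_linked_pairs(ds.reads, ds.index)      # mapQ>30, BQ>5 ...
result, local = concordance.run_long_range_concordance(pairs, ds.anchors, seed=5)
print(f"n={result.n_pairs} r={result.r_observed:.3f} "
      f"shuffled={result.r_shuffled_mean:.3f} p={result.p_fisher:.2e}")
```

prints

```
n=1681 r=0.415 shuffled=0.006 p=1.19e-70
```

i.e. of 2,000 simulated molecules, 1,681 pairs carry ≥3 GCH calls on
both ends; their per-read accessibility fractions correlate at r=0.415
across >20 kb, while the 100 mean-preserving shuffles centre on
r≈0.006 — the coordination lives in molecule identity, not in anchor
averages (Fisher z, p≈10⁻⁷⁰).  The observed r is attenuated below the
latent ρ=0.6 by binomial emission noise at ~5 GCH sites per read end,
exactly as the site-level Monte-Carlo model predicts (r≈0.44 at 200,000
pairs).

The same analyses are available from the shell:

```bash
nomehic simulate --config sim.yaml --seed 5 --out data/
nomehic contexts density --fasta data/reference.fa --labels GCH,HCG,WCG
nomehic calls --bam data/reads.sam --fasta data/reference.fa --out calls
nomehic concordance --bam data/reads.sam --fasta data/reference.fa \
        --bedpe data/anchors.bedpe --seed 3
nomehic allelic --bam data/reads.sam --fasta data/reference.fa \
        --vcf data/hets.vcf --out allelic.tsv
nomehic variants filter --vcf raw.vcf --out filtered.vcf
```

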