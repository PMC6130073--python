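# Methods

This note documents the statistical procedures methfoot implements, the
generative model behind its synthetic panels, the numerical choices that
were genuinely open, and what a green test does and does not establish.

## Methylation-state calling

WGBS reads unmethylated cytosines as thymine, so methylation is inferred
from per-cytosine methylated/unmethylated read counts. Two conversion
errors exist in principle; only non-conversion (a truly unmethylated C
escaping conversion, rate ε) enters the null hypothesis, so only ε is
modelled. ε is estimated per library as the pooled methylated-read
fraction over all chloroplast cytosines — the chloroplast genome is
naturally unmethylated — and a library passes QC iff ε < 1%.

Per site, the test is the exact binomial upper tail
P(X ≥ n_meth | depth, ε), computed only where depth ≥ 4 (`min_depth`,
configurable; the source protocol states the depth rule both as "< 4
removed" and "more than four kept" — we keep depth ≥ 4). BH correction
runs per library across all tested sites of all three contexts jointly
(a per-context option exists); a site is methylated iff q < 0.01.
Degenerate case: ε = 0 with n_meth > 0 yields p = 0, clamped to the
smallest positive float and flagged in the log.

Weighted methylation of a region = Σ n_meth / Σ depth over the region's
context sites passing the depth filter; an uncovered region is *missing*,
not zero. Symmetric-CpG strand merging is available
(`merge_cg_strands`) but off by default, since the upstream protocol
never states it.

## DMR detection

Detection is a re-implementation of a Metilene-style segmentation
workflow with populations as groups and accessions as replicates, not a
wrapper: the engine is the package's own, defined and tested here.

* **Blocks.** Per (comparison, context, chromosome), sites covered
  (depth ≥ 4) in ≥ `min_accessions_per_group` (default 5) accessions of
  both groups are kept; maximal runs with adjacent gaps strictly < 300 bp
  and ≥ 8 sites are candidate blocks. Thresholds are strict exactly as
  published (> 0.4, < 0.01, < 300 bp, ≥ 8 sites).
* **Segmentation.** The per-site signal is d_i = mean_B(i) − mean_A(i) of
  group-mean levels. Binary segmentation splits at the breakpoint
  maximising the CUSUM contrast `sqrt(k(n−k)/n)·|mean_L − mean_R|`.
  Two non-obvious choices, both forced by measurement:
  * the contrast is searched over a **deterministic seeded interval
    grid** (all intervals of halving lengths with 50% overlap), because
    a single full-segment CUSUM is blind to a short DMR deep inside a
    long block — at CHH site density a block is an entire chromosome,
    and a 12-site Δ=0.25 bump in an 8,000-site block moves the
    full-block statistic by less than noise while a matched-scale
    interval scores it at ≈ 0.9;
  * recursion continues while the winning contrast ≥ `split_gain`
    (default 0.3, CUSUM scale). Any stopping rule expressed on raw
    segment means dilutes with block length (a 12-site Δ=0.5 DMR shifts
    a 241-site block's mean difference by 0.03) and stalls recursion;
    the CUSUM statistic has unit variance under noise at every scale,
    so one threshold works for 40-site and 40,000-site blocks alike.
    Under noise its maximum stays near σ_d·sqrt(2 ln n) ≈ 0.15–0.2,
    safely below 0.3, while any callable DMR scores ≥ sqrt(8)·0.2 ≈ 0.57.
  Breakpoints are unconstrained interior points; every visited segment
  with ≥ 8 sites (root, internal, leaves) is a candidate. Fragments
  below 8 sites can never be DMRs and are dropped.
* **Testing.** Per candidate, per-accession weighted methylation over
  the segment (prefix sums of depth-filtered counts); diff = mean_B −
  mean_A. Only candidates already passing the effect filter
  (|diff| > 0.4 CG/CHG, > 0.2 CHH) and the per-group accession minimum
  are tested: the filter is part of the published decision rule, so
  applying it before the test changes only the multiplicity burden,
  never the surviving set. The test is the two-sided exact
  Mann–Whitney U (identical inputs short-circuit to p = 1; groups
  > 25 fall back to the asymptotic method). Bonferroni uses the number
  of segments actually tested, recorded in the run log — testing every
  visited segment would make the denominator exceed 0.01/p_min, where
  p_min = 2/C(21,9) ≈ 6.8e-06 is the smallest achievable exact p at
  9 vs 12 replicates, and nothing could ever be significant.
* **Resolution.** Surviving segments satisfying q < 0.01 are reduced by
  greedy non-overlap selection ordered by (p, −|diff|, position), so
  nested/overlapping survivors collapse to the best-supported one while
  distinct DMRs sharing a block are all kept. direction = "increased"
  iff the selected (later) population gained methylation (diff > 0).

## Nucleotide diversity

Nei–Li π of a region is Σ over sites of the mean pairwise difference
between accessions, divided by region length in bp, so monomorphic sites
contribute zero and values are comparable across region sets. With
dosages d ∈ {0, 1, 2}, the expected difference between two individuals
is p_i + p_j − 2 p_i p_j with p = d/2 (0/1 for homozygous pairs, 0.5
when a heterozygote is involved); pairs missing a genotype are dropped
from that site's pair count. Per-site values are computed as exact
integer ratios (2(m−1)S₁ − S₁² + S₂) / (2m(m−1)) with S₁ = Σd, S₂ = Σd²,
which the test suite verifies against an all-pairs enumeration oracle.

NSR (non-selected regions) = genome minus DMRs minus DSRs, built by
interval subtraction. The 500-bp window analysis tiles each chromosome
from 0, computes |group mean difference| of weighted methylation per
window, classes windows as high (> 0.4) or low (< 0.4) — equality at
the threshold falls in neither class — and compares per-window π between
classes by Welch's t-test. The published correlation between DMR effect
size and diversity change is exposed as a report (|diff| vs π_B − π_A);
the original quantity is underspecified, and this interpretation is
flagged in the output.

## Local association

One permutation engine backs all three factor types: 1000 seeded
permutations of the factor vector's accession labels, reused across all
pairs of a run (exchangeable under the null; one cache per shared-subset
size). Vectors are mean-centred and unit-scaled over shared non-missing
accessions (≥ 10 required). Significance is exceedance: no permutation
may reach the observed |r| (two-sided via |r| so that, e.g., TE loss
with methylation gain is detectable; a `one_sided` flag restores the
signed rule). Per-test null rate is therefore ≈ 1/1001.

* siRNA: every cluster overlapping the DMR by ≥ 1 bp, Pearson on RPM.
* TE: the closest usable variant within 20 kb, point-biserial on
  presence/absence; results are summarised in five distance-quintile
  bins (fixed edges available).
* SNP: all SNPs within ± 20 kb with minor-allele count ≥ 3; a DMR is
  SNP-associated iff some SNP has zero exceedances **and** rank-p ×
  n_snps < 0.05 (per-DMR Bonferroni). Window and distance defaults are
  deliberately conservative: the rank-based permutation p is floored at
  1/1001, so windows holding ≥ 51 tested SNPs could never be significant
  under the Bonferroni rule; ± 20 kb at the simulated SNP density keeps
  expected counts below that ceiling. Both knobs are reported in output.

**Population structure caveat.** The test is structure-naive by design
(no kinship or mixed-model correction, matching the published
procedure). In a panel where allele frequencies are systematically
graded across populations, any population-contrast DMR will genuinely
correlate with many structured SNPs; the default synthetic world has
exactly that property, so its associated fraction (~0.67) exceeds what
the planted associations alone (~0.22) would give. Null calibration and
power are therefore tested on independent vectors and on planted pairs,
and pure-DMR fraction recovery on a structure-free variant
(`pi_scale` equal across populations).

Pure DMRs have no significant association of any type; genes overlapping
them feed enrichment (one-sided Fisher/hypergeometric per term, BH across
terms, significant iff k > 5 analysis genes and q < 0.05 — both strict)
and the expression correlation (Pearson of log2(FPKM+1) vs methylation,
BH across genes).

## Synthetic panel: the generative model

Defaults emulate the target study design: 9 wild, 12 landrace, 24
cultivar accessions; two 400-kb chromosomes; CG/CHG/CHH site densities
12/10/30 per kb; depth ~ Poisson(20) floored at 1; ε = 0.005.

* **Methylomes.** A site's true level is drawn once per site (methylation
  is heritable): CG bimodal (55% of sites near Beta(18,3), rest near
  Beta(1.5,30)), CHG similar with a broader methylated mode, CHH
  uniformly low (mean 0.05). Accessions add N(0, 0.05) jitter, clipped.
  Observed n_meth ~ Binomial(depth, m + (1−m)ε); methylated-cytosine
  under-conversion is folded into the mixture means rather than modelled.
* **Planted DMRs** span 12 consecutive context sites (gaps < 300 bp by
  construction, so every planted region is structurally callable); the
  per-site base level is drawn so the shifted/unshifted contrast is
  exactly Δ (0.5 for CG/CHG, 0.25 for CHH). Dos DMRs shift landraces
  *and* cultivars (domesticated lineage), Imp DMRs shift cultivars only.
  Planted regions are non-overlapping with 500-bp padding; sub-threshold
  Δ is allowed (with a warning) for null-power experiments.
* **Genotypes** are fully homozygous (selfing crop): per site a global
  alt frequency q₀ ~ U(0.1, 0.5) is scaled per population by
  `pi_scale` = 1.0 / 0.6 / 0.35 (wild / landrace / cultivar), which
  orders expected heterozygosity and hence π. SNP density 1/kb;
  inside planted CG/CHG DMRs (the high methylation-variation windows)
  the density is multiplied by `mv_mutation_multiplier` (default 2).
* **Planted associations.** Factor vectors are generated against the
  *realised* per-accession mean methylation of the planted region:
  siRNA RPM = 100 + 25·(r·z + sqrt(1−r²)·noise); TE presence and SNP
  dosage start from the best-aligned binary split of the levels and
  greedily flip labels until the realised point-biserial matches the
  target (thresholding a latent Gaussian would attenuate r ≈ 0.8 to
  ≈ 0.5 on bimodal levels). TE effects decay linearly with planted
  distance over 20 kb. Realised |r| lands within ~0.05 of target.
* **Annotation, expression, DSRs, terms** are neutral scaffolding:
  regularly spaced two-exon genes, TE mask intervals, null lognormal
  expression, random DSRs of 10–30 kb, random gene→term maps.
* One RNG stream per layer, all spawned from the master seed, so a layer
  is reproducible independently; identical seeds give byte-identical
  output trees.

What the generator does **not** emulate: linkage disequilibrium and
demographic history (sites are independent), read-level artefacts
(mapping bias, context miscalls), methylated-C under-conversion,
correlated methylation between neighbouring sites outside planted DMRs,
and realistic TE/gene architecture. A green recovery test therefore
establishes correctness of the decision rules and reasonable power under
idealised noise — not performance on real data.

## Numerical choices and degenerate inputs

* All internal coordinates are 0-based half-open; cytosine reports and
  VCF are converted at the I/O boundary only.
* Overlap criteria are ≥ 1 bp unless stated (configurable fraction).
* Composition ties go to the higher-precedence category
  (TE > exon > intron > intergenic; the TE mask supersedes gene models).
* Exceedance comparisons use |r_perm| ≥ |r_obs| − 1e-12 so that
  permutations reproducing the observed arrangement exactly count
  against significance (conservative).
* Empty inputs are values, not errors, wherever a downstream default is
  well-defined (empty methylome table → warning; uncovered region →
  missing level; no tested segments → empty DMR list with a log note).

## Known limitations

* Bonferroni over tested segments makes the DMR count mildly dependent
  on the effect-filter pass rate; the denominator is logged per run.
* The SNP association rule cannot flag DMRs in windows with ≥ 51 tested
  SNPs (permutation-p floor × Bonferroni); raise `n_perm` or shrink the
  window for dense maps.
* Exact Mann–Whitney p-values ignore tie corrections (scipy exact
  method); with heavily tied CHH levels p-values are conservative.
* π uses pairwise deletion for missing genotypes, which assumes
  missingness is independent of genotype.
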