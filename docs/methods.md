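# Methods

This note records the models behind each stage, the defaults and why they
were chosen, what the synthetic-data generator does and does not emulate,
and the numerical choices that matter when reproducing results.

## Synthetic panel

The generator (`txdiv.simulate`) draws an inbred two-subspecies panel under
the Balding–Nichols model: an ancestral allele frequency
p ~ U(0.05, 0.95) per SNP, subspecies frequencies
p_k ~ Beta(p(1−F_k)/F_k, (1−p)(1−F_k)/F_k), and haploid accession dosages
~ Bernoulli(p_k). Defaults mirror the panel layout the package targets: 35
*Indica* + 56 *Japonica* accessions, two biological replicates each, 1,000
genes, 20,000 SNPs on five 8-Mb chromosomes (a deliberately scaled-down
genome so the default run finishes in minutes), F = 0.4 per subspecies —
at which the Hudson Fst between subspecies is ≈ F, matching the strong
*Indica*/*Japonica* differentiation. Each subspecies additionally splits
into three subpopulations with F_sub = 0.15, echoing the subpopulation
structure of real rice panels. Without this nested structure,
within-subspecies genotypes would be exchangeable, the GRM would approach
the identity, and within-subspecies variance components would be
unidentifiable — no estimator could work, which is a property of the data
and not of the fitting code.

Gene architectures are drawn from a configurable mix (default 40% null,
15% DE, 10% PAV, 15% polygenic heritable, 20% cis-eQTL split
I-specific/J-specific/shared 5/5/10). Accession-level log expression has
total extra-replicate variance V = 0.25; heritable genes allocate
`target_h2` (default 0.5) of V to a 50-SNP polygenic score (rescaled so the
realized genetic fraction is exact) and the rest to an accession-stable
non-genetic effect. eQTL genes use a single cis SNP within 100 kb of the
TSS carrying `cis_h2` = 0.4 of V; for subspecies-specific classes both the
cis effect and the non-genetic accession effect are confined to the active
subspecies, so "heritable in I only" holds at the accession level. DE
genes shift the log mean by ±1 (natural log) in *Japonica* vs *Indica*;
PAV genes first draw an accession on/off state from a logistic model with
subspecies shift ±1.7 (≈ 0.3 vs 0.7 expressed fraction), the off state
producing Poisson(0.1) background counts. Replicate counts are negative
binomial with Var = μ + μ²/φ, φ = 10 by default (the replicate noise level
is not externally constrained; φ is exposed in the config, and φ = ∞ gives
the Poisson limit). Library size factors are U(0.7, 1.4). Sweeps are
injected by near-fixing (≤ 1 minor-allele copy) the target subspecies
inside declared windows.

What the generator does **not** emulate: linkage disequilibrium decay
along the chromosome (SNPs are exchangeable given the frequency model),
admixed accessions, read-level artifacts (GC, mappability), and
gene-length effects. Passing tests therefore demonstrate the estimators'
statistical behavior under the assumed covariance structure, not
robustness to alignment- or LD-driven artifacts in real data.

## Normalization and transforms

Size factors are DESeq-style median-of-ratios against a per-gene
geometric-mean reference over genes with no zero counts (falling back to
total-count ratios if none exists); expression is log2(count/s + 1). This
stand-in is monotone and variance-stabilizing in practice; the exact
spline-based VST of dedicated DE tools is intentionally not reproduced.
Mixed-model inputs are inverse-normal transformed per gene,
Φ⁻¹((rank − ½)/n), with ties permuted under a dedicated RNG stream so tie
handling never perturbs other seeded draws.

## Mixed models

All Gaussian mixed models reduce to one-dimensional profiled likelihoods
(`txdiv.lmm`):

- One-way random intercept (DE, broad H², BLUPs): with fixed effects
  constant within accession, the likelihood factors into within-accession
  sums of squares and a weighted regression of accession means, leaving
  λ = σ²_acc/σ²_e as the only free parameter (bounded Brent on log λ ∈
  [−12, 12], boundary λ = 0 checked explicitly). Balanced designs use the
  closed-form REML solution (σ̂²_e = MSW, σ̂²_acc = (MSB−MSW)/r truncated
  at 0), vectorized across genes. DE tests use ML, not REML: REML
  likelihoods are not comparable across fixed-effect structures.
- GRM model (narrow h²): G is eigendecomposed once; in the rotated basis
  every per-gene REML fit is 1-D in λ = σ²_g/σ²_e over log λ ∈ [−10, 10].
  The multi-gene path evaluates a shared 81-point grid and refines each
  gene's optimum by vectorized golden-section search; agreement with the
  scalar Brent fit is ~10⁻³ in h², and both match a dense GLS likelihood
  oracle to 10⁻⁶ on small toys. Heritabilities are truncated to [0, 1] by
  construction.

Significance: the broad-sense restricted LRT is referred to a simulated
null for the observed replicate design (closed-form and vectorized for
balanced designs) — the boundary puts roughly half the null mass at zero,
so χ² references would be badly miscalibrated. The narrow-sense LRT uses
the standard 0.5·χ²₀ + 0.5·χ²₁ boundary mixture. Both are BH-adjusted with
significance at q ≤ 0.001.

The PAV model (`txdiv.glmm`) is a random-intercept logistic regression fit
by adaptive Gauss–Hermite quadrature (9 nodes centered on each accession's
posterior mode via Newton iterations). A Gaussian ridge with variance 25
on the fixed effects — identical in full and reduced fits, with the
subspecies indicator coded ±½ so label swaps are exact symmetries — keeps
estimates finite under complete separation, which is the biologically
interesting case (genes never expressed in one subspecies). A matching
half-normal penalty on the random-intercept SD prevents the σ → ∞
degeneracy that otherwise occurs whenever replicates are perfectly
concordant within accessions (the typical PAV gene) and would collapse the
LRT to zero.

## Between-subspecies heritability differences

ΔH² (and Δh²) significance comes from permutations that partition the
pooled accessions, ignoring subspecies labels, into two disjoint groups of
size min(n_I, n_J) (35 under the default panel), recomputing heritability
in each. The two-sided empirical p uses the add-one convention,
p = (1 + #{|Δ_null| ≥ |Δ_obs|})/(B+1), so with the default B = 100 the
smallest attainable p is ≈ 0.0099, consistent with calling significance at
p < 0.01. Within-subspecies estimates subsample the larger subspecies to
the smaller's size (seeded) and re-apply the expression filter within each
subspecies.

## Joint cis-eQTL model

Per gene, candidate SNPs lie within a closed ±100 kb window of the TSS
with pooled MAF ≥ 0.10. In each subspecies separately, accession-level
expression (BLUP-shrunken, re-inverse-normal-transformed) is regressed on
the SNP with the first four genotype PCs as covariates (independent error
model across subspecies). Evidence per SNP is a Wakefield asymptotic Bayes
factor averaged over the prior-variance grid W ∈ {0.01, 0.04, 0.16, 0.64},
computed in log space.

Configuration BFs are grid-averaged at the configuration level. The
specific configurations use the single-subspecies BF with the other
subspecies at its null. The shared configuration uses a fixed-effect joint
BF — a single effect β ~ N(0, W) common to both subspecies, giving marginal
covariance diag(V_I, V_J) + W·11'. This choice is load-bearing: if the
shared BF were the product of independent BFs, "I-only" and "both" would
differ only by a null-data BF bounded below by the small-W grid terms
(≈ 0.7), the hierarchical ML over configuration weights would provably
collapse onto "shared", and no specific configuration could ever be
called. With the joint form, a precise near-zero estimate in one
subspecies actively contradicts a shared effect. A SNP with no dosage
variation within a subspecies cannot carry an eQTL there, so
configurations requiring an effect at such a SNP get zero support (the
per-subspecies BF entry itself stays at 1, flagged); this is what lets a
variant absent from one subspecies surface as a specific configuration. It
also means a panel with only one subspecies degrades exactly to a
single-population cis scan.

The hierarchical model per gene is
L_g = π0 + (1−π0)·(1/S_g)·Σ_s Σ_c w_c·BF_gsc, fit by EM (vectorized over
all gene×SNP rows; the total log-likelihood is non-decreasing and the
weights stay on the simplex). π0 is poorly identified by this likelihood —
null genes have Bayes factors with unit null expectation and carry almost
no net evidence, pulling the EM π0 to 0 — so the reported π0 is estimated
from the gene-level permutation p-values instead (Storey's
#{p > ½}/(m/2)). Gene-level significance: the averaged alternative
likelihood A_g is recomputed under B permutations of the residualized
expression, shuffled across accessions within each subspecies
independently, with hyperparameters fixed; p = (1 + #{A_perm ≥ A_obs})/(B+1),
BH across genes. Per-gene permutation streams derive from (seed, gene
index), so results are independent of execution order. A gene is called at
q ≤ 0.05 when its top SNP's best configuration posterior exceeds 0.5;
default B = 1000 (a CLI flag restores larger values). By default the scan
is restricted to genes with significant broad-sense H² (a flag disables
the pre-filter).

## Selection scan

Per called eQTL and subspecies, site-π is averaged over SNPs within
±100 kb of the top SNP. The genome-wide background tiles each chromosome
into 100 kb closed windows after removing every SNP within 100 kb of any
called eQTL and sites of low diversity under a parameterized rule (MAF
below t in at least q of k groups; two-subspecies default t = 0.1, q = 2 —
"low in both"; the multi-subpopulation variant t = 0.01, q = 10 of 12 is
the same code path). Welch's unequal-variance t-test compares eQTL-window
means against background means per (class, group) — the conservative
choice where only "a t-test" is dictated; per-eQTL flags mark windows at
or below the background's empirical 5% quantile. Note the deliberate
asymmetry, mirrored from the procedure this reimplements: the
low-diversity exclusion applies to the background only, so eQTL-window π
sits systematically below the background even without selection; the
sweep signal is therefore always read as a *contrast between groups*
(swept vs unswept subspecies), which the asymmetry cancels.

## Determinism and problem sizes

Every source of randomness derives from explicit seeds
(`numpy.random.default_rng([seed, stream])`), and the end-to-end pipeline
is byte-reproducible under a fixed seed. Default problem sizes (91
accessions, 1,000 genes, 20,000 SNPs, B = 1000 eQTL permutations, B = 100
heritability permutations, 10,000 RLRT null draws) were chosen so the full
pipeline completes in a few minutes on one CPU; all are configurable.

## Known limitations

- No LD in the generator: cis "fine-mapping" behavior (PP over SNPs) is
  easier than in real data, where LD spreads posterior mass.
- The VST stand-in is not the spline VST of DESeq2; CV values on the
  normalized (unlogged) scale are comparable across groups but not
  numerically identical to other tools'.
- Trans-eQTL are out of scope: the configuration model is cis-only.
- The EM estimates configuration weights under the uvlr (independent
  errors) assumption; correlated residuals between subspecies (shared
  batch structure) would bias shared-configuration evidence upward.
- PAV power at the default panel size is bounded by the information in a
  35-vs-56 binomial comparison; frequency differences below ~0.3 are
  usually undetectable at stringent FDR regardless of the model.
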