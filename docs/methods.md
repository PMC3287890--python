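# Methods notes

This note records the statistical model behind `burdenset`, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical conventions that matter for reproducing
results exactly.

## The two-step model

The package addresses quantitative-trait association when causal variation
is spread over many rare alleles. Step 1 reduces each gene to one (or few)
collapsed variables and produces a gene-level p-value; step 2 asks whether
a predefined set of genes is enriched for small p-values, against a null
distribution obtained by re-running the *entire* step-1 computation on
permuted phenotypes.

### Step 1: collapsing tests

Rare means sample MAF ≤ 0.01, inclusive; the threshold is a parameter
(`maf_threshold`). Minor-allele orientation is recomputed from the sample
(ties at frequency 0.5 break toward the VCF ALT allele) because the
collapsing definitions are stated on minor alleles, not on REF/ALT.
Monomorphic variants are excluded from both the rare and the common
partition: they carry no association information but would change the
weighted-sum score's normalization.

- **CMC-1 / CMC-count.** The collapsed variable (carrier indicator or
  rare-allele count) enters an OLS regression together with the gene's
  common variants, and the gene p-value is the joint F-test of all genetic
  coefficients against the intercept-only model. The joint test was chosen
  because it treats the collapsed term and the common variants as one
  multivariate genetic hypothesis; the alternative — the partial F-test of
  the collapsed term conditional on the common variants — is available via
  `cmc_test(..., joint=False)`. Constant design columns are dropped; a gene
  whose design is entirely constant (e.g. no carriers) is degenerate and
  scores p = 1 rather than being removed, so gene-set membership
  bookkeeping stays intact downstream.
- **Weighted sum.** Variant j's weight is w_j = sqrt(n_j q_j (1 − q_j))
  with q_j = (m_j + 1)/(2 n_j + 2) estimated over the whole sample with a
  pseudo-count (weights are therefore strictly positive). The original
  formulation estimates q in unaffected individuals; a quantitative trait
  has no case/control split, so the whole-sample form is used. WeightSum1's
  cross product is computed on centered s and y (location invariance);
  WeightSum2 is an ordinary slope t-test.

### Permutation machinery

One `PermutationPlan` — B random bijections of the sample indices from a
seeded PCG64 generator — is shared by all genes and all tests of one
analysis. Sharing is essential: the set-level null must preserve gene–gene
correlation, which independent per-gene permutations would destroy.
Permutation p-values use the add-one estimator (r + 1)/(B + 1), which can
never be zero; for an exhaustive plan (all n! permutations, identity
included) the exact enumeration p-value r/B is reported instead, since the
identity guarantees r ≥ 1.

Tie handling: permuted statistics within 1e-12 (relative) of the observed
one count as ties. Collapsed genotype scores repeat across individuals, so
exact mathematical ties are common, and BLAS versus scalar accumulation can
split them by one ulp; counting near-ties as ≥ is the conservative,
validity-preserving convention.

The batched engine (`Step1Engine`) exploits that genotypes are fixed across
permutations and replicates: each gene's centered design is reduced once to
an orthonormal basis (SVD with a rank tolerance of max(n, k)·eps·σ_max,
which absorbs duplicate and constant columns), and the explained sum of
squares for *all* permuted phenotype columns is then one matrix product.
F statistics and p-values follow analytically; analytic p-values are
floored at 1e-300. WeightSum1 has no analytic reference distribution, so
its per-column p-values are pooled ranks: each column's statistic is ranked
against all B + 1 columns, which makes observed and permuted p-values
exchangeable by construction.

### Step 2: enrichment

Gene scores are −log10(p), applied identically to the observed and each
permuted p-value (the transform is monotone in significance; the
permutation floor 1/(B+1) bounds the scores). Ranking ties are broken by
gene id, so reruns are bit-identical. The running sum uses the weighted
increment |score|^α / N_R at members (α = 1 default, α = 0 gives the
classical KS statistic; if all member weights are zero the hit increments
fall back to the unweighted form). The p-value is one-sided — enrichment
only — because the scientific hypothesis is concentration of association
signal, not depletion. A gene-resampling null (`null="geneset"`) is
provided as an alternative to the phenotype-permutation null; the
permutation null is primary because it preserves inter-gene correlation.

**VSEA adjustment.** Each gene's observed and permuted scores are
standardized by that gene's own permutation mean and SD (ddof = 1; the
adjustment is idempotent). Genes with numerically constant permutation
scores (SD at round-off scale) get adjusted scores of 0 and a degeneracy
flag. The adjustment is first-two-moments standardization; empirical
quantile normalization would be a drop-in alternative at the same hook but
is not implemented. B ≥ 10 is required — below that the moment estimates
are too unstable to be meaningful.

A note on when VSEA helps: if gene scores are −log10 of well-calibrated
p-values, all genes share one null score distribution and the adjustment is
close to a no-op. Heterogeneity — and VSEA's advantage — enters through
(i) discreteness: a small rare-variant gene has few distinct carrier
configurations, so its observed score is capped well below what large genes
reach by chance, and (ii) miscalibration: under a signal-bearing
(non-normal) trait, normal-theory p-values of low-carrier-count genes drift
from uniformity. In simulations with signal concentrated in small genes and
noise in large ones, VSEA's power exceeded GSEA's by 0.06–0.22 across
effect sizes and seeds (see `tests/test_acceptance.py`).

### Spurious-gene filter

A non-risk gene significant (strictly p < α) in at least k of R phenotype
replicates is flagged. k is not hard-coded: `default_min_hits` returns the
smallest k with P(Bin(R, α) ≥ k) ≤ 0.05, which yields k = 16 at R = 200,
α = 0.05 (implied tail probability 0.0444). Risk genes are never flagged.
Exclusion removes the gene columns from panels, maps and matrices and
shrinks gene sets by their excluded members; a set emptied entirely is
treated as unable to reject (p = 1) in the harness.

## The synthetic-data generator

What it emulates: a mini-exome association study — 697 unrelated
individuals, hundreds of genes of heterogeneous size (log-uniform between 1
and 60 variants by default; small genes dominate, as in exome panels), a
rare/common MAF mixture (75% rare, rare MAFs log-uniform on
[0.001, 0.01] because rare site frequencies skew toward the rarest classes,
common MAFs uniform on [0.011, 0.4]), an additive quantitative trait, and
many phenotype replicates over one fixed genotype draw. The preset
(`mini_exome_preset`) scales the gene count to 300 and designates 13 causal
genes with heritability shares geomspaced from 0.004 to 0.045 — chosen so
single-gene detection power spans roughly the full range at n = 697; these
effects are illustrative, not calibrated to any dataset — plus 25
replicates and 5 confounded gene pairs (ρ = 0.8) linking non-causal genes
to the strongest causal genes.

Mechanisms:

- Genotypes are Hardy–Weinberg, dosage ~ Binomial(2, MAF), independent
  across variants. Confounded pairs instead draw each allele through a
  Gaussian copula: both allele indicators of every variant in either gene
  load on the pair's shared standard-normal latent factor with loading
  sqrt(ρ), thresholds set to keep each marginal MAF exact. This produces
  the long-distance cross-gene correlation that makes the non-causal
  partner "spurious" downstream (carrier-indicator correlation > 0.5 at
  ρ = 0.9), and incidentally some within-gene correlation, which is
  harmless to the collapsing tests.
- Causal genes are conditioned on being polymorphic (redrawn if no minor
  allele is observed): a gene invisible in the sample could not have been
  designated a risk gene.
- The trait is y = Σ_g sqrt(h²_g) · b̃_g + ε, where b̃_g is the gene's
  standardized additive burden (equal weights over its rare variants by
  default; explicit per-variant effects are supported) and
  ε ~ N(0, 1 − Σ h²_g), redrawn independently per replicate. Heritability
  shares are therefore exact in-sample by construction.

What it does **not** emulate: linkage disequilibrium within genes (beyond
the confounder side effect), population or family structure, genotyping
error or missingness patterns, non-normal trait residuals, and any
particular real dataset's effect sizes. Consequently, passing the
nominal-level tests here shows the permutation machinery is correct under
clean exchangeability; it does not certify behavior under cryptic
structure, which the method does not attempt to correct.

## Evaluation design

The harness mirrors the canonical design: a base risk set; perturbed sets
with 5/10/15/20 random noise genes added or risk genes removed; one
reference set of genes causal only for an independent second trait (an
independent trait never enters the analyzed trait's likelihood, so the
reference set is simulated as a designated disjoint gene group); and 200
random null sets of sizes 3–64 for the set-level FPR. Rates are means over
replicates of the fraction of p-values strictly below α = 0.05, with
SE = sqrt(rate(1 − rate)/R). Noise genes are re-randomized per replicate
and drawn *nested* across levels within a replicate (one pool of 20, each
level a prefix), so power comparisons across noise levels are paired.

Problem sizes in the test suite and acceptance script (500 genes × 697
individuals × 1,999 permutations × 40 replicates for the global-null FPR;
300 × 697 × 499 × 200 for the reference-set rate; 80 × 400 × 199 × 120 for
the ordering comparisons) were chosen to keep each run in the seconds-to-
minutes range on a single CPU while leaving Monte-Carlo error small
relative to the effects being asserted. The reference-set rate spreads its
200 replicates over 4 independent genotype draws: replicates over one draw
share the trait's fixed genetic component, so a single-draw estimate is
dominated by that draw's chance correlations between reference-gene
burdens and the genetic component, whereas the ensemble average estimates
the method's unconditional rate.

A discreteness note: with B permutations, permutation p-values live on
{1/(B+1), …, 1}, so the strict rejection rule p < 0.05 has null expectation
⌊0.05(B+1) − 1⌋-ish rather than 0.05 exactly — 0.045 at B = 199, 0.0495 at
B = 1999. The acceptance script uses B = 1,999 (the 2,000-permutation
setting of the reference design) so the measured FPR reflects the method
rather than estimator granularity.

## Known limitations

- No covariates, no binary traits (the case-control Hotelling-type CMC and
  the rank-sum weighted-sum forms are out of scope), no family data.
- No multiple-testing correction across gene sets; rates are per-set.
- The VSEA adjustment uses two moments; heavy-tailed score nulls with equal
  mean/SD would pass through it unchanged.
- Population-structure confounding is not modeled or corrected; the
  spurious-gene filter only addresses replicate-stable long-distance
  correlation, and requires many phenotype replicates, which real studies
  rarely have (it is an evaluation tool more than a field tool).
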