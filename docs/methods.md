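# Methods

## Generative model

Each simulated family is a father–mother–offspring trio observed at two
unlinked diallelic loci: G (alleles A/a), the instrument, and H (alleles
B/b), a heritable confounder.  Genotypes are stored as reference-allele
dosages 0/1/2 and enter the phenotype models through the additive coding
f_A (allele count) and the dominance coding f_D (1 for a heterozygote, 0 for
a homozygote).  For every individual,

    X = β1 + β_GA^X f_A(G) + β_GD^X f_D(G) + β_HA^X f_A(H) + β_HD^X f_D(H)
        + β_U^X U + ε_X
    Y = β2 + β_XY X + β_HA^Y f_A(H) + β_HD^Y f_D(H) + β_U^Y U + ε_Y

with U ~ N(0, σ²_U) a non-genetic confounder and ε_X, ε_Y independent
Gaussian noise.  Founder genotypes are drawn under Hardy–Weinberg
equilibrium (dosage ~ Binomial(2, q)); offspring genotypes are Mendelian
transmissions, one allele drawn at random from each parent, loci independent
(unlinked, no recombination model needed).

Two scenarios:

* **sim1-assortative.** One population of n couples.  A fraction
  `p_assort` of mothers and of fathers is selected uniformly at random; the
  selected sets are each sorted by exposure X and paired rank-to-rank
  (positive assortative mating on the exposure); the remainder is paired
  uniformly at random.  Exactly round(p·n) couples are assortative; ties in
  the sort have probability zero under continuous X.
* **sim2-stratified.** Two independent random-mating subpopulations
  (`p_assort` must be 0, enforced), identical except for allele frequencies,
  pooled and analysed while ignoring the subpopulation label.

Both mechanisms associate the unlinked loci in the pooled offspring
generation (measured here as a positive correlation of genotype codings
between G and H), which is precisely an instrument–confounder association.

## Default parameters

| parameter | default | meaning |
|---|---|---|
| freq_A, freq_B | 0.1 | reference-allele frequencies (subpopulation 2 sweeps 0.1–0.9) |
| β1, β2 | 0 | intercepts; they shift scales only and cannot affect error rates or bias in these linear models |
| β_GA^X, β_HA^X, β_HA^Y | 0 | no additive genetic effects |
| β_GD^X, β_HD^X, β_HD^Y | 1 | strong dominance effects of both loci on every affected trait |
| β_U^X, β_U^Y | 1 | confounder effects |
| σ²_U, σ²_εX, σ²_εY | 0.1 | variances (N(0, 0.1) is read as variance 0.1, i.e. SD √0.1 ≈ 0.316, the standard N(μ, σ²) convention) |
| β_XY | 0 (null runs) / 1.0 (effect runs) | causal effect of X on Y |
| p_assort | scenario sweep, reference point 0.8 | fraction of couples paired by exposure rank |
| n_trios | 1,000 (sim1) / 500 per subpopulation (sim2) | families per dataset |

The dominance-driven configuration is the interesting one: with purely
additive effects, conditioning on parental allele counts already blocks the
confounding path, and the mating-type and parental-genotype adjustments
agree (the additive adjustment is nested in the saturated mating-type one —
this nesting is verified by a test).  The X equation carries H terms
(β_HA^X, β_HD^X) because the confounder locus affects the exposure as well
as the outcome; setting them to 0 recovers the simpler model in which H
touches Y only.

The offspring confounder is a fresh draw by default (U is non-genetic, hence
non-transmissible).  A parent–offspring correlation ρ is available
(`rho_u_parent_offspring`, |ρ| ≤ 1/√2): the offspring confounder is
ρ(U_m + U_f) + √(σ²_U(1 − 2ρ²))·z, which gives correlation ρ with each
parent and variance σ²_U exactly when the parental confounders are
uncorrelated.  The two *parental* confounders are always drawn
independently: under assortative pairing the couples are formed by sorting
on X after U is realised, so a structural spousal-U correlation parameter
would have no coherent meaning in this generative ordering — the realised
spousal U correlation at p_assort > 0 is an endogenous consequence of
matching on X.

## Estimators

All three estimators use only the offspring's X and Y; parents contribute
genotypes (never phenotypes).  Stage 1 regresses X on the instrument codings
[1, f_A(G), f_D(G)] plus the method's conditioning set; stage 2 regresses Y
on [1, X̂] plus the *same* conditioning set with freely re-estimated
coefficients (carrying stage-1 covariate coefficients into stage 2 would
leave outcome-scale confounding unadjusted, defeating the purpose of
conditioning).  The conditioning sets are: nothing (conventional); f_A and
f_D of each parental genotype (parental_genotype); five reference-coded
indicators of the parental mating type with aa/aa as reference
(mating_type).  The mating type is canonicalised by sorting the parental
dosages, so mother/father exchange is structurally irrelevant.

Inference on the X̂ coefficient uses plain OLS standard errors treating X̂
as fixed, with t degrees of freedom n − (retained stage-2 columns).  This is
the convention under which sequential two-stage regressions are usually run,
and the nominal-level results below are obtained under it; a 2SLS-style
corrected standard error (structural residuals evaluated at the observed X)
is available via `se_method="2sls"`.

## Numerical conventions

* Rank handling: column-pivoted QR; columns whose pivot falls below 1e-8
  times the largest pivot are dropped, reported by name in
  `dropped_columns`, and excluded from inference.  Mating-type categories
  absent from a finite sample (e.g. AA/AA at allele frequency 0.1 with
  1,000 families) are therefore dropped explicitly rather than merged.
* If both instrument codings f_A(G) and f_D(G) are aliased with the
  conditioning set (monomorphic locus, or no mating type within which the
  offspring genotype segregates), the fit raises a degenerate-instrument
  error instead of returning an unidentified estimate.
* Exact fits (zero residual variance) report se = 0 and a p-value of 0 for
  a nonzero estimate; this occurs only in deterministic test
  configurations.
* Monte-Carlo runs use replicate seed = base_seed + replicate index, with
  sweep points offset by 10^6 so replicate streams never overlap.
  Degenerate replicates are counted and excluded, never redrawn (redrawing
  would bias the null distribution); a run aborts if more than 10% of
  replicates are degenerate for any estimator.

## Study sizes

The reference study uses 1,000 families per dataset and 1,000 replicates
per null cell (binomial 99% CI half-width ≈ 0.018 around 0.05), and 200
replicates per effect-mode cell with agreement judged within 4 Monte-Carlo
standard errors of the mean estimate.  The assortative sweep uses
p ∈ {0, 0.1, …, 0.8} and the stratification sweep varies the
subpopulation-2 frequency over {0.1, …, 0.9} (both loci jointly); the test
suite spot-checks the grid at {0, 0.4, 0.8} and {0.1, 0.5, 0.9}
respectively, with 400-replicate cells at the intermediate points, to keep
the default run fast.  Type-I error inflation under stratification peaks at
the intermediate frequency 0.5 because homozygotes were assigned equal
phenotypic effects, making the dominance contrast largest there.

## What the simulator does and does not emulate

It emulates: Hardy–Weinberg founders, Mendelian segregation, single-trait
positive assortative mating by exposure rank, two-way admixture, additive
plus dominance single-locus effects, and a continuous non-genetic
confounder.  It does not emulate: linkage or recombination between the
loci, multi-allelic or X-linked variation, cross-trait or multigenerational
assortment, more than two subpopulations, epistasis, selection/collider
sampling on the exposure, or measurement error in phenotypes.  Passing
tests therefore show that the estimators behave as claimed under this
generative model — they do not certify behaviour under, e.g., selection
bias, where conditioning on mating types cannot repair a G–U association
involving a non-heritable confounder.

## Known limitations

* Standard errors are naive two-stage OLS by default (see above); weak-
  instrument diagnostics beyond rank checks are out of scope.
* The estimators are one-sample, individual-level; summary-statistic
  (two-sample) MR and the non-transmitted-allele-score design are out of
  scope.
* Rare mating-type categories are dropped, not merged; with very small
  samples and extreme frequencies this can leave the instrument
  unidentified (reported as a degenerate fit).
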