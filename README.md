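# triomr

Trio-based Mendelian randomization (MR) with conditioning on parental
mating types.

## The problem

MR uses a genetic variant *G* as an instrumental variable for an exposure *X*
to estimate the causal effect β_XY of *X* on an outcome *Y*.  Its validity
rests on the instrument being unassociated with confounders.  That assumption
fails in two entirely ordinary situations, even for unlinked loci:

* **Assortative mating** — if couples match on the exposure, the instrument
  locus *G* becomes associated with a second, heritable confounder locus *H*
  across generations.
* **Population stratification** — pooling subpopulations with different
  allele frequencies associates *G* and *H* without any linkage.

Either mechanism creates gametic-phase disequilibrium between *G* and *H*,
and conventional two-stage MR then rejects true null hypotheses far too often
and returns biased estimates.

`triomr` is for biostatisticians and genetic epidemiologists who want to
study, demonstrate, or guard against this failure mode.  It provides:

1. a simulator of father–mother–offspring trio populations under both
   mechanisms, with additive (f_A: allele count) and dominance
   (f_D: heterozygosity) genetic effects on the phenotypes;
2. three two-stage estimators of β_XY on trio data —
   * **conventional**: stage 1 regresses X on [1, f_A(G), f_D(G)]; stage 2
     regresses Y on [1, X̂];
   * **parental_genotype**: both stages additionally condition on
     f_A and f_D of each parent's genotype (the allele-score adjustment);
   * **mating_type**: both stages additionally condition on indicators of the
     parental *mating type* P — the unordered pair of parental genotypes,
     six categories with aa/aa as reference.  Because P is a saturated
     encoding of the parental genotype pair, this conditioning blocks the
     G–H path even when genetic effects are non-additive, where the
     allele-score adjustment only partially helps;
3. a Monte-Carlo harness measuring empirical type-I error (null runs,
   α = 0.05) and bias E[β̂_XY] − β_XY (effect runs, generative β_XY = 1.0)
   across scenario sweeps, with Monte-Carlo standard errors.

## Worked example

Simulate 1,000 trios with 80% of couples rank-matched on exposure and a
**zero** true causal effect, then fit all three estimators:

```python
from triomr import simulate_scenario, fit_all

data = simulate_scenario("sim1-assortative", seed=11, beta_xy=0.0, p_assort=0.8)
for method, fit in fit_all(data).items():
    print(f"{method:18s} beta_xy_hat={fit.beta_xy_hat:+.4f}  se={fit.se:.4f}  p={fit.p_value:.4f}")
```

```
conventional       beta_xy_hat=+0.1016  se=0.0412  p=0.0138
parental_genotype  beta_xy_hat=+0.0640  se=0.0564  p=0.2569
mating_type        beta_xy_hat=+0.0179  se=0.0650  p=0.7830
```

The true effect is 0.  Conventional MR reports a significant spurious effect
(p = 0.014), the parental-genotype adjustment shrinks it, and the mating-type
adjustment is closest to zero and clearly non-significant.  Across 1,000 such
replicates the pattern is systematic: conventional MR rejects at rate ≈ 0.5
instead of 0.05, while mating-type MR stays at the nominal level.

The same study is available from the shell:

```sh
triomr simulate --scenario sim1-assortative --p-assort 0.8 --n-trios 1000 \
    --seed 7 --out trios.csv
triomr fit --input trios.csv --out fits.csv
triomr experiment --scenario sim1-assortative --mode type1 \
    --n-reps 1000 --seed 1 --out-dir results/ --plot
```

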