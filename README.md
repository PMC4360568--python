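# genload

Models of the **genomic load of heterozygous deleterious mutations** and its
consequences for death in infancy and childhood, built for population
geneticists and researchers in sudden unexpected death in infancy (SUDI) who
want the arithmetic of the load model as tested, reusable code rather than a
back-of-envelope calculation.

## The model

Write *M* for the mean number of heterozygous deleterious mutations in an
adult diploid germ line and *N* for the mean number of new deleterious
mutations arising in gametogenesis and transmitted per zygote. Random
assortment in meiosis makes the zygote load *k* Poisson-distributed:

    k ~ Poisson(M + N)

For *M* to stay in single figures over thousands of generations, selection
must remove the input *N* each generation, acting against zygotes at the
upper end of the distribution. `genload` provides both views of that
selection:

* **Analytic truncation** (`core_model`): the unique threshold *k\** and
  boundary acceptance fraction for which the survivor mean returns exactly
  to *M*, plus the resulting zygote-loss fraction and the post-selection
  adult distribution.
* **Synergistic multi-system simulation** (`meiosis_simulator`): the genome
  partitioned into essential genetic systems; four deleterious mutations in
  one system are lethal at conception, three or two carry graded risks of
  postnatal death. A forward-in-time population simulator shows the mean
  adult load equilibrating under these tiers.

Around the core sit three estimators and a calculator:

* **Consanguinity** (`consanguinity`): a heterozygous allele in a shared
  grandparent is autozygous in a first-cousin couple's child with
  probability (1/2)⁶, so the expected autozygous load is *M*/32 and the
  recessive-disease fraction is D = 1 − exp(−*M*/32); inverting at D = 0.10
  gives M̂ = −32·ln(0.9) ≈ 3.37.
* **X-linked risk** (`x_linked_risk`): attributing the 3:2 male:female SUDI
  death ratio to X-linked carriers with relative risk RR and non-carrier
  males at the female baseline gives carrier prevalence
  p = (1.5 − 1)/(RR − 1) and case carrier fraction RR·p/1.5.
* **Neutral drift and clock** (`neutral_drift`): critical Galton–Watson
  simulation of a new neutral mutation (survival ≈ 2/n, copies ≈ n/2 given
  survival) and the divergence clock (1 base in 300 ÷ 100 new changes per
  generation ≈ 100,000 generations ≈ 2.5 million years).
* **Synthetic cohorts** (`synthetic_data`): seeded generators for Poisson
  populations, gene-dropped first-cousin offspring and X-linked
  case/control cohorts, used to validate every estimator by parameter
  recovery.

## Worked example

The X-linked carrier table — what fraction of male SUDI cases and of
control males would carry a deleterious X mutation, for candidate relative
risks, if the male excess is entirely X-linked:

```console
$ genload xrisk --ratio 1.5 --rr 3 --rr 6 --rr 11
# version: 0.1.0
# sex_ratio: 1.5
# rr: [3.0, 6.0, 11.0]
rr	pct_cases	pct_controls
3.0	50	25
6.0	40	10
11.0	37	5
```

Reading the first row: if carrier males die at 3× the non-carrier rate, a
quarter of all males must be carriers to produce the observed 3:2 sex
ratio, and half of male SUDI cases would carry such a mutation.

The truncation-selection equilibrium at the default M = 7, N = 1:

```console
$ genload equilibrium --m 7 --n 1
{
  "k_star": 10,
  "accept_at_k_star": 0.9268144766489693,
  "loss_fraction": 0.19137871474354007,
  "mean_zygote": 8.0,
  "mean_adult": 7.0,
  ...
}
```

Zygotes with more than 10 deleterious mutations (and ~7% of those with
exactly 10) fail to develop — 19.1% of all conceptions — returning the
adult mean to 7. Richer synergistic-selection models place the total loss
nearer 30%; the forward simulator (`genload simulate`) explores that
regime, reporting conception-stage and postnatal losses separately.

Estimating the load from cousin-marriage outcomes (≤10% of first-cousin
offspring with recessive disease):

```console
$ genload cousin --disease-fraction 0.10
{
  "M_hat": 3.371536501050441,
  "expected_autozygous_load": 0.10536051565782628,
  "model": "poisson",
  ...
}
```

## Documentation

`docs/methods.md` describes the model assumptions, the free parameters and
their defaults, what the synthetic-data generators do and do not emulate,
and the numerical choices made in the solver and simulator.
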