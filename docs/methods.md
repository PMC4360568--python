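# Methods

## The load model and its assumptions

The unit of the model is a *count* of heterozygous deleterious mutations in
conserved, functioning genes — no per-gene identity, no DNA sequence.
Three assumptions carry everything:

1. **Poisson zygote load.** Meiosis assorts mutations independently, so
   with adult mean M and fresh input N the zygote load is Poisson(M + N).
   This ignores linkage (two deleterious mutations on one chromosome are
   not transmitted independently) and any correlation between parental
   loads from assortative mating.
2. **Stationarity.** M does not change across generations, so selection
   removes exactly N per zygote per generation on average.
3. **Selection acts on the upper tail.** Either as hard truncation (the
   analytic solver) or through per-system synergy tiers (the simulator).

### Parameters

| parameter | meaning | default | why |
|---|---|---|---|
| M | mean deleterious mutations, adult diploid germ line | 7 | upper end of the published single-figure range |
| N | new deleterious mutations per zygote | 1 | midpoint of the 0.5–1.5 range |
| L_haploid | conserved genes per haploid set | 20,000 | current consensus gene count |
| genome_bp_diploid | diploid genome size | 6×10⁹ bp | |
| mu_per_bp_div | mutation rate per bp per mitotic division | 5×10⁻¹⁰ | germ-line per-division rate |
| x_fraction_haploid | X share of the haploid genome | 0.05 | ~1000 of 20,000 genes |
| generation_years | years per generation | 25 | forced by the clock's printed 100,000 generations ↔ 2.5 My |

All loads (M, N) are diploid-genome counts; diploid statements such as
"40,000 functioning genes" are 2·L_haploid.

## Truncation equilibrium (core_model)

Survivors are all zygotes with load k < k\* plus a fraction *a* of those
with k = k\*; *a* solves the conditional-mean equation in closed form,

    a = (M·S − m) / (p_{k*} (k* − M)),   S = Σ_{k<k*} p_k,  m = Σ_{k<k*} k p_k,

and k\* is the unique threshold for which a ∈ [0, 1]. The pmf support is
auto-extended until the Poisson tail mass is below 10⁻¹⁴ and renormalised,
so distributions sum to 1 within 10⁻¹²; the solver tolerance on the
post-selection mean is 10⁻⁹. At M = 7, N = 1 this gives k\* = 10,
a ≈ 0.927, and a zygote loss of ≈ 0.191.

Hard truncation is the *minimal* scheme consistent with selection on the
upper tail. Published synergy models of the same process lose of the order
of 30% of zygotes — a graded scheme spreads the removal over more of the
distribution and must cull more in total to achieve the same survivor
mean. The package reports the truncation figure as its analytic result and
leaves the graded regime to the simulator; the two are deliberately not
forced to agree.

The X share of the diploid load is M·x_fraction/2 = M/40 at defaults. An
optional `male_viability_factor` (default 1.0, i.e. no discount) scales
this down for X alleles that are lethal in males and hence depleted among
live-born males.

## Forward synergy simulator (meiosis_simulator)

Default architecture: 10 equal essential systems of 2,000 genes. The tiers
are: ≥ 4 mutations in any essential system → loss at conception; a maximum
essential-system count of 3 → postnatal death with probability q3 = 0.3;
2 → q2 = 0.05; ≤ 1 → no excess risk. q3 and q2 are free parameters fixed
once as documented defaults — the model constrains only their ordering —
and `sweep_loss_fraction` (and the CLI's `--q3/--q2` flags) exists to
explore sensitivity.

Implementation choices:

* Transmission is binomial thinning with probability 1/2 per system; new
  mutations are added per system as independent Poisson(N·wᵢ) with wᵢ the
  system's share of genes — by Poisson splitting this is identical in
  distribution to assigning a single Poisson(N) total multinomially, and
  it vectorises. The scalar `form_zygote` keeps the literal multinomial
  form.
* Mating is random pairing with replacement; regulation is sampling
  survivors back to the fixed population size without replacement.
* New and inherited mutations are exchangeable; homozygosity is not
  tracked (that is the consanguinity module's job). The X-linked count is
  a Poisson(M/40) side-channel that does not feed selection.
* One seeded `numpy` Generator per run; identical seeds give bit-identical
  series. Extinction raises an error carrying the partial series.
* Conception-stage loss and postnatal death are reported separately,
  because the model does not fix how the total loss divides between them.

Equilibrium summaries average the final third of a run and attach
Monte-Carlo standard errors. The validation runs use a population of 5,000
for 200 generations (stationarity is already clear at that scale; the
suite also uses smaller runs of 500–2,000 individuals where only
reproducibility or boundedness is at stake).

## Neutral drift and clock (neutral_drift)

A new neutral mutation's copy number is a critical Galton–Watson process.
Default offspring law: Poisson with mean 1 (stable population), variance
σ² = 1, for which survival to generation n is ≈ 2/(σ²n) = 2/n and the copy
number given survival ≈ n/2. The two-children quartet argument
(25%/50%/25% of 0/1/2 copies transmitted) corresponds to Binomial(2, ½)
offspring, available via `offspring="binomial2"`; its σ² = ½ doubles the
asymptotic survival to 4/n. Estimates carry binomial/sample standard
errors; `branching_survival_profile` evaluates several horizons on common
lineages so the monotonicity of survival in n is preserved exactly.

Clock arithmetic is exact at the defaults: 5×10⁻¹⁰ × 6×10⁹ = 3 miscopies
per division; 3 × (40 + 60) / 2 = 150 new base changes per zygote (the ½
is haploid transmission of each parental germ line's diploid miscopies —
our stated convention, consistent with "over 100"); divergence is compared
between two homologous haploid strands, so (1/300 × 3×10⁹) / 100 = 10⁵
generations, i.e. 2.5 My at 25 years per generation. Indels are not
counted in the divergence density.

## Consanguinity (consanguinity)

The per-allele autozygosity probability is computed by exhaustive
enumeration of all fair-coin meiosis outcomes on the two descent chains —
(1/2)⁶ = 1/64 for first cousins, (1/2)⁴ for sibling matings — rather than
quoted. With two shared grandparents each carrying M alleles the expected
autozygous load is M/32, consistent with the kinship identity
F·(M/2) = M/32 at F = 1/16. Autozygous loci are treated as a Poisson
count (independent rare alleles), giving D = 1 − e^(−M/32) and the
estimator M̂ = −32·ln(1 − D); the linear small-M form M/32 is also exposed
via `expected_autozygous_load`. Penetrance defaults to 1 ("disease" = at
least one autozygous deleterious locus) and is configurable. New
mutations in the cousins' own gametes are ignored — they cannot be
identical by descent. Note the simple inversion at D = 0.10 gives
M̂ ≈ 3.37, smaller than the 4–8 range obtained by richer
simultaneous-equation models under a 30,000-gene assumption; both readings
are reported and not reconciled.

## X-linked risk (x_linked_risk)

The attribution model — stated prominently because everything follows from
it — is that **non-carrier males have the female baseline hazard**, so the
entire male excess (sex ratio ρ = 1.5) is carried by X-linked carriers:
1 + p(RR − 1) = ρ. RR is read as a risk ratio; the table reproduces
cell-for-cell under that reading. Display rounding is to the nearest whole
percent (36.67 → 37) with raw values retained. On case/control data the
carrier-status odds ratio equals RR under this model, so `estimate_rr`
uses the 2×2 odds ratio with a Woolf log-scale CI (Haldane–Anscombe 0.5
correction for empty cells).

## Synthetic data: what it does and does not emulate

The generators produce exactly the processes the estimators assume:
Poisson loads, fair-coin meioses, carrier rates from the attribution
algebra (calling the x_linked_risk functions — one source of truth). They
do **not** emulate linkage, assortative mating, variable penetrance,
diagnostic misclassification, or population stratification. Passing the
parameter-recovery tests therefore shows the estimators are correct *under
the model's own assumptions*, not that real cohorts satisfy those
assumptions. Every cohort echoes its full generator parameters and seed
in a commented TSV header and can be regenerated bit-identically.

## Known limitations

* No per-gene identity: dominance, variable selection coefficients and
  allelic heterogeneity are outside the model.
* The ~30% zygote-loss figure of graded-synergy models is not an output of
  the analytic truncation solver (which gives ≈19% at M = 7, N = 1); the
  simulator's loss depends on the free q2/q3 tiers and is reported with
  sweeps rather than as a single point value.
* The X-linked attribution is an upper-bound construction: any non-genetic
  contribution to the male excess lowers the implied carrier prevalence.
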