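# Methods

## The lethal-equivalents model

The package models hatching failure of inbred eggs as the expression
of fully recessive lethal alleles. The number of lethal equivalents
carried per haploid maternal genome is a Poisson random variable with
mean `B`; an offspring with inbreeding coefficient `F` makes each of
them homozygous (hence expressed) independently with probability `F`.
The number of expressed lethals is therefore Poisson with mean `B·F`
and the probability that an egg escapes them all is

    h(B, F) = exp(−B·F).

`h` is a *relative* hatching rate: every egg also passes a baseline
viability filter shared across treatments, which cancels when a
treatment's pooled hatch rate is divided by the outbred rate. The
three reproduction treatments fix `F`: outbred crosses 0, full-sib
crosses 1/4, automictic (endomitotic) parthenogenesis 1, because
endomitotic restoration of diploidy duplicates a single meiotic
product and yields complete homozygosity.

Inversion at an observed parthenogenetic relative hatching `r` gives
`B̂ = −ln(r)/F = −ln(r)`. Two boundary rules keep the estimator total:
`r = 0` maps to `B̂ = +∞` (serialized as the literal `inf` in
reports), and `r ≥ 1` — possible through sampling noise, since
observed inbred/outbred ratios near or above 1 do occur — is clamped
to `B̂ = 0` and flagged rather than raised. `F = 0` is rejected: load
is not identifiable from non-inbred offspring.

The model deliberately ignores sub-lethal (detrimental) equivalents,
age-structured selection and epistasis; `B` is an early-acting,
egg-stage summary of load.

## Observed rates, pooling and the bootstrap

The pooled hatch rate of a treatment is total hatched over total eggs
across pods (each egg weighted equally), not the mean of per-pod
rates; pods differ several-fold in egg number and per-pod averaging
would overweight small pods. Because the weighting convention is a
genuine analysis choice, a `per_female` option (mean of per-female
pooled rates) is exposed throughout. Both pod ranks enter the pooled
rates.

Uncertainty in `B̂` is quantified by a pod-level nonparametric
bootstrap: pods are resampled with replacement within each of the two
treatments, the pooled relative hatching and `B` are recomputed per
replicate, and the 2.5%/97.5% percentiles form the interval.
Replicates in which the reference (outbred) sample has zero
hatchlings, or either sample zero eggs, leave the ratio undefined;
they are discarded and counted, and more than 50% discarded aborts
with an error rather than returning a meaningless interval. When
replicates contain infinite `B` (zero focal hatchlings) the interval
endpoints use nearest-order-statistic quantiles, since interpolation
across +∞ is undefined. The per-population prediction interval for
the inbred relative hatching is the `B` interval mapped through the
monotone `exp(−B/4)`; an observed inbred value outside it raises the
report's discrepancy flag, which operationalizes the qualitative
"observed higher than predicted" comparison.

## The synthetic experiment

`synthetic_data.simulate_experiment` generates the three-treatment
breeding design the analysis assumes: per population, `n_families`
full-sib families each contribute `females_per_family_per_treatment`
females to every treatment; a female lays with a treatment-specific
probability and produces up to two pods whose egg numbers are Poisson
with rank-dependent means (first pods larger, matching the observed
rank effect; a negative-binomial switch provides overdispersion since
the true egg-number distribution is not known). Each egg hatches if a
baseline Bernoulli (`baseline_hatch`) succeeds *and* an explicit
mechanistic draw expresses no lethal: `k ~ Poisson(B)` lethals, each
expressed with probability `F`. The closed form `exp(−B·F)` is never
used by the generator — this keeps the simulator an independent
oracle for the analytical model rather than a restatement of it.
Hatchlings survive 24 h with a treatment-specific probability; up to
`max_offspring_per_pod` (default 15, the rearing cap of this kind of
design) survivors per pod become offspring records with Gaussian
development time and femur length shifted by treatment, a sex effect
on femur length, an extra-molt indicator that delays development, and
a larval survival draw that determines whether development time is
observed. Offspring are reared only for the outbred and inbred
treatments by default (the usual design restriction); a switch
includes parthenogenetic survivors.

Numeric defaults the design does not pin down were fixed once at
field-realistic values and documented here: baseline hatch 0.75,
laying probability 0.9 for mated females vs 0.45 for virgin females,
24-h survival 0.92 vs 0.5 (parthenogenetic hatchlings fare much
worse), pod means 65/50 eggs, development 32 ± 3 days, femur
22 ± 1 mm with a +2 mm female bonus. The bundled four-population
design uses loads of 1.1, 3.8, 3.9 and 3.9 lethal equivalents, and
its field-derived population gets a parthenogenetic laying
probability of 0.02 to emulate experiments where virgin females yield
no scorable pods.

Limitations the generator does not model: maternal sharing of load
(lethals are drawn independently per egg, so siblings are
uncorrelated beyond the shared `B`), multi-generation purging,
linkage, and phase polyphenism. Passing tests therefore certify the
statistical machinery under the model's own assumptions, not the
biology of any particular colony.

Each population consumes an RNG stream derived from the master seed
and a CRC32 of its name, so adding, removing or reordering
populations never perturbs the draws of the others, and all outputs
are byte-identical across reruns for a fixed seed.

## Genotype simulation

`simulate_genotypes` targets a within-population inbreeding
coefficient: with probability `F_is` a genotype's two alleles are one
draw duplicated (identical by descent), otherwise two independent
draws, giving `E[H_O] = (1 − F_is)·H_E`. Negative `F_is`
(heterozygote excess) uses exact rejection sampling against the
target genotype distribution `P(AᵢAᵢ) = pᵢ² + F·pᵢ(1−pᵢ)`,
`P(AᵢAⱼ) = 2pᵢpⱼ(1−F)`: propose a random-union pair, accept
heterozygotes always and homozygotes for allele *i* with probability
`(1 + F(1−pᵢ)/pᵢ)/(1−F)`. This distribution is only valid when
`F ≥ −pᵢ/(1−pᵢ)` for every allele, so configurations below that bound
are rejected up front with the offending locus named.

## Population-genetic statistics

* **H_E**: unbiased gene diversity `(2n/(2n−1))(1 − Σpᵢ²)` per locus.
* **H_O**: fraction of typed individuals with two distinct alleles.
* **F_IS**: multilocus `1 − ΣH_O/ΣH_E` (ratio of sums, excluding
  monomorphic loci) — more stable than averaging per-locus ratios
  when some loci have tiny `H_E`; per-locus values are also reported.
* **Allelic richness**: hypergeometric rarefaction
  `A_R = Σᵢ[1 − C(N−Nᵢ, g)/C(N, g)]`; `g` defaults per locus to the
  smallest per-population typed copy count (standard reporting), and
  a requested `g` exceeding any sample errors with the offending
  population and locus named.
* **Pairwise F_ST**: the Weir & Cockerham (1984) θ variance-components
  estimator, summed over alleles and loci before taking the ratio;
  negative estimates are reported as computed. θ was chosen because
  it is the field-standard default of the microsatellite packages this
  module replaces.

Missing genotypes are excluded locus-wise; a half-typed genotype is
treated as fully missing. Exact binomial coefficients (`math.comb`)
are used for rarefaction, so no large-sample approximations enter.

## Problem sizes and numerical checks

The verification suite works at sizes chosen to make Monte-Carlo
error negligible relative to the assertions: the inverse map is
checked on a 101 × 20 grid to 1e-12; the mechanistic egg simulation
uses 10⁶ eggs per (B, F) setting with 4-standard-error bounds;
parameter recovery runs 200 replicate experiments of 200 pods per
treatment (~50 eggs each) at a true load of 3.8 with 500 bootstrap
replicates per experiment, requiring the mean estimate within 0.15 of
truth and CI coverage between 90% and 99%; the F_IS generator check
uses 10⁴ individuals at six loci. The toy-table statistics are
compared to an independent exact-rational enumeration written with
explicit loops and `fractions.Fraction`, eliminating a shared-bug
failure mode between implementation and oracle.

## Known limitations

Quantities that depend on a particular study's raw genotypes or
rearing data (published heterozygosity tables, specific F_ST values,
measured inbred relative hatching percentages) cannot be recomputed
from this package alone; the property-based suites above are the
substitute evidence that each statistic is computed correctly. The
load model conflates all early-acting recessive mortality into `B`
and will misattribute, e.g., developmental failure of automictic eggs
(ploidy-restoration errors) to genetic load — one reason observed
inbred hatching can exceed the model's prediction by a wide margin.
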