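# Methods

This note documents the models, defaults and numerical choices behind
`gmatesim`, and what the scaled-down test configuration can and cannot
show.

## Genome and founder history

The simulated genome is a set of equal-length chromosomes (default 18 ×
100 cM) with marker and QTL positions drawn uniformly on the open interval
(0, L), rounded to 1e-6 cM, ties re-drawn. QTL status is assigned to a
uniform random subset of the drawn loci, so markers and QTL share one
positional law. Loci are biallelic, coded {0, 1} internally (exported as
1/2 in PLINK text).

Founder haplotypes are produced by explicit forward simulation rather than
by an external coalescent or QMSim-style tool: phase-1 haplotypes start
with every locus at frequency 0.5 (independent fair coins) and the
population then mates at random for many discrete generations (defaults:
2,000 individuals for 1,000 generations, then a bottleneck to 400 for
another 1,000) with symmetric allele-flip mutation at 2.5 × 10⁻⁵ per locus
per gamete, applied to markers and QTL alike. Because the process is run
to mutation–drift equilibrium, the arbitrary initial state is forgotten;
the bottleneck generates linkage disequilibrium on the cM scale (verified
by test: adjacent-marker r² exceeds r² at ≥ 50 cM). Mating in the
historical phases draws an independent (sire, dam) pair per offspring with
replacement at constant size — a 1:1 mating ratio in expectation, which is
all that matters once the chain is long. Modern founders (default 30
males, 900 females) are drawn uniformly from the last generation and
become pedigree roots with F_PED = 0. Loci monomorphic in the founders are
kept in the map (stable matrix shapes) and simply drop out of every
allele-frequency-based computation downstream.

## Meiosis

Gametes are sampled locus by locus: the first locus of each chromosome
copies a uniformly chosen parental haplotype; each subsequent locus
switches source iff an independent uniform draw falls below the
adjacent-interval recombination fraction r = ½(1 − e⁻²ᶜ) (c in Morgan).
The measure-zero tie u = r is resolved as "no switch". Intervals are
independent (Haldane, no interference) and chromosomes segregate
independently. Offspring store the sire's gamete as haplotype 1 and the
dam's as haplotype 2, so phase is known exactly throughout the simulation
— the segment-based kinship below never needs statistical phasing. There
is no mutation during the breeding phase.

## Traits

QTL allele-substitution effects have gamma-distributed magnitudes
(shape 0.4, scale 1) with independent random signs, then one scalar
rescales the whole vector so the *population* variance of the founder QTL
sums equals σ²_g = h²σ²_p exactly (σ²_p = 1,000; h² ∈ {0.1, 0.3, 0.5}).
Random signs matter: a one-sided gamma draw would make every QTL
trait-increasing and trivialise selection.

Two true-breeding-value modes are provided and covered by consistency
tests:

* **recursive** (default): g_i = ½g_s + ½g_d + w_i, with one fresh draw
  w_i ~ N(0, σ²_w), σ²_w = ¼(1 − f_s)σ²_a + ¼(1 − f_d)σ²_a, where f_s,
  f_d are the parents' pedigree inbreeding coefficients and σ²_a is frozen
  at the base-generation genetic variance. This treats the Mendelian
  deviation as an independent draw per offspring; the alternative reading
  "w_i = w_s + w_d" would correlate all full sibs' deviations and is not
  implemented.
* **genomic**: g_i is the QTL dosage sum, centred on the founder mean.
  Used for founders (the two modes must agree there), for internal checks
  and for real-data entry points.

Phenotypes are y = μ + g + e with fresh e ~ N(0, σ²_e), σ²_e = σ²_p − σ²_g,
and μ = 0 by default (all reported quantities are differences or rates).

## Genomic prediction (BayesB)

Marker effects are estimated by BayesB: effect j is zero with prior
probability π and otherwise N(0, σ²_j) with σ²_j ~ scaled-inv-χ²(ν, S²).
The sampler is single-site Gibbs with the effect integrated out of the
indicator draw; marker variances and the residual variance get standard
scaled-inv-χ² updates, and genotype columns are centred by 2p before
sampling (the reported intercept is mapped back to the raw-dosage scale).
Defaults: chain 20,000 / burn-in 1,000 / thinning 20 (4,000 / 500 / 10 in
the scaled-down configuration), π = 0.95 — matching the simulated
architecture of roughly 1 causal locus per 100 markers — ν = 4.2, and S²
solved from an expected genetic variance (the experiment passes h²σ²_p) via
E[σ²_j] · (1 − π) · Σ2p_jq_j = σ²_g. Markers monomorphic in the current
reference are excluded from the chain and reported with zero effect.
Chains are deterministic given the seed; the numba kernel makes a
desk-scale fit take ~1–2 s.

The reference population is always the two most recent generations,
re-fit from scratch each generation. Cohort u's GEBVs come from the fit
whose window is (u−1, u), so generation-0 metrics are identical across
schemes sharing a seed. Selection is truncation on GEBV (top 30 males /
900 females by default), ties broken by id.

## Relatedness

* **SNP GRM** — VanRaden method 1: G = ZZ' / (2Σp_jq_j) with columns
  centred by 2p_j; allele frequencies are recomputed within the cohort
  being analysed (base-generation frequencies would be an alternative; the
  current-cohort choice keeps the matrix well-scaled as frequencies
  drift).
* **Segment (ROH) GRM** — for each ordered pair of haplotypes the genome
  is scanned for maximal identical stretches; stretches of at least
  `min_length_cM` (default 1.0) and `min_markers` (default 20) contribute
  their cM length. Pair kinship averages the four haplotype-pair fractions
  of the total map length; G_ROH = 2 × kinship, so entries lie in [0, 2]
  and a fully autozygous individual has diagonal exactly 2 (self
  haplotype-pairs included). Thresholds are configurable because no
  canonical values exist; monotonicity in both thresholds is a tested
  invariant.
* **F_GRM** — the per-marker estimator mean_j[(x − 2p)² / 2p q] − 1, which
  may legitimately be negative. A `per_marker=False` variant uses the
  common VanRaden denominator, under which F_GRM equals diag(G) − 1 to
  machine precision; the per-marker form is the default because it is the
  conventional diagonal-based inbreeding estimate.
* **F_PED** — the tabular (recursive additive-relationship) method,
  requiring parents before offspring (which also rules out cycles). The
  test suite checks it against an independent Wright path-counting
  enumeration on pedigrees of up to 20 individuals. The tabular method is
  O(n²) memory; at full scale (~65k animals) a Meuwissen–Luo style
  algorithm would be needed, a known limitation.

## Mate allocation

A mating plan assigns every selected dam to exactly one sire, with a
per-sire capacity bound; litters have fixed size (10 by default, equal sex
split, odd litters alternating). Traditional schemes: random (dams
shuffled, dealt in balanced blocks), positive assortative (sires and dams
both ranked by GEBV descending, blockwise) and negative assortative
(sires ascending vs. dams descending).

The genomic-mating objectives are evaluated through the incidence matrix
P (rows = matings, ½ on sire and dam columns): Gain(P) = 1'PGMa and
Inbreeding(P) = 1'(PGP' + D)1. Writing u = P'1 (half-usage per parent),
the gain is u'G(Ma) and the relatedness term is the quadratic u'Gu — the
group coancestry of the planned progeny, minimised by spreading
contributions across unrelated parents as in optimal-contribution
selection. Both objectives are functions of parent usage only; which
specific dam meets which sire within a usage profile is objective-neutral,
so reported plans should be read as contribution profiles with an
arbitrary feasible pairing. D is the linkage-free within-cross segregation
variance D_kk = Σ_j a_j²[het_s(j) + het_d(j)]/4 (configurable off); merit
is centred before optimization so the gain objective ranks usage rather
than an arbitrary GEBV offset.

Because the traditional schemes use every sire equally, an *exact*
capacity of n_dams/n_sires would force the usage vector and make both GM
objectives plan-invariant; the optimizer therefore defaults to a capacity
of twice the balanced ratio (configurable via `gm_capacity`), giving the
frontier genuine width while still bounding concentration.

The optimizer encodes a plan as a dam→sire assignment vector and runs a
hybrid GA/SA: each population slot carries a fixed scalarization weight
λ ∈ [0, 1] (sweeping the frontier), children come from binary tournaments,
uniform crossover, per-dam mutation at rate 1/n_dams and capacity repair,
and replace their slot if better under λ or via simulated-annealing
acceptance (T₀ = 1, geometric decay 0.995). An elitist archive keeps every
nondominated (gain, inbreeding) plan; the archive endpoints define the
max-gain and min-inbreeding schemes. Defaults: population 200, 800
iterations (50 / 200 desk). On enumerable instances (2–3 sires, 4–6 dams)
the endpoints match exhaustive search in ≥ 95% of seeded runs (tested).

## Experiment and evaluation

One replicate builds a shared base: historical simulation → founders →
two random-mating burn-in generations (the initial two-generation
reference; the second burn-in cohort is generation 0). Every scheme then
runs forward from a deep copy of that state for five generations (three at
desk scale): fit BayesB → GEBV-rank → select → allocate mates per scheme →
breed litters → record cohort means of GEBV, TBV, F_PED and F_GRM.
Replicate r uses base seed + r; all streams are named substreams of a
Philox counter-based generator, so schemes within a replicate share
founders and burn-in exactly.

ΔG is the mean generation-to-generation change in cohort-average GEBV
(telescoping to (ā_G − ā_0)/G). ΔF = 1 − e^β with β the OLS slope of
ln(1 − F_u) on u, computed from F_PED — pedigree inbreeding is the
expectation of identity-by-descent and is exact in simulation, whereas
F_GRM is retained as a descriptive metric only. Summaries report replicate
mean ± SD per scheme × heritability.

## Scaled-down configuration: what it shows and what it cannot

The desk preset (2 × 50 cM chromosomes, 200 markers + 10 QTL each,
200 → 120 historical bottleneck over 80 + 80 generations, 5 sires /
50 dams, litter 4, 3 generations, shortened chain and GA) preserves every
structural element of the full design and runs the complete 7-scheme ×
5-replicate grid in ~2 minutes on one core. It is the configuration used
by the test suite and the acceptance script; the problem sizes are the
package's own choice for a single-machine workflow.

Passing desk-scale tests demonstrate correctness of the machinery
(estimators, oracle-verified optimizers, rate statistics) and the robust
qualitative signals: positive selection response for every scheme and a
higher inbreeding rate under positive assortative than under random
mating. They do *not* demonstrate the fine scheme ordering among the
genomic-mating variants: with only 5 sire lineages behind a 2-generation
bottleneck, every selected pair is similarly related, and between-scheme
differences in offspring F_PED and mean GEBV are smaller than replicate
noise — the corresponding acceptance check is accordingly expected to be
sensitive to seed at this scale. The full-scale preset (30 sires, 900
dams, 30,600 markers) is provided for cluster use, where the original
effect sizes (a few percent on ΔG, tens of percent on ΔF) become
resolvable across five replicates.

Other simplifications shared with the modelled design: discrete
generations, homogeneous environments, constant litter size, single trait
(the three heritabilities are independent traits), additive gene action
only, no X chromosome, no crossover interference, no mutation after the
historical phase, and no statistical phasing (true phase is carried
through the simulation; real-data users must supply phased VCF).
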