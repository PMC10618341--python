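# Methods

## Model and assumptions

The package works with fully homozygous material (inbred or doubled-haploid
lines) and purely additive gene action: no dominance, no epistasis, no
selection. A trait is governed by L biallelic QTL with substitution effects
`a` of the reference allele, drawn i.i.d. standard normal per locus. All
results are *conditional on the genotype matrix X*: they describe how the
realized additive variance V_A = a'Da varies across traits (draws of `a`)
for one fixed population sample.

The score covariance D = Z'Z/N uses divisor N, not N−1. This is not a
bias-correction question but an algebraic one: with divisor N the identity
E[V_A|X] = trace(D) holds exactly, and d_ii = 4p_i(1−p_i) with the sample
frequencies p. Monomorphic loci are retained as zero rows/columns so that
locus indexing is stable across generations and QTL subsets.

W and B are stored as full symmetric matrices, so every "sum over pairs"
counts (i, j) and (j, i) separately; a'Wa then carries the conventional
factor 2 of the covariance component without any extra bookkeeping.

### Exact and approximate moments

V_g, C_w, C_b, V_A are Gaussian quadratic forms, so their conditional
moments follow from E[a'Ma] = tr(M), var[a'Ma] = 2 tr(M²),
cov[a'M₁a, a'M₂a] = 2 tr(M₁M₂). The pairwise covariances vanish because V
is diagonal while W and B have zero diagonals and disjoint off-diagonal
supports — hence var[V_A|X] decomposes exactly, which every fixture asserts
numerically.

The ratio moments (E[b_w|X] ≈ 0, var[b_w|X] ≈ 2 tr(W²)/tr(V)², …) are
first-order delta-method approximations, implemented as such and never
asserted to machine precision; `monte_carlo_moments` is the reference for
their quality (empirically within ~20% at L = 40 and much closer at
L = 250, because V_g concentrates as L grows). When V_g = 0 (all sampled
QTL monomorphic, possible in small-P scenarios) the ratios are returned as
flagged NaN rather than raising, so aggregation can skip and count them.

The lower bound of b is the smallest eigenvalue of V^{−1/2}(D−V)V^{−1/2}
restricted to the polymorphic subspace; positive semidefiniteness of D
guarantees ≥ −1, and eigenvalues within 1e−9 below −1 are clipped as a
floating-point guard. Skewness and kurtosis are the raw standardized third
and fourth central moments (no small-sample correction); the kurtosis of a
normal is reported as 3.

## Meiosis and mating designs

Gametes are generated per chromosome as a Markov walk over the ordered
loci: a random starting haplotype, then a switch across each interval of
d cM with Haldane probability r = (1 − e^(−2d/100))/2, chromosomes
assorting independently. For a no-interference (Poisson crossover) model
this per-interval chain is *exact*, so no explicit crossover-count layer is
needed; the three-locus composition law r₁₃ = r₁₂ + r₂₃ − 2r₁₂r₂₃ is
verified by simulation.

Design conventions (open points resolved here): parents are sampled without
replacement from the panel (with replacement would allow selfs in a
half-diallel); each F1 progeny assigns its cross uniformly at random with
replacement (matching equal expected cross sizes and the degenerate P = 2
case of N identical F1s); random mating draws an unordered pair of two
distinct parents independently for every offspring (monoecious without
selfing — the pairing scheme is otherwise unspecified in the field's usual
description); exactly one DH line is derived per individual. All randomness
flows from one `numpy` Generator per replication, spawned from a master
`SeedSequence`, so runs are bit-reproducible and checkpoint-resumable.

## Synthetic ancestral panels

The generator emulates the *statistical structure* of real elite/landrace
maize panels — 115 lines, 10 chromosomes totalling 1442 cM, a tunable
monomorphic-in-panel fraction, and LD decaying to r² = 0.1 at ~21–22 cM —
not any particular genotypes. Chromosome lengths decrease gently (longest
twice the shortest), loci are uniform on each chromosome.

Each line is a mosaic of a small pool of H founder haplotypes with
exponential segment lengths. Pool alleles are Bernoulli(q_i) with q_i
uniform on [0.02, 0.98] (conditioned on segregating in the pool except for
the designated monomorphic fraction). Short-range r² in such a panel
plateaus near 1/(H−1), so H must satisfy 1/(H−1) > 0.1 for a decay distance
to exist; the default H = 6 gives ~0.2, leaving the mean segment length as
the single knob, calibrated by bisection (11 steps, fixed internal seed)
against the realized binned-r² decay distance. LD-decay binning is 1 cM
with the crossing localized at the first sub-threshold bin's midpoint (the
binning underlying the published threshold rule is not specified; this is a
documented choice).

What the generator does *not* reproduce: a rare-variant-rich site frequency
spectrum (panel frequencies cluster near multiples of 1/H), population
substructure/admixture, and marker-ascertainment effects. Passing tests
therefore demonstrate the mechanics of GPD generation and decay under the
mating designs, not numerical agreement with any real panel — which is also
why the scenario experiments are checked for *orderings and invariances*
(DC > FC > HC in var[b_b]; var[b] decreasing in P; E[V_A] flat across
designs and generations) rather than for published magnitudes that are
conditional on real genotypes.

## Scenario experiments and the decay regression

A scenario is (panel preset, design, P, N, L). Full profile: 500
replications × 50 QTL sets; the test suite and acceptance checks use a
desk-scale profile (30–50 replications × 5–10 QTL sets, L = 250, N = 50–1000,
and N = 20,000 for the single-generation GPD-halving check), sizes chosen so
each check completes in seconds to a couple of minutes while leaving
Monte-Carlo error well below the effect sizes asserted. QTL sets are drawn
fresh per replication, apportioned to chromosomes by genetic length
(largest-remainder rounding). Estimates average over replications × QTL
sets; standard errors are computed *across replications* and labelled as
such. Flagged undefined-ratio realizations are excluded from ratio averages
and counted in the metadata.

The finite-N decay model
var[b_b|N]_r = θ/4ʳ + ((4 − 4⁻ʳ)/3)ω (G1-DH is r = 0) is linear in (θ, ω),
so the fit is an exact least-squares solve — non-negative (`nnls`) by
default, with an unconstrained diagnostic refit and a flag when the
unconstrained ω is negative. The implied steady state is (4/3)ω. The
finite-N deviation scales like the sampling variance of d_ij, roughly 2c/N
with c ≈ 1 — hence ω ≈ 0.03 at N = 50 and ≈ 0.002 at N = 1000 largely
independent of the panel, which is what the acceptance thresholds
(ω > 0.01 at N = 50, ω ≤ 0.006 at N = 1000) encode. The E[V_A] invariance
check allows 2% relative spread: drift erodes expected heterozygosity by
1/(2N) per generation (≤1% over G1→G4 at N = 250) and across-replication
sampling noise is of the same order.

## Known limitations

* Heterozygous material is deliberately unsupported (0/2 coding only); the
  theory as implemented is for fully homozygous lines.
* Ratio moments are first-order approximations; for very small L or nearly
  monomorphic samples their error grows, and the Monte-Carlo path should be
  used instead.
* The eigenvalue bound on b assumes D is an exact sample covariance; a
  user-supplied indefinite "D" is rejected rather than repaired.
* The synthetic panel's frequency grid (multiples of ~1/pool-size) is
  coarser than real panels'; analyses that are sensitive to the fine MAF
  spectrum should supply a real panel via the TSV/VCF readers.
* `sign_asymmetry_probability` is a Monte-Carlo estimate only; no
  closed-form tail probability is attempted.
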