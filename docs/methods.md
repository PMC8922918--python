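# Methods

This note documents the statistical machinery behind `topsel`, the choices
made where the design was genuinely open, and what the synthetic studies do
and do not demonstrate.

## Genomic prediction

**Kinship.** K = W_c W_cᵀ / m, where W_c is the column-centred dosage matrix
over the m polymorphic markers (monomorphic markers are dropped).  No
per-marker standardisation and no normalisation of the diagonal: any global
scaling of K is absorbed by σ²_g, and predictions are invariant to it (this
is tested).  Consequently the diagonal mean equals the average marker
variance (≈ 0.37 for simulated F1 hybrids), not 1.  Centring also makes K
invariant to allele-label flips.  Missing dosages are mean-imputed per
marker before centring and flagged; imputation error is treated as marker
noise.  When only kinship blocks are needed (training × training,
testing × training), they are formed directly from W_c without materialising
the full hybrid-by-hybrid matrix; centring always uses marker means over all
individuals so blocks are mutually consistent.

**REML.** The mixed model y = Xb + μ + ε, μ ~ N(0, K σ²_g), ε ~ N(0, I σ²_e)
is fitted by restricted maximum likelihood, profiled over
h² = σ²_g/(σ²_g + σ²_e).  One eigendecomposition K = U Λ Uᵀ rotates the
model to independent observations; for fixed h² the GLS estimates and the
profiled scale σ²_p have closed forms, and the one-dimensional restricted
likelihood is maximised over h² ∈ (10⁻⁶, 1 − 10⁻⁶) by bounded Brent search
(tolerance 10⁻⁸).  X defaults to an intercept; Z is the identity (one record
per individual — multi-environment preprocessing is upstream of this
package).  Repeated fits against the same kinship (traits, folds,
simulation replicates) reuse the decomposition, which is what makes the
k-fold and recovery studies cheap.

**BLUP prediction.** μ̂ = σ²_g K_{·,train} V⁻¹ (y − Xb̂) with
V = σ²_g K_tt + σ²_e I on the training block.  The σ²_g factor matters: with
K = I this reduces to the scalar shrinkage μ̂ᵢ = h²(yᵢ − ȳ), which is the
closed form the implementation is tested against (without the factor the
limit is off by σ²_g + σ²_e).

**Self-predictions.** Weight learning needs predicted values for phenotyped
individuals; these come from k-fold cross-validation (default k = 10, seeded
shuffle, contiguous near-equal blocks) so that each individual is predicted
by a model that never saw it.  k = n reproduces exact leave-one-out (tested
against an explicit LOO loop).

## The similarity model

For target profile Y and candidates with predicted profiles Ŷᵐ, the
similarity is the softmax of negative weighted L1 distances
D_m = Σᵢ wᵢ |Yᵢ − Ŷᵢᵐ|, computed with max-subtraction so arbitrarily large
distances cannot overflow.  Scores are positive, sum to one over the pool,
and rank identically to the raw distances for any weights.

**Likelihood.** The printed similarity reuses one index for the numerator
and the denominator; read literally it is constant in n and carries no
information.  It is implemented as a proper softmax over candidates m for a
fixed target n, giving the self-identification likelihood
L(w) = Πₙ pₙₙ(w), pₙₘ = softmax_m(−D(Yⁿ, Ŷᵐ; w)).  The gradient is analytic:
∂(−ln L)/∂w_j = Σₙ(|Yⁿ_j − Ŷⁿ_j| − Σₘ pₙₘ |Yⁿ_j − Ŷᵐ_j|), and is verified
against central finite differences on random instances.  The N × N × d
absolute-difference tensor is cached once per fit, so each optimiser step is
a single tensor contraction; at the default training size (582 × 10) this is
~27 MB and a few milliseconds per iteration.

**Optimisation.** A hand-written BFGS maintains the Hessian approximation
B_{k+1} = B_k − B_k s_k s_kᵀ B_k/(s_kᵀ B_k s_k) + y_k y_kᵀ/(s_kᵀ y_k) from
B₀ = I, solves B_k d_k = −g_k, and terminates at ‖g‖ < 10⁻⁶ (or a flagged
non-convergence after 500 iterations — not an exception, since weights from
a near-stationary point are still usable).  The line search is Armijo
backtracking (c₁ = 10⁻⁴, shrink 0.5, at most 50 backtracks); curvature pairs
with sᵀy ≤ 0 skip the update and are counted.  The implementation is
cross-checked against an independent quasi-Newton solver on quadratics,
Rosenbrock, and the similarity likelihood itself.

**Conventions.** Weights start at 1 (all traits equal), are unconstrained
(negative weights are allowed and signal harmful traits; the
`filter_by_weight` step drops them and the caller retrains), and absorb
trait scale — no standardisation is applied to distances by default, though
a z-scaling flag exists for numerical conditioning.  Multiplying a trait by
c while dividing its weight by c changes nothing (tested).  Prediction sets
must be complete; missing trait values are rejected rather than imputed.

## Identification protocol

The accuracy metric: sample pools of N₀ testing individuals (without
replacement within a pool, independently across pools; 200 pools per size by
default), let every member serve once as the target — its observed profile
is matched against the pool's predicted profiles — and count a success when
the member itself attains the top similarity.  The chance baseline is 1/N₀.
Success requires a strict win; exact score ties are resolved by the
deterministic lexicographic id tie-break, so a tied target only counts if it
also wins the tie-break.  Note for calibration studies: pools drawn from one
finite population share individuals, so trial outcomes are positively
clustered and the Monte-Carlo error of a rate exceeds its binomial value;
the test suite therefore estimates that error across independent replicate
populations.

## Omics composition and trait filtering

Each omics layer is reduced separately (never concatenated across layers) to
the smallest number of leading principal components whose cumulative
explained variance reaches the target (default 80%).  Features are
standardised to unit variance first — expression and metabolite intensities
are incommensurate — with a raw-scale flag for data already on one scale.
Trait filters: drop traits with prediction accuracy r below a threshold
(strictly below; the boundary survives), and drop traits whose learned
weight is negative, retraining on the survivors.  Both filters preserve
order and are idempotent.

## Comparators and the success metric

Independent culling intersects the per-trait top-n selections (the
intersection may legitimately be empty — that is the method's known failure
mode with many traits and is reported, not raised).  The desired-gains index
uses b = P⁻¹G*[G*ᵀP⁻¹G*]⁻¹Q, implemented with linear solves rather than
explicit inverses; the defining identity G*ᵀb = Q and the Smith–Hazel round
trip a = G⁻¹Pb, P⁻¹Ga = b are enforced to 10⁻⁸ in tests.  P is estimated as
the sample covariance of observed training phenotypes and G as the sample
covariance of the training self-predictions (the data-scale stand-ins for
phenotypic and additive-genetic covariance; both are injectable).  Desired
gains are expressed as signed fractions of the testing-population trait
mean.

Success (per selected candidate, NS = 100 by default): for culling/index, a
trait succeeds when the observed value clears the testing mean by strictly
more than 0.5 SD in the favourable direction; for similarity selection, when
the observed value is strictly within 0.5 SD of the target's value.  A
candidate succeeds only if all considered traits do; per-trait rates are
reported alongside the joint rate.

## Synthetic NCII studies

The generator emulates a factorial hybrid panel: per-marker allele
frequencies uniform on [0.1, 0.9] (keeps simulated MAF clear of filter
thresholds), parents drawn as independent homozygotes, hybrid dosage = mean
of the parental dosages.  Phenotypes are additive: all traits share one QTL
set (default 100 of 1000 markers), per-QTL effect vectors are multivariate
normal with the target cross-trait correlation, genetic values are rescaled
to variance h²·SD² and iid Gaussian noise supplies the rest.  Defaults are a
194 × 30 grid (5820 hybrids), 10 traits with h² spread over [0.3, 0.8],
exchangeable genetic correlation 0.2, trait mean 100 and phenotypic SD 10 —
a 10% coefficient of variation, typical of flowering-time or plant-height
scales, under which a "5% earlier" ideotype shift equals half a phenotypic
SD.  Training sets follow wrap-around diagonal strips of the grid
(j ≡ i + s mod P), which keeps every parent represented; three strips of a
194 × 30 grid give 582 training hybrids, and an exact published size can be
emulated by seeded trimming.  Omics features are linear combinations of a
few marker dosages plus noise with a controlled genetic variance share.

What the simulator does **not** model: linkage and LD beyond family
structure, dominance and epistasis, genotype × environment interaction,
selection history.  Two consequences worth knowing.  First, identification
rates here are not comparable number-for-number with real-data rates — the
simulated trait panel, its correlations, and its prediction accuracies are
not maize's.  Second, a factorial population has only M + P founders, so
even with independently drawn effects the realised cross-trait genetic
correlations fluctuate at order 1/√(founders) (~0.06–0.2); tests of the
"independent traits" construction therefore check unbiasedness across seeds
rather than a tight single-seed bound.

**Problem sizes.** The bundled studies run the full 5820-hybrid pipeline
with 1000 markers (kinship is stable at this marker count for ~600-hybrid
training sets), 10-fold self-predictions, and 50–200 Monte-Carlo pools per
rate; the REML recovery study uses n = 2000 hybrids with data drawn from the
REML model itself (genetic values with covariance exactly proportional to K)
so that the h² parameter being estimated is exactly 0.5.

**Method-comparison conditions.** The three-way comparison uses ten traits
with h² in [0.6, 0.9] — multi-location BLUP-quality phenotypes, matching
the reliability of real hybrid-trial data — exchangeable genetic correlation
0.4, and four considered traits with antagonistic goals (two decreased, two
increased by 5%).  This is the regime the comparison is about: truncation
methods chase a corner of phenotype space that positive trait correlations
leave nearly empty (the culling intersection is typically empty outright,
and joint index success collapses), while the similarity target — a mean
profile shifted 5% — sits in a populated region that accurate predictions
can find.  With fewer or non-antagonistic traits the index is competitive;
the package makes both regimes easy to explore.

## Numerical details and edge cases

- Eigenvalues of K are clipped at 0 (numerical PSD); σ²_e is floored at the
  smallest positive double to keep V invertible.
- Zero-variance phenotypes, constant vectors in correlations, empty
  selections, all-monomorphic marker sets, non-PSD correlation targets, and
  pool sizes outside [2, N] raise informative errors.
- All randomness flows through explicit integer seeds via numpy Generators;
  every simulation, fold assignment and pool draw is bit-reproducible.
- Rankings break score ties lexicographically by candidate id, so output
  files are stable across runs and platforms; scores are written at 12
  significant digits, which round-trips losslessly.
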