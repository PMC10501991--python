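# Methods

## Population model and representations

A cohort of *M* individuals lives on a shared clone index
*i* = 1..Ω.  Two descriptions are supported throughout:

* **n-representation** — integer cell counts nᵢ⁽ᵐ⁾ per clone, with
  population totals N⁽ᵐ⁾ = Σᵢ nᵢ⁽ᵐ⁾.  Counts are exact data; richness
  and overlap of the full populations are deterministic tallies.
* **p-representation** — occurrence probabilities pᵢ⁽ᵐ⁾ with
  Σᵢ pᵢ⁽ᵐ⁾ = 1.  Each individual's population is modelled as one
  multinomial draw of N⁽ᵐ⁾ cells from p⁽ᵐ⁾; individuals are
  independent.  Richness and overlap are then random variables and the
  package returns their first two moments.

The multinomial assumption is the simplifying core of the model: it
ignores clonal birth–death dynamics, competition and genetic relatedness
between individuals.  Any mechanism that produces a probability vector
per individual (e.g. a V(D)J generation model with individual selection
factors) can feed the p-representation.

## Occurrence probabilities

All moments are assembled from four families of per-clone probabilities:

| quantity | meaning | form |
|---|---|---|
| ρᵢ | clone i present in one multinomial draw | 1 − (1−pᵢ)ᴺ |
| ρᵢⱼ | clones i and j both present | 1 + (1−pᵢ−pⱼ)ᴺ − (1−pᵢ)ᴺ − (1−pⱼ)ᴺ |
| σᵢ | clone i present in a size-S subsample | 1 − C(N−nᵢ,S)/C(N,S) |
| σᵢⱼ | both present in the subsample | inclusion–exclusion of the ratios |

with tilde variants (ρ̃, σ̃) for "present in at least one of the M
individuals/samples", obtained by multiplying the per-member absence
probabilities.  Subsampling is one-shot and without replacement, so the
σ-quantities are multivariate hypergeometric marginals.

Because hypergeometric subsampling of a multinomial draw is again
multinomial (conjugacy), every sampled statistic in the
p-representation is the whole-organism formula with the exponent N
replaced by S.  This identity is verified in the test suite by comparing
two-stage (multinomial then hypergeometric) against one-stage sampling.

Mean and second moment of every count statistic share one structure:
the mean is a sum of per-clone success probabilities, and the second
moment adds a sum over ordered clone pairs i ≠ j of pairwise joint
probabilities.  Pair sums follow the ordered-pair convention throughout
(both (i,j) and (j,i) are counted); no factor-of-two bookkeeping is ever
mixed in.

## Numerical choices

* **Log-space powers.**  (1−p)^N is always exp(N·log1p(−p)); repertoire
  probabilities reach 1e−8 and exponents 1e8, where naive powering loses
  all precision.  The Poisson approximation exp(−pN) is available via an
  explicit `approx_exp` flag and is never substituted silently.
* **Binomial-coefficient ratios.**  C(N−n,S)/C(N,S) is evaluated as the
  log-sum of Π_{ℓ=1..n}(1 − S/(N−n+ℓ)); factorials are never formed.
  For a whole abundance vector the log-ratios for all n = 0..n_max come
  from one suffix cumulative sum over j = N, N−1, …, so a member costs
  O(n_max), not O(Ω·n_max).
* **Pair sums and the resource guard.**  The Σ_{i≠j} terms are O(Ω²).
  They are evaluated blockwise (row chunks × all columns) with NumPy;
  above Ω = 50 000 an explicit `chunk_size` must be passed, otherwise a
  `ResourceGuardError` is raised — a deliberate switch instead of a
  silently week-long run.  Block sizes are additionally capped at ~0.5
  GiB of scratch per block.  For overlap statistics the sums are
  restricted to clones present in all members; this is exact because
  σᵢⱼ⁽ᵐ⁾ (and ρ…-analogues) vanish identically when member m lacks
  either clone.
* **Clamping.**  Inclusion–exclusion can leave [0,1] by round-off;
  excursions within 1e−12 are clamped, larger ones raise a
  numerical-consistency error rather than propagate.
* **Variance floor.**  `MomentSummary` clamps variances in
  [−1e−9·max(1, mean²), 0) to zero; Fano factor and CV² are NaN at zero
  mean (legitimately reached at S = 0) rather than an error.

## Poisson-binomial distributions

The number of individuals Mᵢ carrying clone i, and the sampled overlap
count K_s⁽ᴹ⁾ itself, follow Poisson-binomial laws.  The pmf is computed
by the O(n²) shift-and-add convolution, never by the defining 2ⁿ subset
sum (which the tests keep as an oracle up to n ≈ 15).  For the overlap
pmf the per-clone presence events are treated as independent; the
multinomial/hypergeometric constraint actually couples them weakly and
negatively, so this pmf is exact in its mean but slightly wide in its
variance — the pairwise second-moment formula is authoritative for
variances, and the package documents the pmf as an approximation.

## Power-law closed forms

For ranked probabilities pᵢ = i^(−ν)/H_ν(Ω), the expected richness, its
CV², and the expected sampled M-overlap admit large-Ω closed forms on
specific exponent branches (ν = 0, 1/2, 1, and ν > 1 for richness;
ν = 0 and ν ≳ 0.7 for the overlap asymptotic).  Branch selection is
explicit: requesting a closed form off-branch raises
`UnsupportedBranchError` naming `exact_sum` as the fallback — there is
no silent interpolation, because the branches are asymptotic in
different variables (Ω/N vs Ω/N^{1/ν}).  The 0.7 gate for the overlap
asymptotic is empirical and exposed as the module constant
`NU_ASYMPTOTIC_MIN`.

The exponential integral E(x,y) = ∫₁^∞ t^(−x) e^(−yt) dt uses scipy's
`expn` at integer orders and the upper-incomplete-gamma relation in
30-digit mpmath arithmetic otherwise, accurate to 1e−10 relative over
y ∈ [1e−8, 1e2].  Generalized harmonic numbers are summed directly up to
rank 1e7 and completed with an Euler–Maclaurin tail beyond (relative
error well under 1e−10).

The richness `exact_sum` evaluates the Poissonized occupancy
Σᵢ(1 − e^(−Npᵢ)) — the form the closed forms are derived from — while
the overlap `exact_sum` keeps the fully binomial (1−(1−pᵢ)^S)^M with the
exponential version opt-in.  Two approximation claims were checked
numerically and sharpened:

* the rescaled CV²·N^{1/ν} for ν > 1 converges at large x to a positive
  constant (≈0.30 for ν = 2), not to zero; what vanishes is CV² itself,
  as N^(−1/ν).  Tests assert the verified decay and the branch/direct
  agreement.
* the binomial variance approximation Ω·q(1−q) for the sampled overlap
  overshoots the exact pairwise variance (presences are negatively
  correlated); at Ω = 10³, S = 10², M = 2 the gap is ≈20%.  Tests assert
  the ordering and a 25% agreement band in that dilute regime.

## Information loss

Entropies are in nats (a `to_bits` rescaler is provided; the choice of
base is a global constant factor).  Discretizing a continuous density
into B bins of width Δ loses
L(Δ) = |(S_p − log Δ) − H_q|, where subtracting log Δ removes the
divergence of the binned entropy as Δ → 0; the absolute value is kept
verbatim from the definition even though the enclosed quantity is
non-negative in all exercised cases.  Coarse-graining an
already-discrete distribution groups ceil(Ω/B) consecutive traits per
bin — deliberately including the ragged/empty final bin and the loss
plateaus this rule produces, since those artifacts are part of
spectratype-style grouping — and loses H_p − H_q ≥ 0, which equals
−log(B/Ω) exactly for uniform distributions at divisor B.

Quadrature (bin masses, differential entropy) is scipy adaptive
quadrature at absolute tolerance 1e−10 (1e−8 for entropies); integrable
endpoint singularities such as the x^(−1/2) edge of the bundled
truncated-sqrt density are handled by the adaptive subdivision, and the
contract is only the stated tolerance.

## Synthetic generators

* `shifted_uniform_cohort` — deterministic: member m occupies clone
  indices [1+(m−1)·s, c+(m−1)·s] with equal counts.  Defaults (M = 3,
  c = 1000 clones, 100 cells each, shift s = 250) give group richness
  1500, consecutive-pair overlaps 750, outer-pair and triple overlaps
  500.  The shift is derived from those overlap maxima and exposed as a
  parameter.
* `multinomial_cohort` / `powerlaw_cohort` — independent seeded
  multinomial draws per member (the model itself).
* `hypergeometric_subsample` / `subsampled_cohort` — one-shot
  multivariate-hypergeometric draws; per-member child seeds keep members
  independent but reproducible.
* `sonia_like_cohort` — a synthetic stand-in for generation-model
  output: a Pareto-tailed probability vector over a clone space four
  times the cell count, reproducing the singleton-dominated abundance
  profile (most clones at abundance 1, few above 5).  It matches that
  qualitative shape only — not the sequence composition, the richness,
  or the tail exponent of any particular generation model — so tests on
  it assert structural properties, never reference values.

Every stochastic operation takes an explicit integer seed; there is no
hidden global RNG.

What passing tests on these cohorts show: the analytic moment formulas
are exact for the model they assume.  What they do not show: that real
repertoires follow a time-independent multinomial law, that clone
probabilities are stable across sequencing replicates, or that the
shared clone index is error-free — PCR bias, sequencing error and
clonotype-collapsing choices all sit outside the model.

## Problem sizes

The default suite enumerates exact oracles at Ω ≤ 3, N ≤ 5, runs
Monte-Carlo comparisons with 1e5 replicates on cohorts of a few dozen
clones, and evaluates power-law sums to Ω = 10⁷; the acceptance script's
pair sums run over the 750² and 500² shared-clone pairs of the
shifted-uniform cohort.  These sizes were chosen so every quantity is
either exact or has Monte-Carlo error far below the assertion bands.

## Known limitations

* The overlap pmf's independence approximation (above): variances from
  the pmf exceed the exact pairwise values; use the moment formulas for
  error bars.
* Closed-form branches cover the classic exponents only; intermediate ν
  always works through `exact_sum` but without an asymptotic shortcut.
* The Bayesian posterior richness conditions on known (p, N); inferring
  p from the sample itself is out of scope.
* No unseen-species (Chao-type) estimators and no diversity indices
  beyond richness/overlap — the package quantifies sampling behaviour of
  richness-like counts, not abundance-weighted diversity.
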