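# Methods

`speechlaws` implements a statistical analysis of time-aligned spontaneous
speech at three nested levels — phonemes, words, and breath groups (BGs,
maximal stretches of speech between pauses for breathing or longer) — in
both symbolic units (counts of characters, phonemes, words) and physical
units (seconds). Its two pillars are (i) the lognormality of unit durations
with a sum-of-lognormals generative model, and (ii) the four classical
linguistic laws — Zipf, Herdan/Heaps, brevity, Menzerath–Altmann — together
with their newer parametric formulations (exponential brevity law, size-rank
law, mechanistic Menzerath recursion, speech velocity). Because the corpus
the analysis was designed around is license-restricted, a synthetic
generator with known ground truth stands in for it everywhere; every test
and the acceptance script run on generated data or on printed parameter
values.

## Data model

A corpus is a long-format token table (`speaker_id, level, label, onset_s,
duration_s, word_id, bg_id`), one row per phoneme, word, or pause token;
onsets are in seconds with half-open intervals `[onset, onset + duration)`.
BGs are not token rows: they are derived (a maximal pause-free run of words
within a speaker) and kept in a per-BG table, because a *recorded* BG
duration may legitimately exceed the sum of its word durations — manual
boundary detection between silence and speech carries an additive error with
a small positive mean (voice-onset-time effects). Validation therefore
allows a configurable fractional slack (default 5%, for segmentation gaps)
plus, at BG level only, an absolute slack (default 0.3 s) to accommodate a
bias of either sign on short BGs.

Character counts are letters only, case-folded, punctuation stripped, and
are exposed at word level only: the same word admits several phonetic
realizations, so assigning characters to individual phonemes is ambiguous.

## Synthetic corpus generator

The generator's defaults are the study conditions; they are not tuned per
test.

| parameter | default | what it encodes |
|---|---|---|
| phoneme log-duration (μ, σ) | (−2.68, 0.59) log-s | lognormal phoneme durations |
| word-frequency law (α₁, α₂, r\*) | (0.63, 1.41, 49) | double power law, continuous at the breakpoint |
| vocabulary size | 8000 types | spontaneous-speech lexicon scale |
| phoneme-count coupling (λ_D, D) | (0.5, 64) | brevity: types get ≈ −log_D(p)/λ_D phonemes |
| character coupling (λ_D, D) | (0.6, 26) | brevity in orthographic length |
| type effect sd | 0.1 log-s | per-type offset of mean log-duration |
| serial correlation ρ | 0.5 | AR(1) on log-durations within a BG |
| pause probability q | 1/6 | geometric BG sizes, mean 6 words |
| BG bias ξ ~ N(μ_ξ, σ_ξ) | (0.14, 0.07) s | boundary-detection bias, truncated at 0 |
| tokens / speakers | 3×10⁵ / 40 | study scale (tests use 1.5–10×10⁴) |

Design points worth spelling out:

- **Serial correlation is AR(1)** on the phoneme log-durations, reset at BG
  boundaries (a Gaussian copula with one parameter). Dependence between
  successive durations is an empirical fact the analysis must detect, but
  its form is not pinned down by theory; AR(1) is the minimal one-parameter
  structure compatible with the correlated-sum limit theorem (see below).
  The mutual-information machinery makes no use of this choice.
- **Brevity is induced through optimal coding.** Type sizes are
  `max(1, round(−log_D(p)/λ_D + ε))` with integer noise ε uniform on
  {−1, 0, 1}. λ_D = 1 with no noise is the optimal-code-length limit.
  Realized label lengths can exceed the assigned length only when the 26^ℓ
  capacity of a length class is exhausted — the same constraint a real
  D-ary code faces — and the ground truth records realized lengths.
- **BG sizes are geometric** (pause after each word with probability q),
  the discrete analogue of the exponentially decaying words-per-BG
  distribution, i.e. a memoryless segmentation process.
- **What the generator does not emulate:** phonotactics, prosody, real
  phoneme inventories, speaker heterogeneity in rate, and any
  length-dependent compression of constituents. The last point matters for
  Menzerath–Altmann: generated corpora sit near the constant (order-0)
  regime, which serves as a negative control; MAL *recovery* tests use
  curves produced by the mechanistic recursion instead. Passing tests on
  synthetic data therefore demonstrate estimator correctness under the
  modeled structure, not the empirical truth of the laws in any real
  corpus.

## Duration statistics

Five two-parameter families (lognormal, normal, gamma, Weibull, beta) are
fitted by MLE under identical conditions; the winner maximizes the mean
log-likelihood per observation (natural log), with the Kolmogorov–Smirnov
sup-distance reported alongside (no p-value). Lognormal and normal are
closed-form; gamma/Weibull/beta use scipy's numeric likelihood maximization
with the location pinned at zero. The beta family has bounded support, so
the sample is rescaled to (0, 1) by max·(1+10⁻⁶) and the Jacobian is kept
in the likelihood — without it the families would not be comparable.

The universal collapse standardizes log-durations,
t′ = (log t − ⟨log t⟩)/sd(log t); under lognormality every level falls on
N(0, 1), and the KS distance to the standard normal quantifies the
collapse. Log binning uses equal widths in log₁₀ with 20 bins by default
(the bin count is a display/diagnostic choice, not part of any fit).

A caveat established numerically during development: for word-like
mixtures (a random number n of summands with mean ≈ 3) the five-family
selection is a near-tie — gamma or beta can edge out the lognormal by a few
hundredths of a nat even when the data were built from lognormal parts.
The tests accordingly assert *competitiveness* of the lognormal (within
0.05 nats, small KS) rather than an outright win, except where correlation
or a single summand makes the win clear-cut.

## Sums of lognormals

The Fenton–Wilkinson approximation moment-matches a lognormal to the sum of
n i.i.d. lognormals: with m = n·e^{μ+σ²/2} and v = n(e^{σ²}−1)e^{2μ+σ²},
σ_Z² = ln(1 + v/m²) and μ_Z = ln m − σ_Z²/2. At the phoneme parameters and
n = 3 its KS distance to Monte-Carlo sums is below 0.01. Two empirical
facts the test suite encodes:

- At small n (2–10) the FW lognormal clearly beats the moment-matched
  normal — speech operates far from the CLT regime.
- At large n the normal becomes accurate (KS < 0.015 at n = 300), but the
  FW lognormal *still* wins in KS at any linguistically relevant n, because
  it approximately matches the sum's skewness (≈ 2.2/√n at σ = 0.59) while
  the normal has none. There is no practical crossover point where the
  normal overtakes it.

With positively correlated summands (the realistic case) a limit theorem
due to Beaulieu guarantees the sum approaches a lognormal; numerically,
AR(1) correlation at ρ = 0.6 *shrinks* the lognormal KS distance of the
mixture relative to independent summands, which is the property tested.

Dependence is measured by plug-in mutual information on an equal-frequency
16×16 grid (quantile binning is robust to heavy tails). The plug-in bias
of order (k−1)²/2N never vanishes, so the observed value is always judged
against a null built by shuffling all token durations while preserving the
container-size structure (100 shuffles by default, seeded). With ρ = 0.5
the observed MI exceeds the null mean by one to two orders of magnitude;
with ρ = 0 it stays within three null standard deviations.

## Rank laws

**Zipf.** The rank-frequency table is treated as a discrete probability
over the observed ranks and fitted by multinomial MLE: single model
p(r) ∝ r^(−α); double model with exponents α₁, α₂ and breakpoint r\*,
constrained continuous at r\* (removing one free parameter), with r\*
chosen by profile likelihood (coarse log-spaced candidates, then an
exhaustive local refinement). Model choice is BIC = k ln N − 2 ln L̂ with
k = 1 vs 3 and N the token count. A caveat: the *sorted* empirical rank
curve of even single-exponent data bends systematically at the tail (an
order-statistics effect of ties and reordering), worth a few dozen nats at
N = 10⁵ — more than the BIC penalty. The discriminating signature is
therefore not the raw BIC choice but where the breakpoint lands: interior
(r\* ≈ 49, token mass on both sides, |ΔBIC| ~ 10⁴) for genuinely double
data versus an extreme-tail artifact (r\*/R > 0.8, negligible tail mass,
|ΔBIC| ~ 10¹–10²) for single data.

**Yule.** p(r) ∝ r^(−b) c^r fitted by MLE with direct-summation
normalization over observed ranks; the power law is the c = 1 boundary, the
geometric the b = 0 boundary. Nelder–Mead from three starts.

**Herdan/Heaps.** Vocabulary size V after each word token, against either
token count L or elapsed time T (cumulative word durations; pauses excluded
by default since the T ∝ L argument assumes no silences — includable via a
flag). Because T = E(Y)·L asymptotically (law of large numbers), the
exponents of V ~ L^β and V ~ T^γ must coincide; β = γ within 0.02 on
generated corpora. The exponent is the log–log least-squares slope over
tokens ≥ 100 (the initial every-word-is-new transient is excluded; the
window is configurable). Speaker concatenation order is permuted (10
permutations by default) and the exponent averaged.

**Size-rank law.** Substituting the exponential brevity law into Zipf's law
predicts ℓ(r) = (α/λ) log r + K on each side of the breakpoint, so the
slopes θ₁ = α₁/λ and θ₂ = α₂/λ are *fixed by the upstream fits* and only
the intercepts are estimated (per-segment least squares). Agreement is
reported as the RMSE against log-binned means of the type cloud.

## Brevity law

Qualitatively: Spearman rank correlation between type frequency and type
size (median duration in seconds, median phoneme count, or character
count), two-sided p-value. Parametrically: optimal coding gives
ℓ = −(1/λ_D) log_D p, i.e. f ~ D^(−λ_D ℓ) with λ_D ∈ (0, 1] measuring
distance from optimal compression; with a continuous size measure there is
no natural alphabet and the law reads f ~ exp(−λℓ).

**Estimator orientation matters.** The exponent is estimated by least
squares of *size on log-frequency* — the orientation of the coding
derivation itself — and reported as λ = −1/slope. The reason is
errors-in-variables: the noise lives overwhelmingly in the size measurement
(integer assignment noise, median-of-few-tokens durations), so regressing
log-frequency on size attenuates the slope severely (recovering ≈ 0.25
instead of 0.6, and ≈ 6 instead of 20.6 under the generator's own
conditions), while the reverse orientation keeps that noise in the
response, where ordinary least squares is unbiased. The naive forward
slope is retained as a diagnostic field, and agreement with log-binned
means of the cloud is reported as an RMSE.

The remaining error source is sampling noise in ln f itself (variance
≈ 1/f per type), which inflates λ̂ by ~6% when every observed type enters
the fit. For exponent *estimation* a frequency floor `f_min = 10` keeps
that noise below 10% and centers the recovery; the floor is an exposed
parameter (default 1 at word level, 50 at phoneme level, matching the
practice of cutting rare units to counterbalance low sampling). A formal
disattenuation correction (subtracting E[1/f] from the regressor variance)
was evaluated and overcorrects in the rare-type regime, so it was not
adopted. Changing the alphabet rescales λ_D by ratios of ln D while the
slope in nats is invariant, which keeps the discrete and continuous
formulations consistent.

## Menzerath–Altmann law and speech velocity

The constituent-size law y(n) = a·n^b·e^(−cn) is fitted by
Levenberg–Marquardt nonlinear least squares to the per-n mean constituent
sizes (the construct-instance cloud enters through those means), from a
moments-style start (a = y(1), b = small-n log–log slope, c = 0) with five
jittered restarts. R² is reported both on the per-n means and on 10-bin
linearly binned means of the cloud; the binning is how the relation is
conventionally displayed, but fitting on binned means would bias a
noiseless recovery, so the fit itself uses the unbinned means. With
b, c < 0 the curve has its minimum at n\* = b/c; n\* is reported as a real
number, not rounded to an integer word count.

The mechanistic recursion builds a construct by appending constituents:
t(n) = κ₁(1 + κ₂/(n−1))·t(n−1), with κ₂ ∈ (0, 1) the fraction of the
running average the new constituent inherits and κ₁ ≥ 1 a growth prefactor
(κ₁ < 1 would eventually shrink t(n), which is unphysical). Telescoping
gives ∏(1+κ₂/(j−1)) = Γ(n+κ₂)/(Γ(1+κ₂)Γ(n)), hence exactly the MAL form
with b = κ₂ − 1 and c = −ln κ₁ — both negative, so the two regimes are
generic and two parameters suffice. For the order-2 prefactor we use the
exact large-n constant 1/Γ(1+κ₂) (since Γ(n+κ₂)/Γ(n) → n^κ₂); expanding
log(1+κ₂/(j−1)) to first order instead yields the equivalent small-κ₂
constant e^{κ₂γ_E} via harmonic numbers, but that version deviates by tens
of percent at κ₂ ≈ 0.8 and is documented rather than used. A variant that
exponentiates the growth factor, t(n) = t(1)∏κ₁(1+1/(j−1))^κ₂ = t(1)κ₁^{n−1}n^{κ₂},
telescopes with no approximation at all and is the reference for the
closed-loop identity test (mechanism → curve → fit recovers (a, b, c)
within 5%; in practice to machine precision on noiseless input).

When constituent size is in seconds, v(n) = 1/y(n) is the average speech
velocity of an n-word BG, maximal at n\*. With the worked-example
time-units parameters (0.364, −0.227, −6.7×10⁻³): n\* = 33.9 words,
v_max = 4.87 words/s, and v(6) = 3.96 words/s at the typical six-word BG —
speakers sit below the optimal-efficiency limit.

## Numerical choices and degenerate inputs

- All optimizers start from method-of-moments-style initial values;
  Nelder–Mead tolerances 10⁻⁸–10⁻¹⁰ for the rank laws, `curve_fit`
  (LM) with 5 restarts for MAL.
- Constant samples, empty levels, too-small samples, non-positive
  durations, orphan phonemes, and length mismatches raise typed errors;
  a positive brevity slope sets a `brevity_violated` flag (with a warning)
  rather than failing; a MAL fit without b, c < 0 reports "no optimum"
  rather than failing.
- Rank ties are broken by first occurrence (stable), making the rank table
  invariant under count-preserving relabelings.
- Determinism: every stochastic routine takes a seed; the pipeline fans a
  single global seed out to per-stage children via `SeedSequence.spawn`, so
  stages can be re-run in isolation and full reports are byte-identical
  under a fixed seed.

## Problem sizes

Test corpora use 1.5×10⁴–10⁵ word tokens (vocabulary 500–2000); recovery
runs at the printed parameter values use the study-scale sizes (10⁵
lognormal draws, 3×10⁵ Zipf tokens over 8000 types, 8×10⁵ Yule tokens over
64 ranks, 5000 brevity-coupled types at 3×10⁵ tokens). The numbered
analysis drivers use one 6×10⁴-token corpus. These sizes put every
recovery comfortably inside its stated tolerance while keeping the whole
suite around a minute of compute.

## Known limitations

- The AR(1) dependence structure is a stand-in for whatever process
  produces serial correlation in real speech; only its existence and
  strength are empirically anchored.
- The generator encodes no Menzerath mechanism, so corpus-level MAL fits
  act as negative controls only.
- Phoneme-token label frequencies arise from mixing per-type symbol draws
  with word frequencies, so they follow the generating Yule law only
  approximately; Yule *estimator* recovery is tested on direct samples.
- Phoneme-level lognormality is an assumption of the generative model, not
  something the package explains mechanistically.
- The BG bias parameters (μ_ξ, σ_ξ) are exposed rather than wrapped in the
  ±20% robustness band sometimes quoted for them; users can vary them
  directly.
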