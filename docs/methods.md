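# Methods

`dtews` implements an end-to-end pipeline for anticipating the five
local, codimension-one bifurcations of discrete-time dynamical systems
(period-doubling, Neimark–Sacker, fold, transcritical, pitchfork) from
a single noisy time series, and for benchmarking that predictor against
the classical early-warning indicators, rolling variance and lag-1
autocorrelation.

## Training-data model

Each training example comes from a stochastic difference equation built
from the normal form of one bifurcation, with random higher-order
polynomial terms and additive Gaussian white noise:

* period-doubling: x_{t+1} = −(1+μ)x_t ± x_t³ + Σ_{i=4..10} α_i x_t^i + σε_t
* Neimark–Sacker: (x,y)_{t+1} = (1+μ)R(θ)(x,y)_t ± (x²+y²)R(θ)(x,y)_t
  + Σ_{i=4..10} Σ_{j=0..i} (α_ij, β_ij) x^{i−j} y^j + σ(ε¹,ε²)_t,
  with θ ~ U[0, π]
* fold: x_{t+1} = −μ + x_t − x_t² + Σ_{i=3..10} α_i (x_t − √(−μ))^i + σε_t
* transcritical: x_{t+1} = (1+μ)x_t − x_t² + Σ_{i=3..10} α_i x_t^i + σε_t
* pitchfork: x_{t+1} = (1+μ)x_t ± x_t³ + Σ_{i=4..10} α_i x_t^i + σε_t

α, β are standard normal, the cubic sign is ±1 with equal probability,
and the bifurcation sits at μ = 0 in every family.  μ₀ is drawn
uniformly over the values whose linearised eigenvalue modulus is below
0.8 (U[−1.8, −0.2]; U[−0.9, −0.1] for the fold, where λ = 1 − 2√(−μ)),
so runs start both close to and far from the bifurcation while keeping
noise-induced escapes rare.

Each model is simulated twice from its deterministic equilibrium: a
*forced* run in which μ ramps linearly from μ₀ to exactly 0 over the
600 recorded steps, and a *null* run with μ fixed.  Both begin with a
100-iteration burn-in at μ₀ (noise on — the burn-in exists to reach the
stationary noisy state).  The stored observable is the last 500
recorded points, or the 500 points immediately preceding a transition,
defined as the first deviation from the (moving) equilibrium exceeding
10σ.  For the fold the equilibrium tracked is √(−μ_t); measuring the
deviation against a fixed point instead would flag the deterministic
drift of the branch as a transition (this is covered by a test).  With
σ = 0 the 10σ rule degenerates and an absolute floor of 10⁻³ is used.
Simulations that overflow (the degree-10 tail makes this possible) are
discarded and the model resampled with a fresh seed, keeping class
counts exact; resample counts are recorded in the library manifest.

**Noise amplitude.** The training σ range is a free parameter of the
data-generating recipe.  The default is σ ~ U[0.005, 0.015]: large
enough that fluctuations are visible at the normalisation scale used by
the classifier, small enough that well under 5% of null runs at
|λ| < 0.8 escape the basin during a simulation.  It is exposed in
`build_library(..., sigma_range=...)`.

A library build with n models per class keeps all 5n forced runs
(labelled by family) and a random subset of the null runs (labelled
null), so classes can be balanced exactly; at full scale (10,000 per
class, 10,000 nulls kept) this yields 60,000 entries.

## Classifier

Inputs are censored, normalised and padded to 500 points.  Member 1
sees windows censored at both ends (length L ~ U[50, 500], start
t₀ ~ U[0, len−L]); member 2 sees end-anchored windows (t₀ = len−L), so
it specialises in data close to the bifurcation.  Windows are divided
by their mean absolute value and left-padded with zeros.  Each library
entry is censored once, at preparation time.  For records shorter than
500 points, L is drawn from [50, len]; records longer than 500 keep
their most recent 500 points.

The network is a CNN-LSTM: one 1-D convolution (ReLU) with max
pooling, two LSTM layers with dropout, and a dense softmax over the six
classes (null + five bifurcations).  It is implemented directly on
NumPy arrays — forward pass, full backpropagation through time, and
Adam — which keeps training bit-reproducible from a seed on a single
CPU; the analytic gradients are verified against central finite
differences in the test suite.  Training uses sparse categorical
cross-entropy.  The reference configuration is 50 conv filters, kernel
12, pool 2, LSTM units 50 and 10, dropout 0.10, Adam at 5·10⁻⁴, batch
1024, 200 epochs, and a stratified 0.95/0.025/0.025
train/validation/test split.  Both members share the same split
indices.  Reported predictions are the arithmetic mean of the two
members' probability vectors; the headline score for "any bifurcation
coming" is the summed bifurcation probability 1 − p(null).

**Desk scale.**  Full-scale training (60,000 examples, 200 epochs) is
a multi-hour GPU-class job.  `NetworkConfig.desk_scale()` is the
configuration used throughout the tests: 2,500 training examples
(416 models per class, 420 nulls) and 30 epochs, with the reference
architecture unchanged and only the optimisation rescaled — Adam at
10⁻³ with batch 256 — plus a 0.8/0.1/0.1 split so held-out metrics are
measured on 250 rather than ~60 examples.  This trains in a few
minutes per member on one CPU and reaches held-out multiclass accuracy
≈ 0.75 and binary F1 ≈ 0.98, with the transcritical/pitchfork
confusion expected from their identical linear normal-form terms.
Desk-scale results demonstrate the pipeline's behaviour qualitatively;
they do not measure full-scale accuracy.

**Detrending at inference.**  Training series are raw normal-form
simulations around a known equilibrium and are not detrended.  Applied
models and empirical records have structured trends, so at inference
the classifier consumes detrended residuals — the same residuals as
the classical indicators.  Following the reference protocol, the whole
pre-transition record is detrended once and predictions at a fraction
of the record use the residual prefix up to that point; later data
influence a prediction only through the smooth trend estimate (a
strictly causal per-prefix mode is available, at the cost of smoother
edge artefacts at the evaluation point, which measurably inflate
bifurcation probabilities on null records).  A residual segment that
is identically zero carries no information and returns a flagged
null-dominant vector.

## Classical indicators

Records are detrended with either a Lowess filter (span as a fraction
of series length; default 0.25, used for model runs) or a Gaussian
kernel (standard deviation in samples; default 20, used for interbeat
intervals).  Variance and lag-1 autocorrelation are computed on the
residuals over a trailing rolling window of 0.5 times the *full*
pre-transition length (so an evaluation at 80% of a record uses the
same window size as one at 100%), and trend strength is the
tie-corrected Kendall tau of the indicator against time, over the full
indicator history up to the evaluation point.  Variance uses the population convention
(divide by n; immaterial at these window sizes, but fixed).  Zero-
variance windows yield missing autocorrelation values; an all-equal
indicator series has tau 0 by convention.

The direction of the AC1 trend before a bifurcation depends on the
angle θ of the dominant eigenvalue: for θ ∈ [0, π/2) AC1 increases, for
θ ∈ (π/2, π] it decreases (period-doubling is θ = π).  This law is
checked on simulated normal forms, and fixes the sign convention used
when AC1 trend is a detector score: the score is −tau for
period-doubling models and +tau otherwise (configurable).

## Applied benchmark models

Five noisy maps, each with one control parameter ramped linearly
through a known bifurcation (forced) or held at a far value (null):

| model | system | bifurcation | control, ramp | null | base σ |
|---|---|---|---|---|---|
| fox | cardiac alternans (APD restitution with memory; A=88, B=122, C=40, D=28, τ=180, α=0.2) | period-doubling, T ≈ 198 | T: 300 → 150 | 300 | 0.1 |
| westerhoff | sentiment business cycles (b=0.45, c=0.1, d=0.2) | Neimark–Sacker, a = 24 | a: 10 → 27 | 10 | 0.1 |
| ricker | Ricker with sigmoidal harvest (r=0.75, k=10, h=0.75) | fold, F ≈ 2.36 | F: 0 → 3.54 | 0 | 0.2 |
| lotka_volterra | discrete predator–prey (r=0.5), EWS on prey | transcritical, c = 1 | c: 0.5 → 1.25 | 0.5 | 0.01 |
| lorenz | reduced discrete Lorenz (h=0.5), EWS on x | pitchfork, a = 0 | a: −1 → 0.25 | −1 | 0.01 |

Bifurcations are located numerically: the deterministic fixed point is
found (closed form where available, otherwise Newton iteration with
parameter continuation for the Fox map), and the control value solving
the eigenvalue condition of the Jacobian — eigenvalue −1 for
period-doubling, complex-pair modulus 1 for Neimark–Sacker, +1 for
transcritical/pitchfork, and the tangency system f(x) = x, f′(x) = 1
for the fold — is bracketed and found by Brent's method (tolerance
10⁻⁶).  Tests cross-check each location against brute-force parameter
sweeps.

Forced runs use a 100-step burn-in at the ramp's start value (mirroring
the training protocol; initial states are the corresponding equilibria)
and a ramp whose step increment is set so the pre-transition segment
has approximately the requested length (100–500 points) while the
control still spans its printed interval.  The transition is the
control crossing the located bifurcation value, except the Ricker map,
where it is the population dropping below 0.45 (control crossing is the
fallback if that never happens).  The benchmark grid per model is five
noise amplitudes (base × 2⁰…2⁻⁴) × five lengths × n forced and null
replicates; at full scale n = 100 (5,000 runs per model), the tests use
n = 5.

Detector scores are computed at 80% of the pre-transition data and
pooled into one ROC per detector (scikit-learn's threshold sweep;
verified to equal Mann–Whitney pair counting exactly).  Per-cell ROC
uses each (noise, length) cell's own records.  For interbeat-interval
style evaluation, scores at 10 equally spaced fractions between 60% and
100% are pooled.

## Interbeat-interval pipeline

Optical traces (fixed 40 Hz sampling) are band-pass filtered at
0.1–6.5 Hz with a zero-phase 4th-order Butterworth filter (the filter
family/order is a dialect choice; the passband is the contract).  Beats
are upward crossings of the record mean plus 0.7 standard deviations
(record-level statistics, since the threshold is defined per record);
interbeat intervals are differences of consecutive beat times, and beat
pairs straddling an annotated recording pause are dropped rather than
producing giant spurious intervals.

Period-doubling (alternans) onset is the first beat index at which the
linear-regression slope of the return map — consecutive
(IBI_n, IBI_{n+1}) pairs in a trailing window — falls below −0.95 and
stays below it for the next 10 beats.  The window size is not dictated
by the rule; 10 intervals is used, the smallest window consistent with
the 10-beat persistence requirement, and it is exposed as a parameter.
A window with zero predictor variance has no slope and counts as
not-below-threshold.  On a perfect alternans starting at beat k this
rule fires in [k, k + window_size], so recovered onsets carry a
positive bias of up to one window; the recovery test budget of ±10
beats absorbs exactly this bias.

Null segments are extracted from non-transitioning records at random
positions with uniform random lengths in [100, 500].

**Synthetic recordings.**  The generator emulates an aggregate
recording as an IBI sequence — baseline ≈ 1 s with a slow sinusoidal
drift (±0.05 s over ~300 beats), i.i.d. jitter of 0.01 s, and an
optional alternating component that grows geometrically (factor 1.25
per beat from 0.02 s, saturating at 0.15 s) after a configured onset
beat — rendered as Gaussian pulses (σ = 80 ms) at 40 Hz with additive
trace noise.  It reproduces the features the pipeline depends on
(pulse-train morphology, drift, abrupt-but-growing alternans) but not
others found in real aggregates: no critical slowing down before the
onset, no irregular or bursting rhythms, no recording pauses unless
configured, and no imaging artefacts.  Tests passing on these fixtures
therefore validate the signal-processing chain and the onset rule, not
detection performance on real tissue.

## Numerical and design notes

* All randomness flows through `numpy.random.default_rng` seeds;
  identical seeds give bit-identical libraries, training runs and
  benchmarks (single-threaded).
* The network trains in float32; gradient checks run in float64.
* Mean-absolute-value normalisation is undefined for an all-zero
  window and raises; callers at inference map this to a flagged null
  prediction.
* Rolling windows are trailing (right-edge aligned) so every indicator
  value uses only preceding data; with a fixed absolute window size,
  truncating a record only removes trailing indicator values.
* The fold μ₀ interval [−0.9, −0.1] is slightly narrower than the
  |λ| < 0.8 condition would give ((−0.81, −0.01)); the stated interval
  is used as the sampling contract.
* Whether a trajectory is re-checked for transitions during burn-in is
  left open in the recipe; here only recorded steps are checked, but
  non-finite states during burn-in still mark the model degenerate.

## Known limitations

* Desk-scale classifier metrics are not comparable to full-scale
  training; in particular transcritical recall is low at desk scale
  (the transcritical/pitchfork pair is intrinsically hard to separate).
* The CNN-LSTM is CPU-bound; full-scale training is possible but slow
  (hours), and no pre-trained weights ship with the package.
* `locate_bifurcation` assumes a single eigenvalue-condition crossing
  inside the model's bracket; genuinely new models may need a custom
  bracket or continuation strategy.
* The heart pipeline operates on univariate intensity traces; pixel-
  level processing of camera frames is out of scope.
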