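# Methods

This note documents the models, estimators and numerical choices behind the
package, and what the synthetic benchmarks do and do not establish.

## Scientific setting

Cortical population activity alternates between *synchronized* states
(large slow LFP fluctuations, population-wide burst–silence alternation) and
*desynchronized* states (small fast LFP fluctuations, sustained irregular
firing). The package quantifies, per state, the classical markers of
critical dynamics in pooled spiking activity — neuronal avalanche size and
lifetime distributions, their proximity to a power law, avalanche shape
collapse — and the thermodynamic markers derived from pairwise
maximum-entropy (Ising) models of binarized ensemble activity — heat
capacity peak temperature and entropy. A spatially structured spiking
network model provides ground-truth synchronized and desynchronized regimes
and a testbed for subsampling effects.

## Cortical-state classification (`critstate.states`)

One-second epochs are represented by the channel-averaged multitaper power
spectrum (DPSS tapers, time–bandwidth product 3, 5 tapers; the ±3 Hz
mainlobe this implies is respected by the tests) integrated into 1 Hz bins
over 1–100 Hz. PCA reduces the 100 bins to 3 scores; each score dimension is
divided by its maximum absolute value; k-means (k-means++ with 50 restarts,
fixed seed) is run for k = 2…10 and k is selected by the Dunn index

    DI = min_{i≠j} d(center_i, center_j) / max_k r(k),

with r(k) the maximum center-to-member distance ("radius" reading of the
within-cluster distance; ties break toward smaller k; a clustering of
singletons returns +inf and is flagged degenerate). Clusters receive
semantic names from band powers: the maximal 5–15/1–5 Hz power ratio marks
the fast synchronized state; the remaining clusters are ordered by 1–5 Hz
power (desynchronized lowest, slow synchronized highest).

## Population statistics (`critstate.popstats`)

The population spike train pools all electrodes. When restricted to a state
it is a union of contiguous runs of same-state 1 s segments; inter-spike
intervals are computed within runs only, so no interval spans a state gap.
The population autocorrelation histogram (1 ms bins, ±250 ms) is computed
per segment and averaged; both it and the shift predictor (mean of 100
rate-matched within-segment shuffles) are normalized to a center peak of one
before subtraction, so the corrected curve reads in units of the center peak
with the shuffle baseline at zero. (Normalizing after subtraction is
unstable: the corrected zero-lag bin of uncorrelated data is pure noise.)
The reported area is the enclosed area |curve − baseline| over ±250 ms with
the zero-lag bin removed; a signed integral would cancel the positive and
negative lobes of oscillatory autocorrelations.
The spike-triggered average uses the z-scored same-electrode LFP channel,
averaged over channels; its area is the integral of the negative deflection
between flanking zero crossings.

## Avalanche analysis (`critstate.avalanche`)

Spikes are binned at Δt; an avalanche is a maximal run of bins with count ≥
threshold (inclusive); clusters touching a window edge without a flanking
sub-threshold bin are discarded, with exact spike bookkeeping
(kept + sub-threshold + discarded = binned total). Δt defaults to the mean
population ISI, rounded to the nearest millisecond (floor 1 ms) for
millisecond-resolution recordings; for the network model's full population
train (mean ISI ≪ 1 ms) the exact mean ISI is used, since rounding up to
1 ms would merge entire bursts into single bins.

Size and lifetime samples are compared between a discrete power law
(zeta-normalized, exponent by MLE, xmin fixed at the sample minimum — the
entire distribution is fitted, never an optimized tail) and a lognormal.
The lognormal is discretized (probability mass on [x−½, x+½], renormalized
on x ≥ xmin, μ ≥ 0, σ > 0): comparing a discrete pmf against a continuous
density is inconsistent and lets a boundary-pinned broad lognormal defeat
the power law even on exact power-law samples. The comparison statistic is
the summed loglikelihood difference (positive favoring the power law), its
Vuong-normalized ratio, and a two-sided normal p-value.

Shape collapse follows the mean-profile method: the mean temporal profile of
each lifetime (≥ 20 avalanches, lifetime ≥ 2 bins; the regime comparison
uses ≥ 4 bins to exclude shapeless short clusters) is interpolated onto a
common 100-point grid on (0, 1] (bin i of a lifetime-T profile at scaled
time (i+1)/T, with a (0,0) anchor), amplitude-scaled by T^(1−γ), and the
collapse index CI(γ) is the grid-mean variance across rescaled profiles
divided by the squared range of their mean. γ* is the argmin over a grid
0.5–2.5 in steps of 0.01. A genuine collapse shows a nontrivial exponent
(γ* clearly above 1) with small CI; flat duration-independent profiles
(asynchronous data) return γ* ≈ 1 — amplitudes do not scale and no scaling
function exists — which is how "no collapse" manifests in this estimator.

## Maximum-entropy models (`critstate.mem`)

Ensemble activity is binarized into ±1 patterns (σ=+1 iff ≥1 spike in the
bin); a helper selects the bin size whose mean emission probability matches
a target (0.048 by default, the operating point used throughout). The
pairwise model P(σ) ∝ exp(Σhσ + ½ΣΣJσσ) is fitted by gradient descent on
the moment mismatch (learning rate 0.1, tolerance 0.005 on the maximum
absolute mismatch over all first and second moments, 100 iterations by
default; non-convergence returns the model with a warning flag). Model
moments come from exact enumeration for N ≤ 20 — which removes sampler noise
from tests — or from single-spin-flip Metropolis sampling (5·10⁵ steps,
10⁴ burn-in, seeded) for larger N.

Thermodynamics: temperature rescales all parameters (Ω → Ω/T); the heat
capacity is C(T) = var[E]/T² with E the unscaled-parameter energy of
patterns drawn at temperature T (grid 0.1–3.0, step 0.02). The entropy uses
the thermodynamic identity S(1) = S(T₀) + ∫_{T₀}¹ C(T)/T dT with T₀ = 0.02
and the integral on 200 log-spaced points. The boundary term S(T₀) is the
enumeration entropy at T₀; it reduces to the log ground-state degeneracy as
T₀ → 0 — a term the bare integral misses (the uniform model has C ≡ 0 yet
S = N bits) — and, unlike a degeneracy count, remains correct when fitted
models have quasi-degenerate low-lying states with gaps below T₀. An
internal cross-check against −ΣP log₂P raises beyond 2% disagreement.

State decoding uses Q random N-site ensembles, a contiguous 70/30
train/test split with a random offset per repeat (30 repeats), assignment of
each test distribution to the state model maximizing 1/D_JS (Jensen–Shannon,
natural log), and an exact Binomial(Q·N_states, 1/N_states) 95th-percentile
chance bound. Least-squares slopes of C/N and S/N versus N carry t-based
confidence intervals (half-width t_{n−2} · sqrt(S²/Sxx), S² the unbiased
residual variance); the interval's ~95% coverage is verified by simulation.

## Spiking network model (`critstate.lif`)

2500 conductance-based LIF neurons (70% excitatory) on a 50×50 grid with
25 µm spacing; each ordered pair (i≠j) is connected with probability
exp(−d²/(2·(100 µm)²)) (directed draws; open boundary — no wrap-around —
and no self-connections). Membrane and synaptic parameters are: C = 200 pF,
τ_m = 20 ms, v_rest = −60 mV, v_th = −50 mV, τ_exc = 5 ms, τ_inh = 10 ms,
g_exc = 0.7 nS, g_inh = 50 nS, v_exc = 0 mV, v_inh = −70 mV, 1 ms delay and
1 ms refractory period. Integration is exponential Euler at dt = 0.1 ms
(exact for conductances held constant over a step; halving dt moves pooled
rates by under 5%, a bar plain forward Euler fails at these conductances).
Initial potentials are uniform in [v_rest, v_th).

External drive is an independent Poisson stream per neuron whose every event
moves the membrane by g_ext(v_exc − v)/C, compounded exactly within a step.
The event conductance g_ext is a calibration constant (0.28 nS, ≈0.084 mV
at rest), deliberately distinct from the recurrent excitatory peak: the
regime structure of sparse inhibition-dominated networks places the
synchronous-irregular/asynchronous-irregular transition at the rheobase
drive, so g_ext is set once so that rheobase falls between the two operating
rates. Carrying the recurrent 0.7 nS into the external jump (≈0.21 mV per
event) makes the 6 kHz drive already mean-driving and abolishes the model's
defining dichotomy — both drives then produce asynchronous firing. With the
calibrated value, 6 kHz yields fluctuation-driven population bursts
(population ISI CV ≈ 4–5, tens of percent silent 10 ms bins, avalanche size
exponents near −3/2, lifetime exponents near −2, power law competitive with
the lognormal) and 9 kHz yields asynchronous firing (CV ≈ 1.1, decisively
lognormal size distributions, no profile scaling).

Subsampling removes whole spike trains uniformly at random until the pooled
rate first crosses the target (≤5% undershoot accepted due to discreteness);
Fano stratification computes the per-second Fano factor of the pooled train
(50 ms bins) and partitions segments into quantile bands returned as
labeled recordings.

## Synthetic data generator (`critstate.synth`)

The generator emulates the statistical structure the analysis assumes — a
shared, state-dependent slow rate envelope — not any particular recording.
All channels share one doubly stochastic envelope per state: a von Mises
pulse train w ∝ exp(κ(sin φ − 1)) with κ = 2·atanh(depth) and instantaneous
frequency performing a reflected Ornstein–Uhlenbeck walk inside the state's
band (correlation time 50 ms, so each 1 s epoch samples the whole band and
consecutive epochs of a state have nearly identical spectra). Depth 0 is
homogeneous Poisson firing; deep modulation gives sharp population bursts
separated by near-silent gaps with the harmonic-rich spectrum of cortical
up–down states. Channels fire as Poisson processes with this common
intensity. The five default states occupy distinct narrow bands and depths
(weak 2–5 Hz at 0.05; 6.5–7.5 Hz at 0.75; 10.5–11.5 Hz at 0.88; 2.6–3.4 Hz
at 0.80; 4.1–4.9 Hz at 0.88 with 6 Hz mean rate) so that the five spectral
clusters are close to equidistant in the normalized PC space — the geometry
under which the Dunn index resolves the true number of clusters. States
switch as a symmetric Markov chain on 1 s segments (mean dwell 20 s).

The LFP proxy per channel is −(envelope) − 0.05·(z-scored 20 ms-smoothed
population spike count) + 0.1·(1/f noise): the field integrates far more
neurons than the recorded sample, so its deterministic part is the common
envelope rather than the shot noise of ten channels; population bursts
produce negative deflections, giving the spike-triggered average its trough.
A pulse-train envelope was chosen over exponentiated filtered Gaussian noise
because per-second band power of slow Gaussian noise has ~50% relative
spread (a 1 s window holds a handful of slow-band degrees of freedom), which
makes per-second spectral classification of the generator's own states
unreliable for any classifier.

What the generator does not emulate: electrode-specific rate heterogeneity,
refractoriness and bursting of single units, spatial structure across
channels, volume-conducted artifacts, narrowband alpha ringing, and
non-Markov state dynamics. Passing tests therefore establish that the
estimators recover the structure they target when that structure is present
in a controlled form — not performance bounds on any particular recording.

One consequence of the generator's design deserves emphasis: its
correlations arise purely from shared rate co-modulation, not from
effective interactions. At a bin size matched to a fixed emission
probability, pairwise correlations can only lower the ensemble entropy
below the independent benchmark, so the generator's synchronized state has
slightly *lower* maximum-entropy-model entropy than its desynchronized
state, and the two states' heat-capacity peak temperatures are nearly
equal. The thermodynamic orderings of interest — the more synchronized
regime having its C(T) peak closer to T = 1 and higher entropy — are
properties of genuinely interacting dynamics and are exhibited by the
spiking network model (SI vs AI), where the package's thermodynamic
comparisons are made.

Surrogates: within-window spike-time randomization (uniform redraw inside
each window per electrode; counts per (electrode, window) preserved exactly)
and a rate-matched homogeneous Poisson train per electrode.

## Problem sizes

The bundled analyses and checks use 600 s, 10-channel synthetic recordings;
20 s (SI) and 10 s (AI) network simulations of the full 2500-neuron grid;
10⁵-sample heavy-tail recoveries; N = 6 ensembles with Q = 10 random site
subsets for the thermodynamics; and 10 generator seeds for the end-to-end
state-recovery check. These sizes give stable statistics for every
comparison made (e.g. thousands of avalanches per regime, ±0.02 exponent
recovery) while keeping a full run on one CPU core in the minutes range.

## Known limitations

- The external-drive event size of the network model is a calibrated
  interpretation (see above); all other network parameters are the published
  table values.
- The lognormal/power-law comparison fixes xmin at the sample minimum by
  design; no Clauset-style xmin optimization or third alternative
  (exponential, truncated power law) is provided.
- Entropy via the thermodynamic integral requires exact enumeration
  (N ≤ 20); no sampled-mode entropy is offered.
- The Dunn index inherits its known sensitivity to single outlying segments
  (its denominator is a maximum); on weakly separated data the selected k
  can fall below the generative number of states.
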