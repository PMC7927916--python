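# Methods

## The Poisson hidden Markov model

A recording's multiunit activity is discretized into spike counts per
channel in fixed 10 ms bins (half-open `[t, t+w)`; a trailing partial bin
is dropped so all bins share one width). A latent phase sequence `s_t`
common to all channels follows a first-order Markov chain (initial
distribution π₀, row-stochastic transition matrix **P**); given the phase,
each channel's count is Poisson with mean `λ_js` (emission matrix **Λ**,
stored internally as expected counts per bin; `rates_hz()` converts by
1000/w). Trials are independent sequences sharing the parameters, each
started from π₀ — whether per-trial chains should instead condition on
their first bin is not determined by the procedure we follow, so the
standard shared-π₀ Baum–Welch convention is used.

**Fitting.** Baum–Welch EM with 10 random restarts: π₀ and the rows of
**P** are flat-Dirichlet draws; each emission entry is uniform on
(0, 2 × that channel's mean count). Termination requires *both* a
relative log-likelihood change below 1e-3 *and* a maximum-absolute change
of **P** and **Λ** below 1e-5 (the matrix-change metric is the max-abs
entry difference), with a cap of 500 iterations; hitting the cap flags
the fit as non-converged but is not an error. The restart with the best
final log-likelihood wins, and restarts are seeded individually
(substream per restart index) so each is reproducible on its own. For
K = 1 the M-step lands on the per-channel mean count exactly.

**Numerics.** The forward–backward pass is the scaled linear-space
variant with a per-bin log-shift, which returns the exact log-likelihood
and is underflow-free for at least 10⁴ bins and tens of channels.
Emission log-probabilities are computed as a single matrix product per
iteration (the `log n!` term is precomputed once per dataset). The inner
recursions are numba-jitted when numba is importable, with an equivalent
pure-numpy path otherwise — both are exact, verified against brute-force
enumeration over all `K^T` paths on small instances. Viterbi breaks ties
toward the lower phase index, making decoding fully deterministic (so
with equal emissions and a uniform **P**, the first bin follows
argmax π₀ and later bins fall to phase 0; any such path is a true
maximizer). After fitting, phases are relabeled in increasing order of
population-mean rate, so phase 0 is "Off" and phase 1 "On".

**M-step guarantees.** Rows of **P** and π₀ are renormalized exactly;
states with zero expected occupancy inherit their previous rates rather
than dividing by zero.

## The joint two-area model

The 4-state model enumerates both areas' phases in the canonical order
1 = V1off–V4off, 2 = V1on–V4off, 3 = V1off–V4on, 4 = V1on–V4on. Each
channel's emission rate is constrained equal across the two states in
which its own area keeps the same phase (V1 channels tied across {1,3}
and {2,4}; V4 channels across {1,2} and {3,4}). The tied M-step pools
expected counts and occupancies over each tied pair — the exact maximizer
under the equality constraint — so ties hold to machine precision at
every iteration. Initialization honors the ties (one uniform draw per
tied group), and initialization is purely random (no warm start from
2-state fits). After fitting, states are permuted onto the canonical
order by declaring each area's higher-rate phase its On phase; exact rate
ties break deterministically by state index and raise a flag.

Attention effects are differences between independently fitted
per-condition models, not a shared model with condition covariates. The
scenario contrasts are read off the canonical transition matrix:
`P(1→3) − P(1→2)` (from both-Off, does V4 or V1 switch On first) and
`P(4→2) − P(4→3)` (from both-On, does V4 or V1 switch Off first).

## Model selection

Leave-one-channel-out cross-validation: fit on a seeded random 3/4 of
trials (4 folds by default), decode each held-out trial with channel *j*
removed from the emission likelihood only (transitions untouched), and
score `CVvar[j] = Σ (n_tj − λ_j,s_t)²`. The error curve, averaged over
channels and folds and normalized to the 1-phase model, feeds the elbow
rule: a recording counts as two-phase iff adding the second phase drops
the normalized error by ≥ 10% and no later phase adds another ≥ 10% drop.
Incremental drops are consecutive differences of the K=1-normalized
curve; an alternative mode measures each drop relative to the previous
K's error (`relative_to_previous=True`), since the verbal rule admits
both readings.

## Variance explained

Two-fold cross-validated `R² = 1 − Σ(n_t − λ_s_t)² / Σ(n_t − ⟨n⟩)²` on
held-out trials, decoded with the fitted model. Single-unit mode replaces
the fitted rates with the unit's mean rate over the training trials'
decoded phases. The integration-window sweep (50–500 ms in 50 ms steps)
aggregates counts into windows and predicts each window by the summed
phase rate across its bins. The ceiling is `R²max = 1 − 1/FF` with the
Fano factor from the unbiased variance estimator, computed per window and
averaged across the population. FF < 1 yields a negative R²max and is
reported as-is; zero-mean channels are undefined (NaN).

## Coordination measures

`cc_hmm` mean-subtracts each trial's decoded phase series, normalizes per
trial by `sqrt(Σx²·Σy²)` (so a trial's autocorrelation at zero lag is
exactly 1; a pooled-denominator mode exists), and averages over trials.
Sign convention: with x = V1 and y = V4, `CC(τ)` sums `x(t)·y(t+τ)`, so a
peak at τ < 0 means the V4 series leads. The shuffle predictor averages
the same statistic over 100 derangements of the y trials and is
subtracted to remove event-locked common modulation. The lag-area split
(trapezoidal, τ = 0 excluded from both halves) summarizes the asymmetry.
Trial pairs are truncated to their common length before correlation.

The transition-triggered average (TTA) aligns one area's counts on the
other's isolated transitions (no neighboring transition within 100 ms)
and reports the per-transition mean rate per channel, with a
trial-shuffle predictor. The transition-onset estimate fits two
independent least-squares lines around a grid-searched breakpoint and
reports the lines' intersection; parallel lines (flat traces) are
"missing". Two caveats that shaped the validation design:

- The crossing localizes the kink reliably only when the trace is close
  to two-segment piecewise-linear inside the fitted window. A rise that
  saturates within the window (three regimes) or a curved
  exponential-relaxation rise biases the intersection off the kink.
- A first-order Markov coupling between areas is memoryless: the
  follower's hazard, hence its mean rate, starts moving in the very bin
  of the leader's transition, so such a generator cannot produce a
  positive follower latency. The latency scenario therefore uses an
  explicit-lag generator (the follower repeats the leader's phase
  sequence 20–80 ms later), which is the generative structure that a
  nonzero crossing asymmetry actually reflects.

Event cross-correlograms (`cc_events`) histogram transition-minus-event
time differences and normalize per event (coincidences of transitions per
microsaccade), with the same derangement shuffle.

## Phase dynamics, controls, behavior

Epochs are maximal constant-phase runs; window-edge runs are flagged
censored and excluded from duration statistics but included in occupancy
(which therefore equals the duration-weighted epoch fraction exactly).
Transition-time densities use 100 ms bins normalized per second and per
trial. The attention modulation index is
`(A_RF − A_out)/(A_RF + A_out)`, undefined at 0/0.

Rate matching thins higher-rate conditions per channel by independent
(binomial) spike deletion with probability `1 − target/current`, the
target being the lowest condition mean; thinned counts never exceed the
originals and Poisson thinning preserves the Fano factor. Equality of the
post-hoc means is statistical (the thinning is random); the validation
experiment sizes the data (8 channels, 600 trials × 300 bins per
condition) so the residual fluctuation stays well under 1%.

Baseline pupil diameter is generated (and in real data would be measured)
over a pre-stimulus window; the coupling statistic is the per-recording
Pearson correlation across trials between baseline pupil and the mean
uncensored epoch duration of a phase or joint state.

The behavioral table assigns each qualifying trial (target inside the
RFs, reaction time present) the decoded phase or joint state of the bin
containing the target-dimming time (half-open bins; an event on a bin
edge belongs to the bin starting there) and exports a tidy
(condition, state, RT) table. The mixed-effects fit
`RT ~ attention * state` itself is delegated to standard statistics
packages; the package computes the per-recording mean RT per state used
in nonparametric comparisons.

## Signals

Common-average and bipolar (superficial-minus-deep) re-referencing;
energy as the plain sum of squares; the current source density as the
unscaled second spatial difference over the 150 µm contact spacing (exact
on quadratic depth profiles). The MUA envelope rectifies the wide-band
signal and low-passes it with a 5th-order Butterworth at 300 Hz
(second-order sections; the transfer-function form of that filter is
numerically fragile at 30 kHz). SNR per channel is
`(Signal − Noise)/σ_noise` over eight 50 ms response windows (30–80 …
100–150 ms post-stimulus) against a −200…−50 ms baseline; inclusion
requires SNR strictly above 3 in at least one window. The response
latency model is an exponentially modified Gaussian plus a cumulative
Gaussian, fitted by bounded nonlinear least squares from a 3 × 3
multi-start grid; the latency is the earliest time the fitted curve
reaches 33% of the non-dissipating component's asymptote `c`.

State-conditioned spectra use epochs longer than 250 ms, zero-padded to
1024 samples (epochs longer than the pad are split into non-overlapping
1024-sample segments), multitapered with 7 DPSS tapers at NW = 4
(K = 2NW − 1), averaged within state over 4–200 Hz; the change statistic
is `100·(On − Off)/Off` per frequency, and for the joint model any
requested state-pair contrasts. FDR correction is Benjamini–Hochberg
step-up (statsmodels), verified in tests against a hand-rolled step-up.
Receptive-field maps combine per-channel z-maps by Stouffer's method
(`ΣZ/√k`; a `ΣZ/k` variant is available behind a flag), threshold at
z = 3, and report the supra-threshold centroid, the overlap as a
proportion of the V1 RF, and the center separation.

## Microsaccade detection

Eye position (220 Hz) is differentiated by central differences and
low-passed at 20 Hz with a 2nd-order zero-phase Butterworth. The
per-trial, per-component threshold is six times the robust SD
`sqrt(median(v²) − median(v)²)` of the velocity (the estimator is applied
to velocity, standard practice; a position mode exists behind a flag),
combined elliptically: an event needs
`(vx/6σx)² + (vy/6σy)² > 1` for ≥ 3 consecutive samples. Events closer
than 20 ms merge; runs touching the first or last 3 samples are dropped
(filter edge artifacts). Amplitude and direction come from the position
displacement between onset and offset. Detection is translation-invariant
and the threshold scales linearly with velocity noise.

## The synthetic generator

One simulated recording emulates: a joint 4-state latent chain per trial
(condition-specific transition matrices; the V4-lead asymmetry is encoded
as `P(1→3) > P(1→2)` and `P(4→2) > P(4→3)`, attention as a bias toward
On-entering transitions); per-channel Poisson counts (defaults Off
20 spikes/s, On 100 spikes/s with mild log-normal channel heterogeneity,
per-bin stay probabilities ≈ 0.95–0.98 — the ~100 Hz multiunit regime the
model targets); spike times placed uniformly within bins; task-event
delays drawn from the uniform ranges used for monkey 1 (fixed 614 ms
fixation→stimulus, cue 618–1131 ms after stimulus, first dimming
1162–2133 ms after cue, later dimmings 792–1331 ms apart); reaction times
`base + offset(joint state at target dimming) + N(0, σ)` truncated at
zero; baseline pupil linear in the trial's mean On-epoch duration plus
noise; 220 Hz eye traces with white positional noise and raised-cosine
(20 ms) microsaccade displacement pulses at Poisson times with a 100 ms
refractory gap, optionally coupled to forced Off→On transitions 60 ms
later; and a laminar LFP surrogate of AR(1) (1/f-like) noise, a 5 Hz
component gated to Off phases, a 60 Hz component gated to On phases, and
a Gaussian mid-layer dipole so the CSD has a known sink. Every draw flows
from the master seed through named substreams, so equal configs are
bit-identical; all generative parameters and latent ground truth ride on
the bundle's metadata.

What the generator does *not* emulate — and what passing tests therefore
do not show about real data: refractoriness and non-Poisson count
dispersion, stimulus-driven transients and adaptation, laminar
heterogeneity of On-Off timing, genuine oscillatory structure, slow
nonstationarities, and (except where noted) conduction delays between
areas. Two validation scenarios deliberately add features the plain
generator lacks because the statistic under test is degenerate without
them: the variance-explained scenario runs the latent chain at 1 ms
resolution and adds a slow per-trial gain drift (with bin-aligned
transitions and no extra dispersion, cross-validated R² concentrates *at*
the ceiling R²max and a one-sided comparison against it is meaningless),
and the TTA-latency scenario uses the explicit-lag coupling described
above.

## Validation problem sizes

The standing experiments (`onoffstate.experiments`, re-run by
`scripts/acceptance.py` and asserted by `tests/test_acceptance.py`) use:
exact inference on 100 random instances with T ≤ 8, K ≤ 4, ≤ 3 channels;
single-area recovery at 16 channels, 100 trials × 300 bins, 10 restarts;
joint tied recovery at 2 × 8 channels, 60 trials × 200 bins; the
cross-correlation skew on 30 sessions of 30 trials × 150 bins fitted with
3 restarts; model selection on 50 + 50 recordings of 8 channels,
24 trials × 100 bins, K ≤ 3, 2 folds, 2 restarts; the shuffle predictor
on 500 trials; 200 crossing-recovery replicates; microsaccade detection
on 200 trials of ≈ 5–6 s; 30 sessions each for the RT and pupil
linkages; and the rate-matching control on 600 trials × 300 bins per
condition. At the single-area recovery size the 5% rate-recovery margin
is close to the sampling floor (the per-rate standard error is ≈ 1.6%,
and the worst of 32 rates sits near 3 SE), so occasional excursions just
past 5% at unlucky seeds reflect estimator variance, not bias.

## Known limitations

- Semi-Markov (explicit-duration) structure, non-Poisson emissions,
  input-driven transition rates and models with more than two areas are
  out of scope.
- The two-line crossing is a coarse onset estimator; see the caveats
  above. Real TTA traces should be inspected before trusting it.
- The HDF5 bundle layout is this package's own; readers for vendor
  acquisition formats are not provided.
- Spike detection/sorting from raw voltage is upstream of this package.
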