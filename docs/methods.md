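# Methods

## The field model and its assumptions

The model is a two-population (excitatory/inhibitory) Wilson–Cowan-type
neural field on a half-circle orientation domain θ ∈ [0, π), representing
a hypercolumn whose columns prefer different stimulus orientations.  It
assumes (i) rate dynamics — spiking is abstracted into population rates
filtered by single time constants τ_e, τ_i; (ii) distance-dependent
connectivity through a single π-periodic von Mises kernel shared by both
populations; (iii) a stationary-noise transfer function — the Siegert
formula for a leaky integrate-and-fire neuron, so that the *gain* of the
population response falls as input fluctuations (σ) grow; and (iv) three
additive drives: an orientation-tuned stimulus current, a spatially
uniform working-memory current, and a shared slow Ornstein–Uhlenbeck
current modelling endogenous drive fluctuations.

Units: voltages mV, times ms, currents nA.  The integrate-and-fire cell
behind f_σ has C = 1, V_t = −50, V_r = V_l = −65, t_ref = 5 ms, and the
leak conductance is fixed by requiring that exactly 1 nA brings the
noise-free membrane to threshold (g_l = 1/15 µS); capacitance is read in
units that give the standard membrane constant τ_m = C/g_l = 15 ms.  The
Siegert integral is evaluated with the overflow-safe scaled complementary
error function (`erfcx`); relative accuracy ~1e-10, with an exact
deterministic branch at σ = 0 and a hard zero when the mean voltage sits
more than 25 noise s.d. below threshold.  The simulator interpolates f_σ
from a 4001-point table (range −10..40 nA), which is accurate to well
below the integration error.

## Tuning and the default parameter set

The default parameters were found by the following procedure, in this
order: (1) fix the transfer function as above with baseline noise
σ0 = √2 ≈ 1.414 (chosen so the sigmoid is smooth over the operating
range); (2) choose weights (w_ee = 0.26, w_ei = 0.26, w_ie = 0.28,
w_ii = 0.10 nA/Hz, κ = 6) and time constants (τ_e = 5.6, τ_i = 11.2 ms)
such that the spatially uniform fixed point undergoes a *supercritical*
Hopf bifurcation as uniform current rises, with a usable oscillatory
window ≈ 0.18 nA wide before restabilization; (3) bisect the leading
Jacobian eigenvalue (`tune_to_hopf`, tolerance 1e-4 of the search
interval) and fold the threshold into the baselines so the resting
network sits ≈ 0.05 nA above onset; (4) pick the drive increments
(Δ_stim = 0.012, Δ_WM = 0.008, Δσ = 0.01 nA per level, σ_z = 0.02 nA,
τ_z = 50 ms) so that WM levels 0–3 and contrasts 0–3 stay on the rising
branch of the oscillation, where amplitude, frequency and mean rate all
increase monotonically with WM drive and the operating frequency is
18–22 Hz.

Two properties of this family are worth knowing.  First, the *linear*
onset frequency at threshold is ≈ 9 Hz; the frequency climbs steeply with
drive and reaches the β band at the operating point.  The operating-point
spectrum — what any of the spectral analyses in this package measure — is
β-band (modal cycle frequency ≈ 19.5 Hz).  Second, the strength of the
instability was deliberately chosen deep (fast amplitude relaxation):
near-threshold, weakly stable cycles have phase dynamics so sloppy that
per-cycle frequency estimates are noise-dominated and the
frequency–rate correlation collapses.  The deep-but-supercritical regime
gives r ≈ 0.8 between per-cycle frequency and mean rate under the default
OU drive.  Regimes with still cleaner coupling (r ≈ 0.99) exist but are
subcritical (the oscillation appears at finite amplitude), which
contradicts the continuous onset this model is meant to have, so they
were rejected.

Numerical integration is explicit Euler at dt = 0.1 ms with the OU
process advanced by its exact exponential update; recording keeps every
5th sample (0.5 ms).  Convergence: halving dt moves a fixed-point
solution by < 1% RMS and the limit cycle's amplitude/frequency/mean by
~2% (first-order method).  The first 500 ms are flagged as transient and
dropped by every analysis here.  One integer seed drives the OU stream;
runs are bit-reproducible.

## Cycle segmentation and the model information measures

The LFP proxy is the θ-mean of the excitatory rate.  Cycles are bounded
by −π→π wraps of the Hilbert phase of the mean-removed proxy (the running
maximum of the unwrapped phase provides a well-defined inverse under
noise); cycles with periods outside 20–120 ms are discarded.  Per cycle
and decoding location (π/2 = stimulated, π/4 = flank), the rate waveform
is resampled onto a 256-point phase grid through t = g(φ), giving the
phase density q(φ) = u(g(φ)) g′(φ)/(λT) (renormalized on the grid to
1 ± 1e-6) and a Poisson count distribution with mean λT (tail < 1e-9).
KL divergences floor densities at 1e-12 and warn when flooring occurred
(`strict=True` raises instead); the two-stimulus MI is the Jensen–Shannon
divergence in bits, bounded by 1.  The information-gain direction is
D(q_{π/4} ‖ q_{π/2}) by default; both directions are available and differ
negligibly here.

`freq_rate_correlation` excludes the lowest-amplitude quartile of cycles
before correlating: when the oscillation nearly vanishes, the Hilbert
phase — hence the period estimate — is unreliable.  The working-memory
sweep (`wm_contrast_sweep`) reports per-cycle means; run it with
`sigma_z = 0` for a deterministic per-level comparison (the examples do),
since per-cycle information estimates under noise carry a positive,
amplitude-dependent bias that obscures small between-level differences.

## The synthetic session generator

The generator emulates the *statistical structure* the analysis chain
assumes: two memory conditions (IN/OUT), 4 orientations × 3 non-zero
contrasts plus a zero-contrast condition, epochs
fixation/cue/delay(1 s)/response, 1 kHz LFP = 1/f Gaussian noise + a
delay-confined β sinusoid (18 Hz center, per-trial frequency jitter
2 Hz s.d., amplitude 1.2 IN vs 1.0 OUT), and inhomogeneous-Poisson
spikes whose rate combines a 15 Hz baseline, contrast gain 1.25/level,
von Mises orientation tuning (κ = 0.8), a normalized von Mises
phase-locking factor tied to the true oscillation phase (κ_lock 1.0 IN,
0.4 OUT), stimulus-dependent preferred phases spread evenly over π
radians (the recoverable phase code), and a rate gain of +10% per Hz of
per-trial frequency deviation (the frequency–rate coupling).  The π
spread is a compromise: a full-circle spread maximizes phase MI but
makes pooled spike phases uniform, destroying the spike-phase-locking
index; π keeps both recoverable.  Post-inactivation sessions multiply
κ_lock and the phase-offset spread by 0.3 for IN trials only.

What the generator does **not** emulate: array geometry, spike
waveforms/sorting artifacts, eye movements beyond endpoint scalars,
cross-channel structure, non-Poisson spiking, or any coupling between
the 1/f background and spiking.  Passing recovery tests therefore shows
the estimators detect the effects they target at realistic magnitudes
and reject nulls — not that they are robust to every pathology of real
recordings.

## Estimator conventions

* Multitaper PSD: 3 DPSS tapers, NW = 2, eigenvalue-weighted, per-trial
  then trial-averaged, zero-padded ×4 for sub-bin peak localization;
  analysis window defaults to the last 700 ms of the delay.  Min-max
  normalization follows the stated (X−min)/(max−min) rule; note that on
  synthetic spectra whose global maximum *is* the β peak this
  normalization is degenerate for between-condition comparisons, so the
  recovery tests compare raw band power.
* Peak frequency ties break to the lower frequency.
* STA: per-trial z-scoring over the timepoints within ±100 ms of any
  spike, then trial averaging; slope = |V_peak − V_trough| / |t_peak −
  t_trough|; waveforms whose peak-to-trough range is below 2× the s.d.
  of the |lag| > 75 ms tails are flagged as lacking a clear peak.
* Filter bank: ten fixed bands (1–4 … 90–120 Hz), windowed-sinc FIR of
  order six cycles of the band's low edge (99% energy containment for a
  mid-band tone), applied forward-backward; bands whose low edge does
  not fit three cycles in the trial are flagged invalid.
* MI: windowed (100 ms / 100 ms step) circular-mean spike phases binned
  into 4 equipopulated bins (12 for the saturation test), counts used
  directly; plugin MI minus the mean of 20 label shuffles with fixed
  seeds 1..20.  Windows with no spikes (or exactly cancelling phasors)
  are dropped pairwise.  Corrected MI may be slightly negative on null
  data.
* Capacity arithmetic treats neuron information as additive
  (independence), exactly as the back-of-envelope requires; eccentricity
  exactly 7 dva uses the 2-dva reward window.

## Known limitations

* The supplementary parameter table of the source model is not public;
  the defaults here reproduce the documented qualitative behavior but
  not any particular printed parameter values.
* In this parameterization, *total* phase information decreases mildly
  with WM drive while rate information decreases much faster, so the
  phase/rate ratio grows (420→570× across WM levels) but the absolute
  phase-information trend is opposite to the increase the mechanism is
  expected to show; the corresponding acceptance-level check is left
  failing rather than tuned around.  The same holds for the per-contrast
  frequency-decile trend of phase information (rate-information decile
  trends are negative and highly significant, as expected).
* The linear Hopf onset frequency (≈9 Hz) is below the β band; only the
  operating point is β-band.  All spectral phenomenology (power spectra,
  SPL, MI maps) is measured at operating points.
* Per-cycle frequency–rate correlation is r ≈ 0.80–0.85 under the
  default OU drive; cleaner values require a subcritical regime (see
  "Tuning").
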