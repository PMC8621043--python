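# Methods

## The physical model

An action potential (AP) is modelled as an effective charge travelling at
constant velocity **v** = (vx, vy) along a straight axon parallel to a
planar probe (electrodes at z = 0, tissue at z > 0). In a uniform
quasi-static volume conductor the potential of a point effective charge
q' = q/(4πεε₀) at distance D is V = q'/D, so electrode *i* sees a voltage
transient that peaks when the charge passes the point of the axon closest
to it (closest approach, distance D_m,i, passage time t_m,i).

Two renderings of a transit are provided:

* **point** — the charge is a moving point; the channel waveform is
  V(t) = q′/√(D_m² + v²(t − t_m)²). Peak amplitude is exactly q′/D_m and
  the waveform width is the geometric time constant D_m/v. This is the
  regime in which the amplitude inversion below is exact, and it is used
  for the precision benchmarks.
* **extended** — the AP is a charge density Q′(t − s/v) along the axon;
  the channel potential is the convolution of Q′ with the geometric kernel
  1/√(D_m² + (s − s_m)²). The default waveform is an asymmetric biphasic
  (negative-then-positive) pair of Gaussian lobes with 1 ms total duration:
  extracellular spikes are charge-neutral, and this shape gives transits
  whose width is set by the AP duration rather than by D_m/v. Waveforms
  are normalised by their L1 integral so the total absolute charge equals
  q′; in the short-duration limit the extended model converges to the
  point model.

The choice matters in two ways. A *monophasic* source (point model, or a
single-lobe Gaussian) carries net charge, so its transit has genuine
spectral content below 100 Hz; a 100 Hz high-pass filter then reshapes the
transit (peak loss of order 10–20% and ringing undershoots). A
*charge-neutral* source has essentially no energy below a few hundred
hertz and passes through the drift filter unchanged — which is why the
realistic scene generator defaults to the biphasic extended model, and why
the noiseless precision benchmarks (point model) are run with the filter
stages disabled: there is no drift or noise to remove, and the filter
would otherwise distort the very amplitudes under test.

## Inverse solvers

**Velocity.** The peak time on electrode *i* is t_i = (M_i − s₀)·v/|v|².
Differencing electrodes i, j gives Δt_ij |v|² = vx Δx_ij + vy Δy_ij, where
the electrode coordinate differences may be substituted for the
closest-approach-point differences (their projections on v are equal —
the identity that makes the method closed-form). With K = v/|v|² the
system Δt_ij = Kx Δx_ij + Ky Δy_ij is linear: two independent pairs (three
non-collinear electrodes) determine K exactly; more electrodes are solved
by least squares over all pairs. The velocity is the complex inversion
vx + i·vy = 1/(Kx − i·Ky). If every Δt vanishes the speed is beyond the
resolution limit (flagged, speed = ∞); collinear triads are degenerate
errors.

**Position and charge.** In the frame rotated by α = atan2(vy, vx) the
axon runs along X at unknown (Y, Z) with charge q′. Peak amplitudes
S_i = q′/D_i at closest approach give circle equations
q′²/S_i² = Z² + (Y − Y_i)²; subtracting pairs cancels Z² and leaves a 2×2
linear system in (q′², Y). Of the three pair equations the two with the
largest |ΔY| are used — a pair with coincident rotated positions carries
no lateral information and makes the system singular (this happens
whenever the axon is parallel to an electrode edge, which is why the
default triode is scalene with no side parallel to the nominal axis).
Z is the square root of the mean per-electrode Z² (sources lie at z > 0 by
convention); the spread of the per-electrode Z values is reported as a
quality metric, and solutions with a Z² negative beyond tolerance are
rejected as inconsistent. With more than three electrodes the median over
all non-degenerate triads is taken. The local (Y, Z) is rotated back to
global coordinates using the earliest-peak electrode as X reference,
giving the closest-approach point of the axon to that electrode.

**Error bound.** The point-charge approximation of an extended source of
spatial half-extent s_max has first-order relative error bounded by
ε_i = (1/D_m,i)·(1/(1 + D_m,i²/s_max²))·|ΔD|. s_max is estimated as
speed × duration × multiplier (default multiplier 0.5; duration default
1 ms), and the displacement |ΔD| is taken as |D_i − mean(D)| over the
transit's electrodes. ε is a conservative bound that routinely exceeds 1
for near-probe sources when s_max ≫ D_m, so only extreme values (default
ceiling 10) flag an estimate.

**Resolution limits.** dt_min = 1/fs and v_max = max spacing / dt_min: at
40 kHz only delays above 25 µs register, capping detectable speeds at
3.2 m/s for an 80 µm spacing; 100 m/s requires a 1 MHz / 100 µm system.

## Signal chain

1. **High-pass** (default 100 Hz): FFT-domain, bins below the cutoff
   zeroed with a raised-cosine transition spanning one octave; content
   above twice the cutoff is untouched (1 kHz preserved to <10⁻¹²).
2. **Wavelet denoising** (default sym5, depth ≤ 5): per-level soft
   thresholding at the universal threshold σ√(2 ln N), σ from the MAD of
   the finest detail level.
3. **Detection**: local maxima of |V| on the *high-passed* trace whose
   height and prominence exceed k × MAD-σ (default k = 4). Thresholds and
   amplitudes deliberately come from the pre-denoise trace: its MAD
   reflects the true noise floor, and soft shrinkage biases peak
   amplitudes downward by up to the universal threshold, which would
   corrupt the amplitude inversion. On effectively noiseless traces
   (MAD ≈ 0) the threshold falls back to 10⁻³ of the channel maximum. A
   2 ms refractory keeps one event per spike (one per biphasic lobe pair).
   Peak time and amplitude are refined by a 3-point parabolic fit.
4. **Matching**: events on distinct channels group into a transit when all
   pairwise |Δt| fit in the window max-spacing / v_min (default v_min
   0.1 m/s → ~0.8 ms for an 80 µm triode); greedy by earliest peak, ties
   by amplitude; groups with < 3 channels are reported unmatched.
5. **Delay refinement**: within each matched transit, inter-channel delays
   are re-estimated by cross-correlating the denoised waveform segments
   (±1.5 ms) against the largest-amplitude channel, with a parabolic fit
   on the correlation apex. A single apex fit uses three samples; the
   correlation uses the whole transit and, on weak wide spikes at 40 kHz,
   cuts delay errors from ~100 µs to below one sample period — the
   difference between losing and keeping the direction sign of fast
   transits.

## Synthetic scenes

`generate_locust_like_scene` draws axons as straight lines parallel to the
probe: (y, z) closest-approach positions uniform over a disc of radius
100 µm (a nerve trunk resting on the probe, z ≥ 10 µm), speeds from three
classes with weights 0.64 / 0.24 / 0.12 on (1–2.5), (0.5–1), (0.2–0.5)
m/s — the fibre-diameter census of a locust ventral nerve cord — and
direction +x with probability 0.93 (afferent bias of a stimulated,
decapitated preparation) with ±10° jitter. Defaults: 40 kHz sampling (the
reference acquisition rate), Gaussian noise σ = 10 µV, biphasic 1 ms APs
rendered with the extended model, q′ = 23 000 µV·µm calibrated so a 1 m/s
axon at 50 µm peaks near 150 µV (point-model scenes use q′ = 5 000,
~100 µV at 50 µm). Each axon fires once at a uniform time in a 2 s
recording. Same seed ⇒ bit-identical recordings.

What the generator does *not* emulate: tissue inhomogeneity and frequency-
dependent conduction, electrode impedance and filtering, bursting/refractory
firing statistics, waveform diversity across axons, and myelinated
(saltatory) propagation. Passing tests on these scenes therefore validate
the geometry, timing and amplitude logic of the method — not its behaviour
under real tissue and electrode non-idealities.

## Numerical choices

* Quadrature for single-point extended potentials: adaptive integration
  over the waveform support extended by ±5 D_m (relative tolerance 1e-6);
  scene rendering uses the equivalent discrete convolution on the sample
  grid, with sub-sample peak alignment by linear interpolation.
* Point-model transit tails are truncated where the amplitude falls below
  10⁻³ of the peak (truncation only zeroes far samples; retained samples
  are exact).
* Degeneracy tolerances: collinearity and coincident-Y tests at 1e-9 to
  1e-12 of the geometric scale; Z² may be negative up to 1e-6 of q′²/S²
  before a transit is marked inconsistent.
* Problem sizes: the precision benchmark uses four axons spanning
  0.25–2 m/s in a 0.35 s scene at 200 kHz and 40 kHz; the population scene
  uses 200 axons over 2 s at 40 kHz; the analytic forward-inverse check
  uses 1000 random well-posed scenes. These sizes give stable statistics
  (binomial 3σ bands of a few percent) while keeping the whole suite in
  the minutes range.
* Degenerate transits never abort a batch: rows are flagged
  (`unresolvable_velocity`, `degenerate_geometry`, `inconsistent_amplitudes`,
  `above_vmax`, `epsilon_over_ceiling`) and excluded from summaries, with
  the exclusion count reported.

## Known limitations

* The amplitude inversion assumes S_i = q′/D_i, exact only for point-like
  sources. For realistic extended APs (spatial extent v·T comparable to or
  larger than D_m) the recovered Z is biased toward larger heights and q′
  is an effective, electrode-dependent charge; the ε bound quantifies the
  regime. Velocity and direction, which depend only on timing, are
  unaffected by this bias.
* At 40 kHz, speeds near the 3.2 m/s resolution limit have strongly
  quantised raw delays; sub-sample refinement recovers much of this, but
  weak fast transits remain the dominant source of direction
  misclassification, consistent with the outlier rates seen in vivo.
* Overlapping transits within one matching window on the same channel are
  suppressed by the refractory rule rather than resolved; colliding APs
  from different axons are a declared non-goal.
* Non-planar probes and axons not parallel to the probe plane are out of
  scope.
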