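# Methods

## Model of phonation onset

The voice onset is modelled as the growth of the cycle-peak envelope of the
glottal area waveform (GAW) from a small initial oscillation to saturated,
sustained phonation. Near the oscillation threshold the vocal folds behave
like a dynamical system passing a Hopf bifurcation, which gives the
analytic envelope

    M(t) = r0 * [(1 - xi) * exp(-2 a t) + xi]^(-1/2),   xi = (r0 / r_sat)^2

with M(-inf) = 0, M(0) = r0 (the first-cycle amplitude) and
M(+inf) = r_sat (the saturation amplitude). The growth rate `a` (s^-1)
controls the transition speed. The 32.2 -> 67.8 % crossing interval of M is
exactly (1/2a)·ln((1-c1²)c2²/(c1²(1-c2²))) = 0.99766/a, which is why `a`
is treated as the reciprocal of VOT_67 and why the M family never reports
VOT_90. Polynomial envelopes P2/P3/P4 make no dynamical assumption; they
are pure least-squares smoothers of the peak series and measure VOT by
locating threshold crossings numerically.

The adopted closed form of M deserves a note: it is fixed by three
requirements simultaneously — M(0) = r0, the t -> ±inf limits above, and
the reciprocal-of-a property — and these pin it down uniquely.

## Measurement chain and its assumptions

* **Normalization** divides by the maximum area within the first syllable,
  taken as the first 40 % of the total signal duration. Everything
  downstream is dimensionless.
* **f0** is estimated on the first 180 ms: autocorrelation of the
  mean-removed window, the best *local* autocorrelation maximum at lags
  between 1/500 and 1/50 s, refined by parabolic interpolation. Requiring a
  local maximum (rather than an argmax over the lag range) makes a window
  shorter than ~2 cycles fail loudly instead of returning a range edge.
* **Band-pass (GAW_f)**: Butterworth of overall order 4 (order-2 low-pass
  prototype transformed to a band-pass), pass band 0.7–1.3·f0, applied
  forward–backward. Zero-phase filtering is a deliberate choice: VOT is a
  time measurement, and one-directional filtering would bias peak times by
  the group delay. The squared magnitude response of the two passes still
  satisfies the band contract (f0 passed at >= 0.9 amplitude, 4·f0 and
  0.2·f0 attenuated by >= 20 dB, DC removed).
* **Cycle peaks**: one per cycle; cycles are delimited by the minima
  between consecutive maxima (unfiltered) or by negative-to-positive zero
  crossings (filtered, which oscillates about zero). Flat maxima resolve
  to their earliest sample. A peak is "preceded by closure" when the
  signal reached the closure threshold (default 0.005 normalized units —
  true closure gives exactly 0, segmentation noise motivates a small
  positive epsilon) since the previous peak; for filtered signals closure
  is judged on the paired unfiltered signal, since a zero-mean waveform
  carries no closure information.
* **Saturation amplitude** r_sat = maximum of the kernel-5 central moving
  average of closure-preceded peak amplitudes within the first syllable.
  Peaks before the first vocal-fold contact are excluded from the average
  (at the very start the folds oscillate without touching and those
  amplitudes understate the cycle energy). The last peak inside the
  maximizing window bounds the fit domain.
* **Fit-point selection**: unfiltered fits use only peaks after first
  contact; filtered fits use all peaks up to the bound. At least 3 peaks
  are required.
* **Fitting**: M variants use bounded trust-region least squares
  (a ∈ [1, 1000] s⁻¹, r_sat ∈ [0, 2], r0 ∈ [0, 1]) with multi-start
  a ∈ {10, 50, 200} s⁻¹, r_sat initialized at the measured cma maximum and
  r0 at the first fit-peak amplitude. Each richer variant is additionally
  warm-started from the previous variant's solution and keeps it unless
  improved, so the nesting inequality rmse(M_asr) <= rmse(M_as) <=
  rmse(M_a) holds structurally, not just statistically. The model clock is
  anchored at the first selected fit peak (t = 0 there), consistent with
  M(0) = r0. Polynomials are solved on times rescaled to [-1, 1] for
  conditioning, by minimum-norm least squares when underdetermined
  (deterministic), with coefficients reported in the original ms basis.
  The reported RMSE is always over genuine cycle peaks; the residual
  including the supporting point is kept as a separate attribute because
  the order-nesting inequality P4 <= P3 <= P2 applies to that quantity.
* **VOT crossings** are located on a dense grid plus bisection (default
  refinement 1e-4 ms). The lower threshold must be crossed *from below*:
  a fit that sits above 32.2 %·r_sat over its whole trusted domain yields
  a non-computable VOT. This is precisely the failure mode of polynomials
  without the supporting point, which rise toward early times; treating a
  high left-boundary value as a "crossing" would silently hide it.
  Polynomial crossings are only trusted on [supporting point, last fit
  peak] — beyond the data a polynomial diverges. The M envelope is
  analytic on all of t and monotone, so its domain is extended leftward
  until it drops below the lower threshold. With multiple crossings
  (oscillatory polynomials) the first lower crossing and the first later
  upper crossing count.
* **Corpus statistics**: reliability = percentage of recordings with a
  computable VOT; VOT mean/SD over computable recordings (sample SD,
  n-1); RMSE mean/SD over the recordings whose VOT_67 was computable for
  that family/variant. Reporting precision mirrors clinical tables:
  reliability and VOT to integers, RMSE to two decimals (the unrounded
  table is always available).

## Synthetic generator

`generate_gaw` builds r(t) = E(t) · max(0, (sin(2πf0·t) − c)/(1 − c))^q
where E follows M(t) with chosen (a, r0, r_sat) and the per-cycle offset c
is below −1 for the first `n_open_cycles` (minima stay positive: no
vocal-fold contact) and −0.2 afterwards (minima clip at zero: full
closure). Defaults describe a female-range onset at 8000 fps: f0 = 200 Hz,
a = 25 s⁻¹ (VOT_67 ≈ 40 ms), r0 = 0.1, r_sat = 1, two open cycles, 600 ms
duration (so the 40 % first-syllable window contains a saturated plateau).

Noise model: the default `noise_sd = 0.02` is *per-cycle amplitude
jitter* — each cycle's amplitude is scaled by 1 + N(0, 0.02) — which
perturbs peak amplitudes the way segmentation errors do while leaving the
closed phase at exactly zero, keeping closure detection well-posed.
Additive white sample noise and slow baseline drift are available
separately (defaults 0) to exercise the band-pass stages; white noise at
amplitudes comparable to the closure epsilon would make first-contact
detection ill-posed for any detector, which is a property of the problem,
not of this implementation. Ground truth stores the crossing-convention
VOT_67 = 0.99766·1000/a ms, the reciprocal 1000/a, the true f0 and the
first-contact sample read off the clean rectified waveform.

`generate_frames` renders the GAW as a dark vertical ellipse (area
proportional to the GAW) on bright tissue with multiplicative 50 Hz
flicker and an additive high-frequency grid, emulating the artifacts the
frame-enhancement steps target. Per-frame min–max stretching cancels the
multiplicative flicker exactly up to 8-bit quantization.

What the generator does **not** emulate: segmentation dropouts, glottis
shape change and mid-line drift, aperiodicity/jitter of f0 within the
onset, camera motion, and real closure residue (posterior chinks). Passing
tests therefore demonstrate correctness of the measurement chain under the
stated signal model, not segmentation robustness on clinical recordings.

## Numerical choices and degenerate inputs

* Growth-rate/crossing arithmetic is done in seconds internally, ms at all
  interfaces; frequencies in Hz; `a` in s⁻¹.
* Envelope evaluation guards overflow for t ≪ 0 (returns 0) and keeps
  r0 < r_sat strictly inside the optimizer via a 1e-9 margin.
* Constant frames, all-zero first syllables, windows without periodicity,
  fewer than kernel-many eligible peaks, fewer than 3 fit peaks, and
  coincident peak times raise typed errors; absence of vocal-fold contact
  and non-computable VOT are *valid results*, not exceptions (unfiltered
  fitting does require contact, since no fit peaks remain without it).
* All randomness flows through one seeded `numpy` generator passed
  explicitly; identical seeds give bit-identical signals and reports.

## Problem sizes

Default analyses run on 600 ms of 8000 fps signal (4800 samples, ~120
cycles). The parameter sweeps cover a ∈ [1, 1000] s⁻¹ (13 log-spaced
points) × ξ ∈ [1e-6, 0.5] (8 points); recovery studies use 100 seeded
replicates; corpus studies use 20–50 synthetic recordings with
a ∈ [15, 60] s⁻¹ and f0 ∈ [180, 240] Hz. These sizes give stable
statistics for every criterion while keeping a full run in the tens of
seconds.

## Known limitations

* Glottis segmentation is out of scope: the pipeline starts from the GAW
  (the in-vivo segmentation tool that produced the study corpus is not
  publicly described). The frame-enhancement front end is provided and
  tested, but only a trivial threshold read-back links frames to areas in
  tests.
* The first syllable is defined as the first 40 % of the signal duration,
  not by linguistic segmentation; recordings with a different temporal
  layout need a custom `syllable_fraction`.
* f0 estimation assumes a quasi-stationary onset within 180 ms; strong
  intra-window f0 glides can bias the band edges.
* VOT_90 on polynomials inherits the supporting point's least-squares
  compromise: the fitted value at the supporting point is near but not
  exactly zero, so envelopes whose early peaks sit above ~5 % of r_sat may
  be VOT_90-non-computable while VOT_67 succeeds — the reliability
  ordering expected of the two definitions.
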