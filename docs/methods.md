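# Methods

This note documents the models, algorithms and parameter choices behind
`uwbvitals`, in enough detail to judge what the package's tests do and do not
demonstrate.

## Echo model and simulator

A stationary subject at nominal range d₀ presents a chest wall at

    d(t) = d₀ + m_b sin(2π f_b t + φ_b) + m_h sin(2π f_h t + φ_h)
              + a_d sin(2π f_d t + φ_d)

(respiration, heartbeat, optional whole-body drift). Each received frame is

    r(t, τ) = Σ_i A_i p(τ − τ_i) + A_T p(τ − τ_d(t)),     τ_d = 2 d(t)/c

with static multipath amplitudes/delays (A_i, τ_i) and target echo strength
A_T. The pulse p is a Gaussian-envelope cosine at 7.29 GHz; its envelope
width is set so the −10 dB spectral width equals the 1.4 GHz bandwidth. One
fast-time sample per range bin at 23.328 GS/s gives a bin spacing of
c/(2·f_s) ≈ 6.43 mm, and the simulator evaluates the pulse directly on that
range grid. Additive white Gaussian receiver noise (σ = 0.02 per sample
relative to a unit echo) completes a frame.

The essential mechanism this preserves: at a bin near the target, the
slow-time signal is cos(φ₀ + β sin 2πf t) with modulation depth
β = 4π f_c m / c ≈ 0.31 rad per millimeter of displacement. Millimeter
respiration (β ≈ 0.6–1.8 for humans) is therefore a *nonlinear* phase
modulation: it produces harmonics and intermodulation sidebands, and the
component amplitudes go as Bessel functions (fundamental ∝ J₁(β)), with
carrier-phase nulls at unlucky bins. The pipeline must and does cope with
all of this; idealized sinusoidal amplitude modulation would hide it.

Two consequences worth knowing:

* Localization accuracy is bounded by the pulse's range resolution
  c/(2B) ≈ 107 mm, not by the 6.4 mm bin: the maximum-energy bin avoids
  phase nulls and can sit 2–3 bins from d₀. Tests assert the physical bound.
* Strong respiration (m_b ≳ 5 mm) pushes harmonic energy (J₂, J₃ terms at
  2f_b, 3f_b) into the heartbeat band. For humans this is harmless — any
  heart-band mode is still far weaker than respiration, so the label is
  unaffected — but heart-*rate* estimates are only reliable when the
  heartbeat component exceeds that harmonic leakage.

### Species presets

Defaults are chosen once as realistic resting-subject conditions and are
fully configurable:

| species | f_b (Hz)  | f_h (Hz)  | m_b (mm) | m_h (mm) | drift | echo A_T |
|---------|-----------|-----------|----------|----------|-------|----------|
| human   | 0.2–0.5   | 1.0–1.7   | 2–6      | 0.1–0.4  | —     | 1.0      |
| dog     | 0.2–0.45  | 1.3–2.0   | 1–3      | 1–3      | —     | 1.0      |
| cat     | 0.2–0.5   | 1.6–2.4   | 0.5–2    | 0.5–2    | —     | 0.5      |
| rabbit  | 0.8–1.4   | 2.6–4.2   | 0.3–1    | 0.1–0.3  | 1 mm, 0.06–0.14 Hz | 0.5 |

Rationale. Frequency ranges bracket observed resting rates (human 0.35/1.35,
dog 0.3/1.65, cat 0.3/1.85 Hz; rabbits breathe above the human range).
Human chests are respiration-dominant by an order of magnitude; dog and cat
chests put comparable motion into the heartbeat (thin tissue over a heart
seated against the front ribs), so their two amplitude intervals coincide —
and because an independent draw from identical intervals cannot express
which component dominates, the drawn pair is oriented heartbeat-dominant
for species whose lung-to-heart weight ratio falls in the pet regime (see
below). Dogs at 10–22 kg are torso-scale targets with human-strength echoes,
which is exactly why the energy gate cannot reject them; cats and rabbits
present roughly half the echo amplitude (smaller radar cross-section) and
much smaller displacements, so the gate catches most of them. Rabbits fidget:
a 1 mm sub-0.15 Hz body-drift term is included, and their fast breathing
falls inside the *human* heart band — their decomposition therefore has no
respiration-band vital mode, only residual drift, reproducing the known
failure-of-index-based-mode-labelling case.

The LHWR → amplitude-ratio link `amplitude_ratio_from_lhwr` is a power law
(affine in log-log) anchored at LHWR 1.5 → ratio 1 and LHWR 3 → ratio 10.
No quantitative anatomical law justifies any particular curve; this one is
strictly increasing, positive, puts every tabulated pet value (1.12–1.50) at
or below 1 and the human value (≈3) well above, and is used only to orient
preset draws.

The slow-time frame rate (20 frames/s), record length (20 s, N = 400
frames) and noise level are stated choices: 20 frames/s comfortably
oversamples the 5 Hz analysis band, and 20 s resolves 0.05 Hz in the
spectrum — fine enough to separate any two preset rates.

## Preprocessing

DC/clutter removal subtracts a sliding mean along slow time per range bin.
Edge windows are shifted inward so every window spans exactly Q frames;
interior windows are centered. Q defaults to the full record, i.e. global
per-bin mean subtraction, which is exact for these 20 s records and makes
the operation idempotent. The low-pass is a 101-tap Hamming windowed-sinc
FIR at 5 Hz cutoff, applied zero-phase by default (single pass on a
reflect-padded record, centered samples kept: no group delay, no startup
transient); a causal mode with the inherent 50-frame delay is available for
real-time use.

## Energy gate

E_x = Σ_n s_x(n)² per bin after preprocessing; the target is the argmax (ties
to the smaller index). The detection range is split into M = 5 segments
(segment length ⌈X/M⌉ bins); each segment's human reference energy is the
mean located-target energy of calibration human recordings falling in it,
and uncovered segments inherit the nearest calibrated value (flagged).
α_E = E_ref(segment)/E_target; α_E < 10 proceeds to decomposition, α_E ≥ 10
is labelled animal, boundary included (rejecting a pet is the safe error in
monitoring). Energy standards are duration-specific: calibration and test
recordings must share record length, as E scales with N.

## VMD

The decomposition minimizes the summed bandwidth of analytic,
frequency-shifted modes subject (softly, τ = 0) to reconstruction. Spectral
ADMM updates:

* mode: û_k(ω) = (f̂ − Σ_{i≠k} û_i + λ̂/2) / (1 + 2α(ω − ω_k)²)
* frequency: ω_k = ∫₀^∞ ω|û_k|² dω / ∫₀^∞ |û_k|² dω
* dual: λ̂ ← λ̂ + τ(f̂ − Σ û_k), with τ = 0 by default (VMD as a filter
  bank; exact reconstruction is not enforced on noisy data).

α is dimensionless with frequencies in cycles/sample; defaults K = 4,
α = 9000, tolerance 10⁻⁶ (summed relative squared mode change), max 500
iterations. Initialization is uniform over the band (deterministic); zero
and seeded-random schemes are available. The input is mirror-extended by
half its length at each end and trimmed after inversion. Modes are reported
sorted by center frequency.

Numerical choices:

* **Duplicate-mode consolidation.** When K exceeds the number of narrowband
  components, surplus modes converge onto an existing component and split
  its energy — which would silently halve a band's measured energy. Modes
  whose center frequencies end within the Wiener half-power bandwidth
  1/√(2α) of each other are summed (energy-weighted center frequency); by
  the decomposition's own resolution they are one component. A flag restores
  strict fixed-K output.
* **Analysis rate.** The pipeline decimates the target's slow-time signal to
  twice the low-pass cutoff (20 → 10 Hz; the 5 Hz FIR is already the
  anti-alias filter) before decomposition, so uniform initialization spreads
  all K modes across the occupied band rather than parking some in the band
  the filter emptied.
* An empty mode (all-zero spectrum) keeps its previous center frequency; a
  zero input returns zero modes, converged, immediately. Non-convergence is
  reported via a flag, not an exception.
* Boundary fidelity: with τ = 0, spectral spread caused by the mirror
  extension's derivative kink is attenuated by the Wiener filters, so a few
  percent of reconstruction error concentrates in roughly the outer
  half-filter-length of the record; signals whose phase reflects smoothly
  (cosine-like at the record ends) reconstruct to ~1–3%.

## Classification

u_r is the highest-energy mode with center frequency in [0.1, 0.7] Hz, u_h
likewise in [0.8, 2.5] Hz (human bands; boundaries inclusive; an index-based
compatibility mode exists). RHER is the time-domain energy ratio; the label
is human iff log₁₀(RHER) > 0, the boundary going to animal. The log-threshold
0 (RHER = 1) encodes "respiration-dominant chest = human" directly; observed
cohorts separate by 1.5–3 decades around it. A band with no mode yields an
explicit *indeterminate* outcome instead of a forced label. Rates are the
quadratically interpolated FFT magnitude peaks of the selected modes
(±0.05 Hz at 20 s records).

## What the synthetic tests show — and what they don't

The simulator reproduces the displacement-to-echo physics (Bessel-series
amplitude structure, harmonics, phase nulls, multipath clutter, drift,
white noise) under the preset study conditions: single stationary subject at
1 m, calm, 20 s records. Passing cohorts therefore demonstrate that the
pipeline implements the discrimination mechanism correctly and robustly
*under those conditions*. They do not demonstrate performance on real
recordings, which add posture- and subject-dependent echo structure,
non-sinusoidal breathing waveforms, sensor phase noise, gross body motion,
through-furniture propagation, or multiple simultaneous subjects — all out
of scope here.

Known limitations: one target per cube; energy standards tied to record
duration and geometry; heart-rate estimates degrade when respiration
harmonics dominate the heart band; borderline animals with m_b ≈ m_h sit at
RHER ≈ 1 by construction, and a few percent of simulated dogs land on the
human side of the threshold — mirroring the field observation that no single
energy- or rate-based statistic separates dogs perfectly.

## Problem sizes

Default test and acceptance runs use 20 s × 20 frames/s records (400
frames, ~750 range bins over 0.2–5 m), 5 calibration humans, and cohorts of
20 subjects per species; the full suite runs in well under a minute on one
CPU.
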