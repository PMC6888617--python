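# uwbvitals

Human/animal discrimination for impulse-radio ultrawideband (IR-UWB) radar
vital-sign monitoring.

## The problem

Contactless monitors (sleep trackers, infant monitors, heart-rate sensors)
watch a subject's chest through the sub-millimeter modulation it imprints on
radar echoes. House pets break them: a dog, cat or rabbit resting in the beam
has respiration and heart rates inside the human range, so rate-based checks
cannot tell it from a person, and the monitor raises alarms on a perfectly
healthy pet. `uwbvitals` implements a two-stage discriminator that works on
stationary subjects, where gait-based methods do not apply, plus a
physics-based echo simulator so the whole chain can be developed and tested
without radar hardware or animals.

## The method

A recording is a radar data cube S(x, n): X range bins (fast time) by N
frames (slow time). The pipeline runs four steps:

1. **Preprocessing.** Static clutter is removed by subtracting a sliding mean
   along slow time per range bin, then a linear-phase FIR low-pass at 5 Hz
   keeps only the physiological band.
2. **Initial identification.** The slow-time energy E_x = Σ_n s_x(n)²
   localizes the subject at the maximum-energy bin. The gate statistic
   α_E = E_human(segment) / E_target compares it against a per-range-segment
   human reference calibrated from known human recordings; α_E ≥ 10 means the
   echo is far too weak to be a person → **animal**. Small pets usually stop
   here; dogs do not (their echoes are human-strength), which is why a second
   stage exists.
3. **Vital-sign acquisition.** The target bin's slow-time signal is
   decomposed by variational mode decomposition (VMD): K = 4 narrowband
   modes u_k with center frequencies ω_k, found by ADMM with Wiener-filter
   mode updates and power-centroid frequency updates (balancing parameter
   α = 9000, tolerance 10⁻⁶).
4. **Classification.** The respiration mode u_r (largest-energy mode with
   ω ∈ [0.1, 0.7] Hz) and heartbeat mode u_h (ω ∈ [0.8, 2.5] Hz) give the
   respiratory-and-heartbeat energy ratio

       RHER = Σ_t u_r(t)² / Σ_t u_h(t)²

   Human chests are respiration-dominant (lung-to-heart weight ratio ≈ 3);
   pet chests put comparable or more motion into the heartbeat (LHWR
   1.1–1.5, heart close behind the front ribs). log₁₀(RHER) > 0 → **human**,
   otherwise **animal**.

The simulator renders the standard echo model — a static multipath background
plus a pulse echo whose delay follows the chest displacement
d(t) = d₀ + m_b sin(2πf_b t) + m_h sin(2πf_h t) (+ body drift) — with a
Gaussian-envelope 7.29 GHz pulse on a 6.4 mm range grid, reproducing the
carrier-phase mechanism that turns millimeter motion into slow-time amplitude
modulation. Species presets (frequency/amplitude ranges, drift, echo
strength) live in `uwbvitals.physio`.

## Worked example

```
$ uwbvitals -q demo -n 2 --seed 0
species        seed   alphaE           stage1  log10RHER          label
human    1826701615     0.91  human-candidate       1.72          human
human    1367864807     1.33  human-candidate       2.07          human
dog      1097657232     3.83  human-candidate      -0.49         animal
dog       579362556     2.71  human-candidate      -0.68         animal
cat       661058652    13.27           animal                    animal
cat        87989972    11.88           animal                    animal
rabbit    161576974    46.61           animal                    animal
rabbit     35492827    43.19           animal                    animal
human accuracy 100%, animal accuracy 100%
```

Reading the table: both humans sit near the calibrated human energy
(α_E ≈ 1) and show strongly respiration-dominant decompositions
(log₁₀RHER ≈ +2). The dogs also pass the energy gate (α_E ≈ 3–4 < 10) — the
gate alone cannot reject them — but their heartbeat-dominant chests give
log₁₀RHER < 0 and the RHER stage labels them animal. The cats and rabbits
never reach the decomposition: their echoes are 12–47× weaker than the human
standard.

The same flow is available programmatically:

```python
from uwbvitals import run_pipeline, synthesize_subject
from uwbvitals.study import calibrate_from_simulated_humans

standard = calibrate_from_simulated_humans(n_subjects=5, seed=11)
report = run_pipeline(synthesize_subject("dog", seed=2), standard)
print(report.final_label)          # animal
print(report.alpha_e)              # ~2–4: passed the energy gate
print(report.classification.log10_rher)  # < 0: rejected by RHER
```

Other CLI subcommands: `simulate` (write a cube file), `calibrate` (build an
energy standard from human recordings), `classify` (one recording → report),
`decompose` (dump the VMD modes of a recording).

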