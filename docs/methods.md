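# Methods

## Signal model

An FMCW radar transmits chirps whose frequency ramps linearly from the
start frequency `fc` over a bandwidth `B` in `Tc` seconds. Mixing the echo
of a reflector at distance `d` with the transmitted chirp gives a complex
IF sample stream

```
x_IF(t) = α·A_T · exp( j( 2π·(B/Tc)·t_d·t + 2π·fc·t_d ) ),    t_d = 2d/c
```

after dropping the residual video phase term `π(B/Tc)t_d²` plus oscillator
phase noise, which is negligible at the sub-11 m ranges modelled here. The
first phase term is the beat frequency (distance → frequency), the second
is the displacement channel: a chest movement of `Δd` advances the phase by
`4π·Δd/λ`, about 2.5 rad per millimetre at λ ≈ 4.98 mm.

The synthesizer freezes each target's distance within a frame
(stop-and-hop): chest velocity times the 50 ms frame period is far below
the 4 cm range resolution. Chirps within a frame are concatenated along
fast time — with the vital-sign preset (256 kept ADC samples × 2 chirps)
one second of data forms the 20 × 512 × n_rx cube, one range profile per
frame from the frame's first chirp, so the slow-time rate is the frame rate
(20 Hz). All receivers carry the same deterministic signal plus independent
circularly-symmetric complex Gaussian noise; `noise_std` is the total
per-sample noise standard deviation, so a unit-amplitude echo at
`noise_std = 10^(-SNR_dB/20)` has the stated per-sample SNR. The speed of
light is taken as 3·10⁸ m/s throughout.

**ADC window.** The preset's `Fs·Tc ≈ 275` samples per chirp is more than
the 256 samples the cube geometry implies; the ADC window is modelled as
the first `samples_per_chirp/Fs` seconds of each ramp. The range transform
zero-pads the kept window to the nominal chirp length `round(Fs·Tc)` so the
bin spacing equals the range resolution `c/(2B)` (4.00 cm rather than the
4.3 cm an unpadded 256-point transform would give); bin `b` is centred at
`b·d_res`, 0-based. Parseval holds for the unwindowed transform with the
`1/N_fft` energy normalization.

## Synthetic data

Chest displacement is two superposed tones around a baseline stand-off:
breathing (default peak 4 mm) and heartbeat (default 0.3 mm), standard
magnitudes in the radar-vitals literature for a seated subject; neither the
morphology of real respiration nor heart-rate variability is modelled.
Body movements are raised-cosine displacement bumps (default 2 cm over
1 s) at Poisson times (default 2/min). The clinical reference is emulated
at exactly 125 samples/s: a Gaussian-derivative pulse per heartbeat (beat
timing only, no PQRST morphology) and a respiration sinusoid sharing the
chest model's breathing phase, plus per-second HR/BR readouts equal to the
ground-truth rates (optional jitter). Radar and reference share one time
origin, so the two modalities are synchronous by construction.

Cohorts draw ages uniformly on [0, 13) years. Vital rates fall linearly
with age — HR = 150 − 6·age bpm, BR = 40 − 1.8·age bpm — with 8 %
lognormal inter-individual spread, clipped to stay inside the extraction
bands; this pediatric-norm map is what makes the age groups statistically
separable. Height follows a simple growth curve (50 cm at birth, ~85 cm at
2 y, +6 cm/y after) with 4 % noise; weight comes from a BMI draw centred
on 16.7 kg/m², so BMI ≡ weight/height² by construction. Every generator is
deterministic under its seed.

What passing tests show, and do not show: the pipeline recovers two-tone
sinusoidal motion embedded in Gaussian noise and clutter; real chest
signals are neither sinusoidal nor stationary, and real movement artifacts
are not raised cosines, so quantitative results here do not transfer to
clinical recordings — the synthetic study is a correctness and sensitivity
harness, not a clinical validation.

## Extraction chain

1. **Range-FFT** per frame after per-frame DC (fast-time mean) removal;
   receiver 0 and the frame's first chirp by default, with an optional
   coherent receiver average.
2. **Subject detection**: the bin with maximal slow-time variance of the
   *complex* profile series, ties toward the nearer bin. The complex
   variance (not magnitude variance) is essential: at 60 GHz even
   millimetre motion rotates the bin's phasor through several radians, so
   the variance concentrates at the magnitude-peak bin, whereas the
   magnitude's variance peaks on the response-kernel flank one bin away,
   where the kernel null makes the phase unusable. A bin with zero variance
   everywhere raises `NoMotionDetected`.
3. **Displacement**: unwrapped phase of the selected bin's slow-time
   series, scaled by λ/(4π) and mean-removed. Unwrapping tracks excursions
   beyond λ/4 provided the frame-to-frame change stays below λ/4
   (~2.5 cm/s at 20 fps); faster motion aliases and leaves λ/2 steps —
   that regime is exactly what the movement index flags.
4. **Band separation**: zero-phase (forward–backward) order-4 Butterworth
   bandpass filters, breathing 0.1–0.7 Hz and heart 0.9–3.0 Hz. The
   filter family, order and cutoffs are this package's choices: the
   pediatric bands (breathing to 42 breaths/min, heart 54–180 bpm) are
   disjoint so the dual-filter design is well posed, and the zero-phase
   filtering keeps radar and reference aligned for validation.
5. **Rate estimation**: sliding 15 s windows, 1 s stride, Hann taper, 8×
   zero padding, in-band magnitude-spectrum maximum with quadratic
   log-magnitude interpolation. At the 20 Hz slow-time rate this gives
   ~4 bpm pre-interpolation resolution and well under 1 bpm after.
6. **Movement index**: per window, the maximum 2 s short-time RMS of the
   chest *velocity* component outside the union of the two vital bands
   (bands removed by full-record spectral masking, which has no filter
   edge transients), normalized by the fastest unambiguously trackable
   velocity λ/4·fps. Working on velocity rather than displacement keeps
   the index local when phase-slip steps contaminate the unwrapped trace,
   and the short-time maximum keeps a 1 s burst from being diluted by the
   15 s window. Pure in-band vitals score ≈ 0.05; a 2 cm/1 s movement
   scores ≈ 0.3–0.7. Windows above the default threshold 0.2 carry NaN
   rates and `valid = False`: vital signs are only reported while the body
   is at rest.

Rates are invariant to overall cube amplitude scaling (the chain is
phase-based after bin selection).

## Agreement statistics

Radar windows are paired with the nearest per-second reference readout (no
interpolation), dropping movement-flagged windows. ICC(2,1) — two-way
random effects, absolute agreement, single measurement — is computed from
the two-way ANOVA mean squares,
`(MSR − MSE) / (MSR + (k−1)·MSE + (k/n)(MSC − MSE))` with k = 2; the
absolute-agreement single-rater form is the standard choice for method
comparison. Bland–Altman uses the n−1 sample SD and the 1.96 multiplier
for the 95 % limits of agreement. The Kruskal–Wallis statistic compares
the pooled rank distributions of the two series (two groups, tie-corrected,
χ²₁ approximation); note this tests distributional difference, not paired
agreement — a small p-value means the distributions differ, and the report
deliberately returns (H, p) without interpreting them further, since the
inverse reading sometimes seen in applied work is not adopted here.

## Age classification

One 30 s range-FFT image per participant (600 frames at 20 fps),
log-compressed and min-max normalized; an all-zero cube renders an
all-zero image. The 4-/3-/2-group schemes partition [0, 13) at
{3, 6, 9}, {4, 8} and {6} years, half-open intervals with boundary ages
joining the older group. Splits are participant-disjoint and stratified:
test quotas allocated across groups by largest-remainder rounding of the
proportional shares, sampled within-group by seed. The reference backend
is a nearest-centroid classifier on three deterministic features of the
image's highest-variance column: dominant temporal frequency in the
breathing band, dominant frequency in the heart band, and the band
log-energy ratio, z-scored with training statistics. Heavier image
classifiers (e.g. CNNs) plug in through the same `fit`/`predict`
interface; the shipped backend exists to exercise the framework
deterministically, not to chase image-classification ceilings.

## Dataset bundles

`Rawdata/P###.h5` (complex64 IF cube, radar config embedded as a JSON
attribute), `VitalSign/P###.h5` (reference waveforms and per-second rates;
radar-extracted vitals CSVs are written alongside as `P###_vitals.csv`),
`Participants/participants.csv`, and a JSON manifest (format version,
participant count, creation seed, config). HDF5 objects are written with
timestamp tracking disabled and sorted key order, so identical inputs
produce byte-identical bundles. A `.incomplete` marker exists during
writes; readers refuse bundles that still carry it, and validate folder
structure, manifest consistency and per-participant file presence without
reading any array payloads. Cubes are stored as complex64: the simulated
noise floor sits far above float32 quantization.

## Problem sizes and numerical choices

The shipped studies use the vital-sign acquisition geometry with a single
receiver for bulk simulation (the extraction chain reads one receiver by
default): 60 s recordings for rate recovery and agreement (46 analysis
windows each), 31 s for classification images, 10 participants for
agreement studies and 50 (24 boys / 26 girls) for classification cohorts.
The noise-sensitivity grid spans σ ∈ {0.3, 1.5, 4.0} around the
unit echo amplitude — from effectively clean to a bin-level SNR near one
after the 256-point coherent FFT gain — and is evaluated with movement
censoring disabled so window exclusion cannot mask the degradation.
Degenerate inputs are handled explicitly: empty echo lists give zero
cubes, zero-variance profiles raise `NoMotionDetected`, constant reference
series make regression and ICC raise instead of returning NaN, and
all-tied Kruskal–Wallis input raises rather than dividing by zero.

## Known limitations

* Two-tone chest motion with no respiratory sinus arrhythmia, HRV, or
  harmonic content; movement artifacts are parametric bumps.
* Single-subject scenes; no angle-of-arrival or MIMO processing, no
  clutter-map subtraction beyond per-frame DC removal (raw cubes are
  preserved so alternative clutter-removal schemes can be compared).
* Motion faster than ~2.5 cm/s radial aliases the phase channel; such
  intervals are flagged, not corrected.
* The reference emulation reproduces beat timing and breathing phase only,
  not ECG morphology or impedance-pneumography physics.
* The classifier backend is a deliberately simple spectral model; absolute
  accuracies are properties of the synthetic cohort and backend, not of
  any deep model on real recordings.
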