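# Methods

This note documents the models, numerical choices and validation strategy
behind `liebauflow`, in the order the pipeline uses them.

## Measurement model

The quantity of interest is the net volumetric flowrate `Q` through a
valveless pumping loop, measured by filming tracer particles in a straight
transparent observation tube. The tracked, time-averaged tracer velocity
`v` is a centerline-type measure: the ~0.5-mm tracers are large relative to
the 3-mm lumen, are entrained toward the axis, and are imaged at the tube
mid-plane. The conversion to mean flow is

    Q = k_w · A · v

with `A = πr²` the lumen area and `k_w` the centerline-to-mean correction
for the operating pulsatile regime.

### Womersley regime and k_w

The regime is set by the Womersley number `Wo = r·√(ρω/µ)`, with
`ω = 2πF` the angular compression frequency. The fundamental oscillatory
mode in a rigid circular pipe is

    u(ξ) ∝ 1 − J₀(i^{3/2}·Wo·ξ) / J₀(i^{3/2}·Wo),   ξ = r/R ∈ [0, 1]

(`J₀`: Bessel function of complex argument, via `scipy.special.jv`). The
package defines `k_w` as the ratio of the cross-section-averaged to the
centerline time-averaged velocity *magnitude* of that mode,

    k_w(Wo) = 2 ∫₀¹ |u(ξ)|/|u(0)| · ξ dξ,

evaluated by composite-Simpson quadrature on 513 uniform radial nodes
(≥ 257 required; the Stokes layer at `Wo = 50` is still resolved by ~10
nodes) and clamped to `[0.5, 1]`. Limits: `k_w → 0.5` as `Wo → 0`
(parabolic profile; exact closed form) and `k_w → 1` as `Wo → ∞` (flat
profile). `k_w` is monotone non-decreasing in `Wo`. `Wo = 0` returns the
Poiseuille limit rather than an error; below `Wo = 0.05` the closed-form
parabola is used to avoid a 0/0 in the Bessel ratio. Tests compare the
Simpson value against an independent trapezoid quadrature at 10× node
density (agreement ≤ 1e-3).

Published worked numbers in this literature imply `k_w ≈ 0.668` for the
3-mm tube at 2.5 Hz with water; our quadrature definition gives
`k_w(Wo=5) = 0.666` but `k_w(6.10) = 0.767` at that tube's actual `Wo`.
The closed form behind the published value is not available, so the
quadrature definition above *is* the package's contract; the worked-triple
consistency check therefore treats 0.668 as an input, not as a prediction
of this model. Whether the original analysis evaluated `Wo` with the
observation-tube or the compliant-segment radius is unknown; the package
always uses the geometry it is given.

### Multi-harmonic waveforms

All corrections use the fundamental mode only. The compression waveforms
here are pulse trains whose Fourier content is dominated by the
fundamental; higher harmonics see larger effective `Wo` (flatter profiles,
larger `k_w`), so the single-harmonic `k_w` is a mild underestimate for
very peaky waveforms. This is a known approximation, shared with the
Doppler-ultrasound use of the same correction.

## Closed-form calculators

| quantity | formula | units |
|---|---|---|
| Young modulus | `E = g·m·L/(A·ΔL)` | Pa |
| compression frequency | `F = 1/(t_on + t_off)` | Hz |
| Moens–Korteweg speed | `c = √(E·h/(ρ·d))` | m/s |
| natural frequency | `F_n = c/(2L)` | Hz |
| peristaltic reference | `Q = F·A·P` | m³/s |
| Poiseuille scaling | `R ∝ µ·L/r⁴` | arbitrary |

`g` is fixed at 9.81 m/s². The tensile-test type accepts strains up to 1:
the soft silicone used for compliant segments is linear over that whole
range, so the 100 % secant modulus equals `E`. All internal units are SI;
the reporting layer converts to mm/s, µl/s, ml/min, cP and kPa
(µl/s → ml/min is exactly ×0.06).

The glycerol–water viscosity uses the Cheng (2008) exponential-mixing
correlation: `µ = µ_w^α µ_g^{1−α}` with temperature-dependent component
viscosities and a mass-fraction-dependent exponent, valid 0–100 °C.
Mixture strengths are volume fractions as prepared, converted to mass
fractions with a glycerol density of 1.26 g/ml; this interpretation
reproduces the six working-fluid viscosities (0.95–2.26 cP at 22 °C)
within 1.5 %, whereas reading them as mass fractions misses the top of the
range by ~15 %.

## Synthetic scenes

The generator emulates the laboratory video well enough to validate every
pipeline stage against known truth. Defaults mirror the recordings:
60 frame/s, three 30-s clips, ~8 particles in view, 0.05 mm/px (a 0.5-mm
tracer spans 10 px).

* **Waveform.** Each compression cycle contributes a raised-cosine rise
  over `t_on` followed by an exponential decay (time constant `t_on`)
  over `t_off` — particles advance in a burst per compression and coast
  between, without claiming pump mechanism. The per-frame cross-section-
  mean series is rescaled *after* discretization so its time average times
  `A` equals the requested flowrate exactly (the conservation invariant is
  exact, not approximate). Modes: `forward` (non-negative), `symmetric`
  (zero-mean shuttle superposed on the target mean — the mid-tube pincher
  case), `constant` (steady flow, the exact-kinematics reference).
* **Kinematics.** Each particle gets a hidden radial fraction drawn
  area-uniformly in `[0, 0.2]` of the radius and a fixed transverse
  coordinate (thin-slab projection; no radial migration, no out-of-plane
  motion). Its axial velocity is the centerline series (mean series ÷
  `k_w`) times the Womersley profile at its radial fraction. Confining
  tracers to the core is what makes the tracked aggregate a centerline
  measure, matching the `Q = k_w·A·v` model; with the default extent the
  profile across the core deviates from the centerline by ≲ 2 %.
* **Stationarity.** Particles are seeded uniformly along the window plus a
  virtual upstream extension sized from the total centerline displacement,
  so in-view density is stationary over the clip without an explicit
  arrival process.
* **Noise.** Detections are true positions plus isotropic Gaussian jitter
  (default 0.5 px), thinned by a miss probability (default 5 %), plus
  single-frame false positives (default 0.5/frame). Rendered stacks draw
  dark discs with one-pixel anti-aliased edges on a light background plus
  Gaussian sensor noise (sd 2 gray levels). The pixel-coordinate
  convention is continuous: pixel `(i, j)` covers `[j, j+1) × [i, i+1)`.
* **Determinism.** Per-clip RNG streams are `default_rng([seed, clip])`;
  a fixed seed gives byte-identical detection tables.

What the generator does **not** emulate: real optics (depth of field,
refraction through the tube wall), radial particle migration, particle
inertia or slip, wall deformation, secondary flows, or the pump's true
position/frequency dependence — sweeps impose the generating flowrate
through a declared amplitude model. Passing tests therefore demonstrate
correctness of the *measurement chain*, not fidelity of a pump simulation.

## Tracking

* **Detection.** One Otsu threshold for the whole stack (per-frame
  thresholds flicker on sparse scenes); dark pixels are connected-component
  labelled and reduced to darkness-weighted centroids (sub-pixel). Blobs
  under 25 % of the expected particle area are discarded. Verified
  accuracy: ≤ 0.04 px RMS for fully visible, well-separated discs; discs
  clipped by the frame border or merged with a neighbour are outside the
  contract.
* **Linking.** Consecutive-frame correspondence is a rectangular
  minimum-cost assignment (`scipy.optimize.linear_sum_assignment`) on
  Euclidean distance, gated at `max_link_distance`: it maximizes the
  number of within-gate links, then minimizes their total distance. This
  is deterministic and input-order independent (ties broken by sorting
  detections lexicographically by frame, x, y); tests verify equality with
  a brute-force enumeration oracle on small instances.
* **Gap closing.** A second global gated assignment joins track ends to
  later track starts (gap ≤ `max_gap_frames` frames, distance ≤
  `max_gap_distance`); chains are stitched and each closed gap recorded.
  A step bridging a k-frame gap divides its displacement by k+1 frames.
* **Gates.** `LinkerConfig.for_peak_velocity` sets
  `max_link_distance = 1.5 × (peak per-frame displacement) + 4σ_jitter`.
  The jitter allowance matters: without it, jittered steps near the pulse
  peak exceed the gate and are preferentially dropped, biasing slow-flow
  estimates low by up to ~20 %. Default `min_track_length` is 5
  detections. No motion model, no track splitting/merging — the algorithm
  family is nearest-neighbor plus gap closing by design.

## Flow quantification

The clip velocity is the *duration-weighted* mean over all linked steps of
all tracks (each step weighted by its frame span), pooling steps rather
than averaging per-track means, so every observed particle-frame counts
equally. Velocities are signed; net flow may be negative. Replicates:
sample (n−1) SD across per-clip means, flagged undefined for a single
clip. `Q = k_w·A·v` with the SD scaled by the same factor. A useful
property of the duration-weighted estimator: jitter telescopes along a
track (interior noise cancels in the summed displacement), so the mean is
extremely stable under detector noise and the replicate SD responds to
jitter only once it dominates particle-sampling variance.

## Sweeps

The dependence of the true flow on the swept variable is an input
`AmplitudeModel` — default `Q = q₁·F·max(0, 1 − 2·offset/L)`, optionally
× `µ_ref/µ` — chosen to reproduce the qualitative experimental findings
(linear in frequency, zero at mid-tube, inverse-resistance in viscosity)
without claiming mechanism; `q₁ = 16 µl/s/Hz` puts the 2.5-Hz point near
the measured ~40 µl/s. Fits are unweighted OLS (the original analysis
reports linear trends without weighted fits); viscosity-sweep points with
`Wo > 5` are fitted but flagged, where the linear flowrate–viscosity
relationship is expected to break down. Per-point seeds are
`base_seed + grid index`. No hypothesis testing beyond the descriptive
fits.

## Validation problem sizes

Test and acceptance runs use 10-s (or shorter) clips and 1–8 replicates
per condition rather than the full three 30-s clips; at the default
particle density this still yields thousands of linked steps per clip, and
recovery results are insensitive to clip length beyond a few seconds. The
end-to-end checks generate scenes at 5/15/40 µl/s (water, 1.0/1.5/2.5 Hz,
`Wo` 3.9–6.1) over ten seeds and require recovery within 5 % noiseless
and 15 % at default noise; measured errors are ≤ 3 %. Frequency-sweep
slope recovery over five seeds is required within 5 % of the generating
slope; measured ≤ 1 %.

## Known limitations

* `k_w` is the magnitude-ratio of the fundamental mode; it is not the
  closed form used in the original analysis, and at the 3-mm
  tube's 2.5-Hz operating point the two differ (0.767 vs the implied
  0.668). Absolute flowrates inherit this definitional choice; synthetic
  recovery does not, because generator and estimator share the definition.
* The tracker assumes well-separated particles; dense scenes (spacing
  comparable to the link gate) will mislink, and merged blobs are detected
  as one particle.
* The natural-frequency calculator assumes the thin-wall Moens–Korteweg
  speed; no wave reflection or resonance is simulated.
* The protocol grid of the original study rounds 1/(0.2+0.5) s⁻¹ to
  1.5 Hz; the package always uses the exact reciprocal (1.43 Hz).
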