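# liebauflow

Quantification of valveless (Liebau / impedance) pump output from
tracer-particle video, with the supporting pump-physics calculators and a
ground-truthed synthetic-scene generator.

A Liebau pump drives net unidirectional flow through a valveless circuit by
periodically compressing a compliant tube segment *asymmetrically* relative
to its junctions with stiffer tubing — a candidate mechanism for valveless
circulation in embryonic hearts and simple invertebrates. Measuring such a
pump's output typically means filming ~0.5-mm tracer particles in a
transparent observation tube at 60 frame/s, tracking them, and converting
the tracked velocity into a volumetric flowrate. This package implements
that entire measurement chain for experimentalists and modellers who need
it reproducible and testable:

* **Tracking** — blob detection on grayscale frame stacks, frame-to-frame
  nearest-neighbor linking solved as an optimal assignment, and gap closing
  across missed detections.
* **Flow quantification** — the pulsatile-flow regime is characterized by
  the Womersley number `Wo = r·√(ρω/µ)`; the time-averaged tracer velocity
  `v` (a centerline-type measure) is converted to the net flowrate with the
  centerline-to-mean correction `k_w`:

      Q = k_w · A · v,     k_w = (2/R²·u₀) ∫₀ᴿ |u(r)| r dr ∈ [0.5, 1]

  where `u(r)` is the oscillatory (Womersley) velocity profile, `A` the
  lumen area, and replicate SD comes from independent clips.
* **Pump physics** — Young modulus from a tensile test `E = g·m·L/(A·ΔL)`;
  Moens–Korteweg pulse-wave speed `c = √(E·h/(ρ·d))`; natural frequency
  `F_n = c/2L`; the idealized peristaltic reference output `Q = F·A·P`;
  a glycerol–water viscosity correlation; Poiseuille resistance scaling
  `R ∼ µ·L/r⁴`.
* **Synthetic scenes** — particle detection streams (and optionally
  rendered TIFF/PNG stacks) of tracers advected by a pulsatile waveform
  with an exactly known net flowrate, including detection jitter, missed
  detections and false positives, so every pipeline stage is validated
  against ground truth.
* **Sweeps** — flowrate versus compression frequency, fluid viscosity and
  pincher position, with OLS fits and plots.

## Worked example

Quantify a synthetic scene of the 3-mm observation tube filled with water,
compressed at 2.5 Hz, generated with a true net flowrate of 38.6 µl/s
(three 30-s clips at 60 frame/s):

```python
from liebauflow import physics
from liebauflow.physics import CompressionProtocol, FluidProperties, TubeGeometry
from liebauflow.scene import SceneConfig, generate_scene
from liebauflow.flow_quant import quantify_detections
from liebauflow.analysis import _linker_for, peristaltic_comparison

geom = TubeGeometry(segment_length=0.038, inner_diameter=3e-3, wall_thickness=0.5e-3)
water = FluidProperties(density=1000.0, dynamic_viscosity=0.95e-3)
protocol = CompressionProtocol.from_frequency(2.5, pincher_length=3.5e-3)
regime = physics.womersley_regime(geom, water, protocol)

cfg = SceneConfig(geometry=geom, fluid=water, protocol=protocol,
                  target_mean_flowrate=38.6, rng_seed=0)
detections, truth = generate_scene(cfg)
result = quantify_detections(detections, geom, regime, _linker_for(cfg),
                             cfg.pixel_scale, cfg.frames_per_second)
```

This prints (via the fields of `regime` and `result`):

```
Wo = 6.10, k_w = 0.767
v = 7.06 +/- 0.01 mm/s over 3 clips
Q = 38.3 +/- 0.1 ul/s = 2.30 ml/min  (truth 38.6)
```

`Wo = 6.1` is an intermediate regime — neither parabolic (`Wo < 1`) nor
flat (`Wo > 10`) — so the centerline-to-mean correction is `k_w = 0.767`.
The pipeline recovers the generating flowrate within 1 %. Comparing against
an idealized peristaltic pump with a 5-mm lumen and the same 3.5-mm pincher
at 2.5 Hz:

```python
cmp = peristaltic_comparison(result, protocol,
                             TubeGeometry(0.038, 5e-3, 0.5e-3))
# cmp.reference_ul_s = 172, cmp.ratio = 0.22
```

i.e. the Liebau output is roughly a quarter of the peristaltic ceiling.

The same pipeline is scriptable from a shell (`liebauflow simulate / detect
/ track / quantify / sweep / report`); see `liebauflow --help`.

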