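"""Synthetic tracer scenes with known net flowrate.

The laboratory measurement this package quantifies is video of ~0.5-mm dark
carbon particles drifting through a straight transparent tube under
pulsatile flow.  This module generates ground-truthed stand-ins for that
video so that every downstream stage (detection, linking, gap closing,
flow quantification) can be validated against a known answer:

* :func:`pulse_waveform` builds the per-frame cross-section-mean velocity
  series for a compression protocol, scaled so its time average times the
  lumen area equals a requested net flowrate exactly.
* :func:`generate_scene` advects virtual particles with that waveform —
  each particle rides the Womersley profile at its hidden radial position —
  and emits a detection table with configurable centroid jitter, missed
  detections (to exercise gap closing) and single-frame false positives,
  together with a :class:`SceneTruth` record of the generating flow.
* :func:`render_scene` rasterizes a clip into a grayscale frame stack
  (dark anti-aliased discs on a light background with mild sensor noise)
  for testing the image-domain detector.

Particles enter upstream of the field of view and exit downstream; the
upstream seeding region is sized from the total centerline displacement so
the in-view particle density is stationary over the clip.  Tracers are
confined to a core around the tube axis (``tracer_radial_extent``), so the
tracked aggregate velocity stands in for the centerline velocity that the
k_w correction maps to the mean flow — the same measurement model as the
experiment.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .physics import (
    CompressionProtocol,
    FluidProperties,
    TubeGeometry,
    kw_correction,
    womersley_number,
    womersley_profile,
)

__all__ = [
    "DegenerateSceneError",
    "SceneConfig",
    "SceneTruth",
    "pulse_waveform",
    "generate_scene",
    "render_scene",
    "write_detections",
    "read_detections",
    "write_frames",
]

DETECTION_COLUMNS = ["clip", "frame", "x_px", "y_px", "area_px"]


class DegenerateSceneError(ValueError):
    """The configuration puts no particle in view in any frame."""


@dataclass(frozen=True)
class SceneConfig:
    """Full parameterization of a synthetic clip set.

    Defaults mirror the experimental recordings: 60 frame/s, three 30-s
    clips per condition, 0.5-mm tracers, and a 3-mm-ID observation tube.
    ``target_mean_flowrate`` is the true net flowrate in ul/s.  Velocities
    follow ``pulse_waveform``; each particle's axial speed is the
    centerline series times the Womersley profile at its radial position
    (``radial_profile='flat'`` disables the profile — every particle moves
    at the mean velocity, useful for exact-displacement tests).
    """

    geometry: TubeGeometry
    fluid: FluidProperties
    protocol: CompressionProtocol
    target_mean_flowrate: float  # ul/s
    frames_per_second: float = 60.0
    clip_duration: float = 30.0  # s
    n_clips: int = 3
    field_of_view: tuple[float, float] = (12.8, 3.2)  # mm (axial, transverse)
    pixel_scale: float = 0.05  # mm/px
    particle_diameter: float = 0.5  # mm
    particle_density: float = 8.0  # expected particles per frame in view
    waveform_mode: str = "forward"  # or "symmetric"
    waveform_amplitude: float | None = None  # mm/s, symmetric mode only
    radial_profile: str = "womersley"  # or "flat"
    tracer_radial_extent: float = 0.2  # tracers confined to r/R <= this
    detection_jitter_sd: float = 0.5  # px
    miss_probability: float = 0.05
    false_positive_rate: float = 0.5  # per frame
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.frames_per_second <= 0 or self.clip_duration <= 0 or self.n_clips < 1:
            raise ValueError("fps, clip_duration must be > 0 and n_clips >= 1")
        if self.detection_jitter_sd < 0:
            raise ValueError("detection_jitter_sd must be >= 0")
        if not 0.0 <= self.miss_probability < 1.0:
            raise ValueError("miss_probability must be in [0, 1)")
        if self.false_positive_rate < 0:
            raise ValueError("false_positive_rate must be >= 0")
        if self.waveform_mode not in ("forward", "symmetric", "constant"):
            raise ValueError(f"unknown waveform_mode {self.waveform_mode!r}")
        if self.radial_profile not in ("womersley", "flat"):
            raise ValueError(f"unknown radial_profile {self.radial_profile!r}")
        if not 0.0 < self.tracer_radial_extent <= 1.0:
            raise ValueError("tracer_radial_extent must be in (0, 1]")

    @property
    def n_frames(self) -> int:
        return int(round(self.frames_per_second * self.clip_duration))

    def noiseless(self) -> "SceneConfig":
        """Copy with jitter, misses and false positives all zero."""
        return replace(
            self, detection_jitter_sd=0.0, miss_probability=0.0, false_positive_rate=0.0
        )


@dataclass
class SceneTruth:
    """Ground truth of a generated scene.

    ``mean_velocity`` is the per-frame cross-section-mean axial velocity in
    mm/s (one array per clip — identical across clips by construction);
    ``centerline_velocity`` is the same series divided by ``kw``.  The true
    net flowrate in ul/s equals the time average of the mean-velocity
    series times the lumen area (mm/s x mm^2 = ul/s) exactly.
    ``trajectories`` holds the unobserved particle paths (columns clip,
    particle, frame, x_mm, y_mm) for every frame a particle is in view.
    """

    mean_velocity: np.ndarray  # mm/s, per frame
    centerline_velocity: np.ndarray  # mm/s, per frame
    net_flowrate: float  # ul/s
    womersley: float
    kw: float
    trajectories: pd.DataFrame

    def to_json(self, path: str | Path) -> None:
        payload = {
            "net_flowrate_ul_s": self.net_flowrate,
            "womersley_number": self.womersley,
            "kw": self.kw,
            "mean_velocity_mm_s": self.mean_velocity.tolist(),
            "centerline_velocity_mm_s": self.centerline_velocity.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def pulse_waveform(
    protocol: CompressionProtocol,
    target_mean_flowrate: float,
    geom: TubeGeometry,
    *,
    frames_per_second: float = 60.0,
    duration: float = 30.0,
    mode: str = "forward",
    amplitude: float | None = None,
) -> np.ndarray:
    """Per-frame cross-section-mean velocity series (mm/s) for one clip.

    Each compression cycle contributes a raised-cosine rise over
    ``time_on`` followed by an exponential decay (time constant
    ``time_on``) over ``time_off`` — particles advance in a burst with each
    compression and coast between them.  The series is scaled after
    discretization so its time average times the lumen area equals
    ``target_mean_flowrate`` (ul/s) exactly.

    ``mode='forward'`` keeps the series non-negative and requires a
    non-zero target.  ``mode='symmetric'`` superimposes a zero-mean
    back-and-forth pulse of peak ``amplitude`` (mm/s) on the constant
    offset that realizes the target; with target 0 it mimics a mid-tube
    pincher (particles shuttle but there is no mean flow).
    ``mode='constant'`` is steady flow at the target mean — not a pump
    waveform, but the exact-kinematics reference for validation.
    """
    if mode == "constant":
        n = int(round(frames_per_second * duration))
        area_mm2 = geom.lumen_area * 1e6
        return np.full(n, target_mean_flowrate / area_mm2)
    freq = protocol.frequency
    n = int(round(frames_per_second * duration))
    if n < 1:
        raise ValueError("duration too short for one frame")
    t = np.arange(n) / frames_per_second
    tc = np.mod(t, 1.0 / freq)
    shape = np.where(
        tc < protocol.time_on,
        0.5 * (1.0 - np.cos(np.pi * tc / protocol.time_on)),
        np.exp(-(tc - protocol.time_on) / protocol.time_on),
    )
    area_mm2 = geom.lumen_area * 1e6
    v_target = target_mean_flowrate / area_mm2  # mm/s
    if mode == "forward":
        if target_mean_flowrate == 0:
            raise ValueError(
                "forward waveform cannot realize zero net flow (zero amplitude); "
                "use mode='symmetric'"
            )
        return shape * (v_target / shape.mean())
    if mode == "symmetric":
        if amplitude is None:
            amplitude = 5.0  # mm/s, an order-of-magnitude typical pulse
        if amplitude <= 0:
            raise ValueError("symmetric mode needs a positive pulse amplitude")
        centered = shape - shape.mean()
        peak = np.abs(centered).max()
        return centered * (amplitude / peak) + v_target
    raise ValueError(f"unknown waveform mode {mode!r}")


def _clip_rng(seed: int, clip: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(clip)])


def generate_scene(config: SceneConfig) -> tuple[pd.DataFrame, SceneTruth]:
    """Generate detection tables and ground truth for all clips.

    Returns a detection table with columns ``clip, frame, x_px, y_px,
    area_px`` (sorted by clip, frame, x, y; sub-pixel coordinates) and the
    :class:`SceneTruth`.  Identical configurations — including the seed —
    produce byte-identical tables.
    """
    geom, fps = config.geometry, config.frames_per_second
    dt = 1.0 / fps
    n = config.n_frames
    window_x, window_y = config.field_of_view
    r_mm = geom.radius * 1e3

    mean_v = pulse_waveform(
        config.protocol,
        config.target_mean_flowrate,
        geom,
        frames_per_second=fps,
        duration=config.clip_duration,
        mode=config.waveform_mode,
        amplitude=config.waveform_amplitude,
    )
    wo = womersley_number(geom, config.fluid, config.protocol)
    kw = kw_correction(wo) if config.radial_profile == "womersley" else 1.0
    center_v = mean_v / kw
    # centerline displacement since clip start, at each frame time
    disp = np.concatenate([[0.0], np.cumsum(center_v[:-1]) * dt])

    area_px = math.pi * (config.particle_diameter / 2.0 / config.pixel_scale) ** 2
    lam = config.particle_density / window_x  # particles per mm of tube
    buffer = 2.0  # mm, guards the seeding-region edges
    x_lo = -max(disp.max(), 0.0) - buffer
    x_hi = window_x + max(-disp.min(), 0.0) + buffer
    half_window_y = min(window_y / 2.0, r_mm)

    det_frames: list[pd.DataFrame] = []
    traj_frames: list[pd.DataFrame] = []
    any_visible = False
    for clip in range(config.n_clips):
        rng = _clip_rng(config.rng_seed, clip)
        n_particles = rng.poisson(lam * (x_hi - x_lo))
        x0 = rng.uniform(x_lo, x_hi, n_particles)
        # area-uniform radial positions within the tracer core
        xi = config.tracer_radial_extent * np.sqrt(rng.uniform(0, 1, n_particles))
        side = rng.choice([-1.0, 1.0], n_particles)
        if config.radial_profile == "womersley":
            shape_factor = womersley_profile(wo, xi)
        else:
            shape_factor = np.ones(n_particles)
        y_mm = window_y / 2.0 + side * xi * r_mm  # thin-slab projection

        x = x0[:, None] + shape_factor[:, None] * disp[None, :]  # (N, T) mm
        visible = (x >= 0.0) & (x <= window_x) & (
            np.abs(y_mm - window_y / 2.0) <= half_window_y
        )[:, None]
        pidx, fidx = np.nonzero(visible)
        if pidx.size:
            any_visible = True
        traj_frames.append(
            pd.DataFrame(
                {
                    "clip": clip,
                    "particle": pidx,
                    "frame": fidx,
                    "x_mm": x[pidx, fidx],
                    "y_mm": y_mm[pidx],
                }
            )
        )
        keep = rng.uniform(0, 1, pidx.size) >= config.miss_probability
        jitter = config.detection_jitter_sd
        x_px = x[pidx, fidx][keep] / config.pixel_scale
        y_px = y_mm[pidx][keep] / config.pixel_scale
        if jitter > 0:
            x_px = x_px + rng.normal(0.0, jitter, x_px.size)
            y_px = y_px + rng.normal(0.0, jitter, y_px.size)
        det = pd.DataFrame(
            {
                "clip": clip,
                "frame": fidx[keep],
                "x_px": x_px,
                "y_px": y_px,
                "area_px": area_px,
                "is_truth": True,
            }
        )
        n_fp = rng.poisson(config.false_positive_rate * n)
        if n_fp:
            fp = pd.DataFrame(
                {
                    "clip": clip,
                    "frame": rng.integers(0, n, n_fp),
                    "x_px": rng.uniform(0, window_x / config.pixel_scale, n_fp),
                    "y_px": rng.uniform(0, window_y / config.pixel_scale, n_fp),
                    "area_px": area_px,
                    "is_truth": False,
                }
            )
            det = pd.concat([det, fp], ignore_index=True)
        det_frames.append(det)

    if not any_visible:
        raise DegenerateSceneError(
            "no particle ever enters the field of view; check density, waveform "
            "and field_of_view"
        )

    detections = (
        pd.concat(det_frames, ignore_index=True)
        .sort_values(["clip", "frame", "x_px", "y_px"], kind="mergesort")
        .reset_index(drop=True)
    )
    area_mm2 = geom.lumen_area * 1e6
    truth = SceneTruth(
        mean_velocity=mean_v,
        centerline_velocity=center_v,
        net_flowrate=float(mean_v.mean() * area_mm2),
        womersley=wo,
        kw=kw,
        trajectories=pd.concat(traj_frames, ignore_index=True),
    )
    return detections, truth


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def render_scene(
    config: SceneConfig,
    clip: int = 0,
    *,
    background: int = 220,
    foreground: int = 30,
    sensor_noise_sd: float = 2.0,
) -> tuple[np.ndarray, SceneTruth]:
    """Rasterize one clip into a uint8 frame stack (frames, height, width).

    Particles are drawn at their true positions as dark discs of the
    configured diameter with one-pixel anti-aliased edges; mild Gaussian
    sensor noise is added.  Detection jitter / misses do not apply here —
    the stack is the input the image-domain detector is validated on.
    """
    _, truth = generate_scene(config.noiseless())
    traj = truth.trajectories
    traj = traj[traj["clip"] == clip]
    w_px = int(round(config.field_of_view[0] / config.pixel_scale))
    h_px = int(round(config.field_of_view[1] / config.pixel_scale))
    radius_px = config.particle_diameter / 2.0 / config.pixel_scale
    pad = int(math.ceil(radius_px)) + 2

    stack = np.full((config.n_frames, h_px, w_px), float(background))
    for frame, group in traj.groupby("frame"):
        img = stack[frame]
        for x_mm, y_mm in zip(group["x_mm"].to_numpy(), group["y_mm"].to_numpy()):
            cx, cy = x_mm / config.pixel_scale, y_mm / config.pixel_scale
            x0, x1 = int(cx) - pad, int(cx) + pad + 1
            y0, y1 = int(cy) - pad, int(cy) + pad + 1
            xs = np.arange(max(x0, 0), min(x1, w_px))
            ys = np.arange(max(y0, 0), min(y1, h_px))
            if not xs.size or not ys.size:
                continue
            # pixel (i, j) samples the scene at its center (j + 0.5, i + 0.5)
            dist = np.hypot(
                xs[None, :] + 0.5 - cx, ys[:, None] + 0.5 - cy
            )
            coverage = np.clip(radius_px + 0.5 - dist, 0.0, 1.0)
            patch = background - (background - foreground) * coverage
            img[np.ix_(ys, xs)] = np.minimum(img[np.ix_(ys, xs)], patch)
    if sensor_noise_sd > 0:
        rng = _clip_rng(config.rng_seed, 10_000 + clip)
        stack = stack + rng.normal(0.0, sensor_noise_sd, stack.shape)
    return np.clip(stack, 0, 255).astype(np.uint8), truth


# ---------------------------------------------------------------------------
# file interfaces
# ---------------------------------------------------------------------------


def write_detections(detections: pd.DataFrame, path: str | Path, truth_column: bool = False) -> None:
    """Write a detection CSV (columns frame, x_px, y_px, area_px [, is_truth])."""
    cols = DETECTION_COLUMNS + (["is_truth"] if truth_column else [])
    out = detections.reindex(columns=[c for c in cols if c in detections.columns])
    out.to_csv(path, index=False)


def read_detections(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"frame", "x_px", "y_px"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: detection CSV missing columns {sorted(missing)}")
    if "clip" not in df.columns:
        df.insert(0, "clip", 0)
    return df


def write_frames(stack: np.ndarray, outdir: str | Path, fmt: str = "tiff") -> Path:
    """Write a frame stack as numbered TIFF or PNG files plus a manifest."""
    import imageio.v3 as iio
    import tifffile

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ext = {"tiff": "tif", "png": "png"}[fmt]
    names = []
    for i, frame in enumerate(stack):
        name = f"frame_{i:05d}.{ext}"
        if fmt == "tiff":
            tifffile.imwrite(outdir / name, frame)
        else:
            iio.imwrite(outdir / name, frame)
        names.append(name)
    manifest = {"n_frames": len(names), "format": fmt, "frames": names}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return outdir / "manifest.json"
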