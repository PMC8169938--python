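"""From tracks to net flowrate.

The headline quantity of a Liebau-pump experiment is the net volumetric
flowrate ``Q = k_w * A * v``: ``v`` is the time-averaged velocity of the
tracked tracers in the observation tube (a centerline-type measure, since
the tracers ride near the axis), ``A`` the lumen area, and ``k_w`` the
Womersley centerline-to-mean correction for the operating regime.
Replicate variability comes from repeating the estimate over independent
clips, exactly as the experimental protocol repeats 30-s recordings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .physics import TubeGeometry, WomersleyRegime, ul_s_to_ml_min
from .tracking import LinkerConfig, Track, link_tracks, track_velocities

__all__ = [
    "EmptyClipError",
    "VelocityEstimate",
    "FlowrateResult",
    "clip_mean_velocity",
    "replicate_velocity",
    "net_flowrate",
    "quantify_detections",
]


class EmptyClipError(ValueError):
    """No usable tracks survived filtering in a clip."""


@dataclass(frozen=True)
class VelocityEstimate:
    """Time-averaged tracer velocity across replicate clips (mm/s).

    ``sd_across_clips`` is the sample (n-1) standard deviation of the
    per-clip means; it is NaN — flagged undefined — for a single clip.
    """

    mean_velocity: float  # mm/s
    sd_across_clips: float  # mm/s, NaN if n_clips == 1
    n_clips: int

    def __post_init__(self) -> None:
        if self.n_clips < 1:
            raise ValueError("n_clips must be >= 1")
        if self.n_clips > 1 and not self.sd_across_clips >= 0:
            raise ValueError("sd_across_clips must be >= 0 for n_clips > 1")

    @property
    def sd_defined(self) -> bool:
        return self.n_clips > 1 and math.isfinite(self.sd_across_clips)


@dataclass(frozen=True)
class FlowrateResult:
    """Net volumetric flowrate of one configuration.

    Signed: a negative value is flow toward the longer elastic segment
    (reversal), zero is no net flow.  ``sd`` propagates the velocity SD
    linearly (Q = k_w A v is linear in v).
    """

    flowrate_ul_s: float
    sd_ul_s: float
    velocity: VelocityEstimate
    regime: WomersleyRegime
    geometry: TubeGeometry

    @property
    def flowrate_ml_min(self) -> float:
        return ul_s_to_ml_min(self.flowrate_ul_s)

    @property
    def sd_ml_min(self) -> float:
        return ul_s_to_ml_min(self.sd_ul_s)


def clip_mean_velocity(steps: pd.DataFrame, weighting: str = "duration") -> float:
    """Time-averaged axial velocity (mm/s) of one clip's linked steps.

    ``weighting='duration'`` (the contract) weights every linked step by
    the number of frames it spans, so a step bridging a closed gap counts
    for its whole unobserved interval and every observed particle-frame
    contributes equally.  ``weighting='uniform'`` averages steps unweighted
    (for sensitivity checks only).
    """
    if steps.empty:
        raise EmptyClipError("no linked steps in clip; nothing to average")
    v = steps["velocity_mm_s"].to_numpy()
    if weighting == "duration":
        w = steps["frame_span"].to_numpy(dtype=float)
        return float(np.average(v, weights=w))
    if weighting == "uniform":
        return float(v.mean())
    raise ValueError(f"unknown weighting {weighting!r}")


def replicate_velocity(clip_means) -> VelocityEstimate:
    """Mean and sample SD across per-clip mean velocities."""
    means = np.asarray(list(clip_means), dtype=float)
    if means.size == 0:
        raise ValueError("need at least one clip mean")
    sd = float(np.std(means, ddof=1)) if means.size > 1 else float("nan")
    return VelocityEstimate(
        mean_velocity=float(means.mean()), sd_across_clips=sd, n_clips=int(means.size)
    )


def net_flowrate(
    estimate: VelocityEstimate, geom: TubeGeometry, regime: WomersleyRegime
) -> FlowrateResult:
    """Q = k_w * A * v, with the SD scaled by the same factor.

    ``v`` in mm/s and ``A`` in mm^2 give Q directly in ul/s.
    """
    factor = regime.kw * geom.lumen_area * 1e6  # mm^2
    sd_v = estimate.sd_across_clips
    return FlowrateResult(
        flowrate_ul_s=factor * estimate.mean_velocity,
        sd_ul_s=factor * sd_v if math.isfinite(sd_v) else float("nan"),
        velocity=estimate,
        regime=regime,
        geometry=geom,
    )


def quantify_detections(
    detections: pd.DataFrame,
    geom: TubeGeometry,
    regime: WomersleyRegime,
    linker: LinkerConfig,
    pixel_scale: float,
    fps: float,
) -> FlowrateResult:
    """Full quantification of a multi-clip detection table.

    Each clip (column ``clip``; absent means a single clip) is linked and
    averaged independently; the replicate estimate is then converted to a
    flowrate.  A clip in which no track survives filtering raises
    :class:`EmptyClipError` naming the clip.
    """
    if "clip" not in detections.columns:
        detections = detections.assign(clip=0)
    clip_means = []
    for clip, group in detections.groupby("clip", sort=True):
        tracks = link_tracks(group, linker)
        steps = track_velocities(tracks, pixel_scale, fps)
        if steps.empty:
            raise EmptyClipError(f"clip {clip}: no usable tracks after filtering")
        clip_means.append(clip_mean_velocity(steps))
    return net_flowrate(replicate_velocity(clip_means), geom, regime)
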