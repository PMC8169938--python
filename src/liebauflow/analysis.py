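"""Sweep orchestration: flowrate versus frequency, viscosity and pincher position.

The experimental result surfaces are one-dimensional sweeps: net flowrate
against compression frequency (linear increase), against fluid viscosity
(linear decrease, with deviations once the Womersley number exceeds ~5),
and against pincher offset from the junction (maximal at the edge, zero at
mid-tube).  This module re-creates those surfaces on synthetic scenes.

The dependence of the TRUE flow on the swept variable is an input — an
:class:`AmplitudeModel` mapping protocol/fluid to a target net flowrate —
not a fluid-structure simulation: the point of a sweep here is parameter
recovery (does the pipeline read back the generating slope?), not a claim
about Liebau pump mechanism.  The default model is linear in frequency,
zero for a mid-tube pincher, and optionally proportional to the inverse
Poiseuille resistance for viscosity sweeps.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import linregress

from . import __version__
from .config import ExperimentConfig
from .flow_quant import FlowrateResult, quantify_detections
from .physics import (
    CompressionProtocol,
    FluidProperties,
    TubeGeometry,
    cp_to_pa_s,
    kw_correction,
    m3_s_to_ul_s,
    peristaltic_flowrate,
    womersley_number,
)
from .scene import SceneConfig, generate_scene, pulse_waveform
from .tracking import LinkerConfig

__all__ = [
    "SweepError",
    "AmplitudeModel",
    "SweepSpec",
    "SweepResult",
    "PeristalticComparison",
    "run_sweep",
    "peristaltic_comparison",
    "report",
]

SWEEP_VARIABLES = ("frequency", "viscosity", "pincher_offset")
#: viscosity-sweep points above this Womersley number are flagged: the
#: linear flowrate-viscosity relationship is expected to break down there
WO_FLAG_THRESHOLD = 5.0


class SweepError(RuntimeError):
    """A grid point's pipeline failed; the message names the point."""


@dataclass(frozen=True)
class AmplitudeModel:
    """Maps an operating point to the generating (true) net flowrate, ul/s.

    ``Q = flowrate_per_hz * F * max(0, 1 - 2 * offset / L)``, optionally
    multiplied by ``reference_viscosity / viscosity`` (inverse Poiseuille
    resistance at fixed geometry).  The linear-in-F, zero-at-mid-tube form
    reproduces the qualitative experimental findings without claiming pump
    physics; 16 ul/s per Hz puts the 2.5-Hz point near the measured
    ~40 ul/s.
    """

    flowrate_per_hz: float = 16.0  # ul/s per Hz with the pincher at the edge
    reference_viscosity: float | None = None  # Pa.s

    def target(
        self, protocol: CompressionProtocol, geom: TubeGeometry, fluid: FluidProperties
    ) -> float:
        position = 1.0 - 2.0 * protocol.pincher_offset_from_junction / geom.segment_length
        q = self.flowrate_per_hz * protocol.frequency * max(0.0, position)
        if self.reference_viscosity is not None:
            q *= self.reference_viscosity / fluid.dynamic_viscosity
        return q


@dataclass(frozen=True)
class SweepSpec:
    """One sweep: the variable, its grid, and everything held fixed.

    Grid units follow reporting conventions: Hz for ``frequency``, cP for
    ``viscosity``, mm for ``pincher_offset``.  Per-point seeds are derived
    deterministically as ``base_seed + grid index``.  ``scene_overrides``
    is forwarded to :class:`SceneConfig` (noise levels, clip duration,
    particle density, ...).
    """

    variable: str
    grid: tuple[float, ...]
    experiment: ExperimentConfig
    amplitude_model: AmplitudeModel = AmplitudeModel()
    base_seed: int = 0
    n_clips: int = 3
    clip_duration: float = 10.0
    scene_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.variable not in SWEEP_VARIABLES:
            raise ValueError(f"variable must be one of {SWEEP_VARIABLES}")
        grid = tuple(float(v) for v in self.grid)
        if not grid:
            raise ValueError("grid must be non-empty")
        if any(b <= a for a, b in zip(grid, grid[1:])):
            raise ValueError("grid must be strictly increasing")
        object.__setattr__(self, "grid", grid)

    def point(self, value: float) -> ExperimentConfig:
        """The experiment configuration at one grid value."""
        exp = self.experiment
        if self.variable == "frequency":
            protocol = CompressionProtocol.from_frequency(
                value,
                time_on=exp.protocol.time_on,
                pincher_length=exp.protocol.pincher_length,
                pincher_offset_from_junction=exp.protocol.pincher_offset_from_junction,
                occlusion_fraction=exp.protocol.occlusion_fraction,
            )
            return dataclasses.replace(exp, protocol=protocol)
        if self.variable == "viscosity":
            fluid = FluidProperties(
                density=exp.fluid.density,
                dynamic_viscosity=cp_to_pa_s(value),
                temperature=exp.fluid.temperature,
            )
            return dataclasses.replace(exp, fluid=fluid)
        protocol = replace(exp.protocol, pincher_offset_from_junction=value * 1e-3)
        return dataclasses.replace(exp, protocol=protocol)


@dataclass
class SweepResult:
    """Per-point flowrates plus the fitted line Q = slope * x + intercept."""

    spec: SweepSpec
    values: list[float]
    results: list[FlowrateResult]
    true_flowrates: list[float]  # ul/s, from the amplitude model
    slope: float
    intercept: float
    r_squared: float
    flagged: list[bool]
    seeds: list[int]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for value, res, truth, flag, seed in zip(
            self.values, self.results, self.true_flowrates, self.flagged, self.seeds
        ):
            rows.append(
                {
                    self.spec.variable: value,
                    "velocity_mm_s": res.velocity.mean_velocity,
                    "sd_velocity_mm_s": res.velocity.sd_across_clips,
                    "womersley_number": res.regime.womersley_number,
                    "kw": res.regime.kw,
                    "flowrate_ul_s": res.flowrate_ul_s,
                    "flowrate_ml_min": res.flowrate_ml_min,
                    "sd_ul_s": res.sd_ul_s,
                    "true_flowrate_ul_s": truth,
                    "excluded_flag": flag,
                    "seed": seed,
                }
            )
        return pd.DataFrame(rows)


def _scene_for_point(
    spec: SweepSpec, exp: ExperimentConfig, target: float, seed: int
) -> SceneConfig:
    overrides = dict(spec.scene_overrides)
    mode = "forward" if target != 0 else "symmetric"
    return SceneConfig(
        geometry=exp.geometry,
        fluid=exp.fluid,
        protocol=exp.protocol,
        target_mean_flowrate=target,
        n_clips=spec.n_clips,
        clip_duration=spec.clip_duration,
        waveform_mode=overrides.pop("waveform_mode", mode),
        rng_seed=seed,
        **overrides,
    )


def _linker_for(scene: SceneConfig) -> LinkerConfig:
    wave = pulse_waveform(
        scene.protocol,
        scene.target_mean_flowrate,
        scene.geometry,
        frames_per_second=scene.frames_per_second,
        duration=scene.clip_duration,
        mode=scene.waveform_mode,
        amplitude=scene.waveform_amplitude,
    )
    wo = womersley_number(scene.geometry, scene.fluid, scene.protocol)
    kw = kw_correction(wo) if scene.radial_profile == "womersley" else 1.0
    peak = float(np.abs(wave).max()) / kw
    return LinkerConfig.for_peak_velocity(
        max(peak, 1.0),
        scene.pixel_scale,
        scene.frames_per_second,
        jitter_sd_px=scene.detection_jitter_sd,
    )


def run_sweep(spec: SweepSpec) -> SweepResult:
    """Generate, track and quantify every grid point, then fit a line.

    Ordinary least squares on (grid value, flowrate), unweighted.  For
    viscosity sweeps, points whose Womersley number exceeds 5 are fitted
    but flagged.  A failing grid point aborts the sweep with the point
    identified.
    """
    values, results, truths, flags, seeds = [], [], [], [], []
    for i, value in enumerate(spec.grid):
        seed = spec.base_seed + i
        exp = spec.point(value)
        target = spec.amplitude_model.target(exp.protocol, exp.geometry, exp.fluid)
        try:
            scene = _scene_for_point(spec, exp, target, seed)
            detections, _ = generate_scene(scene)
            result = quantify_detections(
                detections,
                exp.geometry,
                exp.regime(),
                _linker_for(scene),
                scene.pixel_scale,
                scene.frames_per_second,
            )
        except Exception as exc:  # noqa: BLE001 - re-raised with the point named
            raise SweepError(
                f"{spec.variable} sweep failed at grid point {value!r}: {exc}"
            ) from exc
        values.append(float(value))
        results.append(result)
        truths.append(target)
        flags.append(
            spec.variable == "viscosity"
            and result.regime.womersley_number > WO_FLAG_THRESHOLD
        )
        seeds.append(seed)

    q = [r.flowrate_ul_s for r in results]
    if len(values) >= 3:
        fit = linregress(values, q)
        slope, intercept, r2 = fit.slope, fit.intercept, fit.rvalue**2
    else:
        slope = intercept = r2 = float("nan")
    return SweepResult(
        spec=spec,
        values=values,
        results=results,
        true_flowrates=truths,
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        flagged=flags,
        seeds=seeds,
    )


@dataclass(frozen=True)
class PeristalticComparison:
    """Measured Liebau output next to the peristaltic reference F*A*P."""

    ratio: float
    measured_ul_s: float
    reference_ul_s: float


def peristaltic_comparison(
    result: FlowrateResult | float,
    protocol: CompressionProtocol,
    geom: TubeGeometry,
) -> PeristalticComparison:
    """Ratio of a measured flowrate to the peristaltic reference.

    The experimental headline: a Liebau pump at 2.5 Hz delivers about a
    quarter of what an idealized peristaltic pump of the same lumen,
    pincher and frequency could.
    """
    measured = result.flowrate_ul_s if isinstance(result, FlowrateResult) else float(result)
    reference = m3_s_to_ul_s(peristaltic_flowrate(protocol, geom))
    if reference == 0:
        raise ZeroDivisionError("peristaltic reference flowrate is zero; ratio undefined")
    return PeristalticComparison(
        ratio=measured / reference, measured_ul_s=measured, reference_ul_s=reference
    )


def report(results: list[SweepResult], outdir: str | Path) -> list[Path]:
    """Write per-sweep CSVs, fit parameters, plots and a run manifest.

    Deterministic inputs give byte-identical CSVs.  An empty result list
    raises before any file is created.
    """
    if not results:
        raise ValueError("nothing to report: empty result list")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written: list[Path] = []
    manifest = {"version": __version__, "sweeps": []}
    for result in results:
        name = result.spec.variable
        csv_path = outdir / f"sweep_{name}.csv"
        result.to_frame().to_csv(csv_path, index=False, float_format="%.6g")
        written.append(csv_path)

        fit_path = outdir / f"sweep_{name}_fit.json"
        fit_path.write_text(
            json.dumps(
                {
                    "variable": name,
                    "slope": result.slope,
                    "intercept": result.intercept,
                    "r_squared": result.r_squared,
                },
                indent=1,
            )
        )
        written.append(fit_path)

        fig, ax = plt.subplots(figsize=(5, 3.5))
        q = [r.flowrate_ul_s for r in result.results]
        sd = [r.sd_ul_s for r in result.results]
        ax.errorbar(result.values, q, yerr=sd, fmt="o", capsize=3, label="measured")
        if np.isfinite(result.slope):
            xs = np.linspace(min(result.values), max(result.values), 50)
            ax.plot(xs, result.slope * xs + result.intercept, "-", lw=1, label="OLS fit")
        ax.set_xlabel(_AXIS_LABELS[name])
        ax.set_ylabel("net flowrate (ul/s)")
        ax.legend(frameon=False)
        fig.tight_layout()
        png_path = outdir / f"sweep_{name}.png"
        fig.savefig(png_path, dpi=120)
        plt.close(fig)
        written.append(png_path)

        manifest["sweeps"].append(
            {
                "variable": name,
                "grid": list(result.values),
                "seeds": result.seeds,
                "base_seed": result.spec.base_seed,
                "n_clips": result.spec.n_clips,
                "clip_duration_s": result.spec.clip_duration,
            }
        )
    manifest_path = outdir / "run_manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1))
    written.append(manifest_path)
    return written


_AXIS_LABELS = {
    "frequency": "compression frequency (Hz)",
    "viscosity": "dynamic viscosity (cP)",
    "pincher_offset": "pincher offset from junction (mm)",
}
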