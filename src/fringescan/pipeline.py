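"""End-to-end single-frame processing.

Stage order:  Om -> Pm/Am -> Sm -> Wm -> Vm -> Bm -> Qm -> Um -> Mm -> Fm
(-> point cloud when a calibration model is supplied).  Each stage's
runtime, valid-pixel count and warnings are collected into a
machine-readable run report; a failure propagates with the stage name.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import numpy as np

from . import maps as maps_mod
from .calibrate import CalibrationModel, PointCloud, phase_to_cloud
from .marker import MarkerResult, recover_absolute_phase
from .maps import MapStack, QualityWeights
from .patterns import PatternSpec
from .unwrap import UnwrapResult, curvature_correction, unwrap

__all__ = ["PipelineConfig", "PipelineError", "FrameResult", "PipelineResult",
           "run_single_frame", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """All tunables of the single-frame chain.

    ``pattern`` describes the projected pattern (period, marker index and
    modulation); ``quality`` the map weights.  Remaining fields control
    masking, unwrapping seed choice and marker band filtering.  Unknown
    keys in a config file are rejected.
    """

    pattern: PatternSpec = field(default_factory=lambda: PatternSpec(
        width_px=512, height_px=512, period_px=16.0, marker_index=12))
    quality: QualityWeights = field(default_factory=QualityWeights)
    overexposure_level: float = 0.98
    mask_source: str = "intensity"
    mask_threshold: float | None = None
    closing_radius: int | None = None
    min_amplitude: float = 0.05
    unwrap_random_seed: int | None = None
    correct_curvature_bias: bool = True
    marker_band_halfwidth: float = 0.2
    marker_rel_threshold: float = 0.5
    marker_min_magnitude: float = 0.02

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        kwargs = {}
        if "pattern" in data:
            pat = data.pop("pattern")
            known = {f.name for f in dc_fields(PatternSpec)}
            bad = set(pat) - known
            if bad:
                raise ValueError(f"unknown pattern config keys: {sorted(bad)}")
            kwargs["pattern"] = PatternSpec(**pat)
        if "quality" in data:
            q = data.pop("quality")
            known = {f.name for f in dc_fields(QualityWeights)}
            bad = set(q) - known
            if bad:
                raise ValueError(f"unknown quality config keys: {sorted(bad)}")
            kwargs["quality"] = QualityWeights(**q)
        known = {f.name for f in dc_fields(cls)} - {"pattern", "quality"}
        bad = set(data) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        kwargs.update(data)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)


@dataclass
class FrameResult:
    maps: MapStack
    unwrap: UnwrapResult
    marker: MarkerResult
    report: dict


@dataclass
class PipelineResult:
    frame: FrameResult
    cloud: PointCloud | None
    dropped_pixels: int
    report: dict


def _stage(report: dict, name: str):
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            report["stages"].setdefault(name, {})
            self.caught = warnings.catch_warnings(record=True)
            self.wlist = self.caught.__enter__()
            warnings.simplefilter("always")
            return self

        def __exit__(self, exc_type, exc, tb):
            self.caught.__exit__(None, None, None)
            entry = report["stages"][name]
            entry["seconds"] = time.perf_counter() - self.t0
            for w in self.wlist:
                report["warnings"].append(f"{name}: {w.message}")
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(name, exc) from exc
            return False

    return _Ctx()


def run_single_frame(image: np.ndarray, config: PipelineConfig | None = None
                     ) -> FrameResult:
    """Process one fringe image to its absolute phase map ``Fm``."""
    if config is None:
        config = PipelineConfig()
    img = np.asarray(image, dtype=float)
    spec = config.pattern
    period = spec.period_px
    stack = MapStack(image=img)
    report: dict = {"stages": {}, "warnings": []}

    with _stage(report, "object_mask"):
        stack.Om = maps_mod.compute_object_mask(
            img, overexposure_level=config.overexposure_level,
            closing_radius=config.closing_radius,
            nominal_period_px=period, mask_source=config.mask_source,
            mask_threshold=config.mask_threshold)
        report["stages"]["object_mask"]["valid_px"] = int(stack.Om.sum())

    with _stage(report, "period_amplitude"):
        stack.Pm, stack.Am = maps_mod.compute_period_amplitude(
            img, stack.Om, nominal_period_px=period,
            min_amplitude=config.min_amplitude)
        report["stages"]["period_amplitude"]["valid_px"] = int(
            np.isfinite(stack.Pm).sum())

    with _stage(report, "stability"):
        stack.Sm = maps_mod.compute_stability(stack.Pm)

    with _stage(report, "wrapped_phase"):
        stack.Wm = maps_mod.compute_wrapped_phase(img, stack.Om, stack.Pm)
        report["stages"]["wrapped_phase"]["valid_px"] = int(
            np.isfinite(stack.Wm).sum())

    with _stage(report, "verticality"):
        stack.Vm = maps_mod.compute_verticality(img, stack.Om, stack.Pm)

    with _stage(report, "border"):
        stack.Bm = maps_mod.compute_border(stack.Om, nominal_period_px=period)

    with _stage(report, "quality"):
        am_n = maps_mod.normalize_map(stack.Am, stack.Om)
        stack.Qm = maps_mod.compute_quality(stack.Bm, am_n, stack.Vm,
                                            stack.Sm, config.quality)

    with _stage(report, "unwrap"):
        result = unwrap(stack.Wm, stack.Qm, stack.Om,
                        rng_seed=config.unwrap_random_seed)
        stack.Um = result.Um
        report["stages"]["unwrap"]["tree_edges"] = result.tree_edges
        report["stages"]["unwrap"]["components"] = result.n_components

    # the unwrapped phase keeps its (Um - Wm) = 2*pi*k contract; the known
    # second-order curvature response of the phase estimator is removed
    # from the continuous phase that feeds the absolute map
    phase = stack.Um
    if config.correct_curvature_bias:
        with _stage(report, "curvature_bias"):
            phase = stack.Um - curvature_correction(stack.Um, stack.Pm)

    with _stage(report, "marker"):
        marker = recover_absolute_phase(
            img, stack.Om, phase, spec,
            component_map=result.component_map,
            band_halfwidth_frac=config.marker_band_halfwidth,
            rel_threshold=config.marker_rel_threshold,
            min_magnitude=config.marker_min_magnitude)
        stack.Mm = marker.Mm
        stack.Fm = marker.Fm
        report["stages"]["marker"]["phase_shift_rad"] = marker.phase_shift

    return FrameResult(maps=stack, unwrap=result, marker=marker, report=report)


def run_pipeline(config: PipelineConfig, image: np.ndarray,
                 calibration: CalibrationModel | None = None
                 ) -> PipelineResult:
    """Full chain; with a calibration model the absolute phase becomes a
    metric point cloud (one point per valid pixel)."""
    frame = run_single_frame(image, config)
    cloud = None
    dropped = 0
    if calibration is not None:
        with _stage(frame.report, "cloud"):
            cloud, dropped = phase_to_cloud(frame.maps.Fm, frame.maps.image,
                                            calibration)
            frame.report["stages"]["cloud"]["points"] = len(cloud)
            frame.report["stages"]["cloud"]["dropped"] = dropped
    return PipelineResult(frame=frame, cloud=cloud, dropped_pixels=dropped,
                          report=frame.report)
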