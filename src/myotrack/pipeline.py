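"""End-to-end pipeline: detect, track, filter, extrapolate, correct, measure.

``process_stack`` is the library entry point operating on in-memory
stacks; ``run_pipeline`` wraps it with file input/output and a JSON run
summary, as used by the command line.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import detection, filtering, tracking
from .config import RunConfig
from .correction import CorrectedStack, correct_stack
from .detection import Landmark
from .field import DisplacementField, field_from_trajectories
from .filtering import FilterReport
from .kinematics import ContractionGrid, contraction_field
from .stack import ImageStack, read_stack, write_stack
from .tracking import Trajectory

log = logging.getLogger(__name__)

COORD_HEADER = ("# coordinates: 0-based (row, col); integer coordinate = "
                "pixel centre; lengths in um are pixels * pixel_width_um\n")


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage name."""


@dataclass
class PipelineResult:
    """All intermediate and final products of one run."""

    stack: ImageStack
    landmarks: list[Landmark]
    trajectories: list[Trajectory]
    retained: list[Trajectory]
    filter_report: FilterReport
    field: DisplacementField
    corrected: CorrectedStack
    contraction: ContractionGrid | None
    timings_s: dict[str, float]

    def summary(self) -> dict:
        lam_err = None
        if self.field.error_curve is not None:
            lam_err = float(np.min(self.field.error_curve[:, 1]))
        return {
            "n_frames": self.stack.n_frames,
            "frame_shape": list(self.stack.shape),
            "pixel_width_um": self.stack.pixel_width_um,
            "frame_interval_s": self.stack.frame_interval_s,
            "n_landmarks_detected": len(self.landmarks),
            "n_trajectories_retained": len(self.retained),
            "removed_by_stage": self.filter_report.stage_counts(),
            "lambda_c_um": self.field.lambda_c,
            "loo_error_at_lambda_c_um": lam_err,
            "timings_s": {k: round(v, 3) for k, v in self.timings_s.items()},
        }


def _stage(name, timings, fn, *args, **kwargs):
    t0 = time.perf_counter()
    try:
        out = fn(*args, **kwargs)
    except Exception as exc:
        raise PipelineError(f"stage '{name}' failed: {exc}") from exc
    timings[name] = time.perf_counter() - t0
    log.info("stage %-10s %.2f s", name, timings[name])
    return out


def process_stack(stack: ImageStack,
                  config: RunConfig | None = None,
                  kinematics: bool = True) -> PipelineResult:
    """Run the full motion-correction pipeline on a stack in memory."""
    config = config or RunConfig()
    timings: dict[str, float] = {}

    landmarks = _stage(
        "detect", timings, detection.detect_landmarks,
        stack.frames[0], r=config.window_half_size,
        bandpass_small=config.bandpass_small,
        bandpass_large=config.bandpass_large,
        seed=config.gmm_seed, min_landmarks=config.min_landmarks)

    trajectories = _stage("track", timings, tracking.track_all,
                          stack, landmarks)

    retained, report = _stage(
        "filter", timings, filtering.apply_filters, trajectories,
        interframe_distance_factor=config.interframe_distance_factor,
        relative_position_factor=config.relative_position_factor,
        median_test_epsilon=config.median_test_epsilon,
        median_test_threshold=config.median_test_threshold)
    if not retained:
        raise PipelineError("stage 'filter' failed: no landmarks retained")

    field = _stage("extrapolate", timings, field_from_trajectories,
                   retained, stack.shape, config.lambda_grid,
                   stack.pixel_width_um, stack.frame_interval_s)

    corrected = _stage("correct", timings, correct_stack, stack, field)

    grid = None
    if kinematics:
        grid = _stage("kinematics", timings, contraction_field,
                      field, config.grid_spacing_um)

    return PipelineResult(stack, landmarks, trajectories, retained, report,
                          field, corrected, grid, timings)


def trajectories_table(result: PipelineResult) -> pd.DataFrame:
    """Long-format table of every tracked position, with removal cause."""
    px = result.stack.pixel_width_um
    rows = []
    for traj in result.trajectories:
        cause = result.filter_report.cause(traj.landmark_id)
        for t in range(traj.n_frames):
            r, c = traj.positions[t]
            rows.append({
                "landmark_id": traj.landmark_id, "frame": t,
                "row_px": r, "col_px": c,
                "row_um": r * px, "col_um": c * px,
                "A": traj.fit_params[t, 0], "B": traj.fit_params[t, 1],
                "sigma_px": traj.fit_params[t, 2],
                "residual": traj.residuals[t],
                "valid": traj.valid, "removed_by": cause,
            })
    return pd.DataFrame(rows)


def contraction_table(grid: ContractionGrid) -> pd.DataFrame:
    n, gr, gc = grid.K.shape
    frames, cr, cc = np.meshgrid(np.arange(n), np.arange(gr),
                                 np.arange(gc), indexing="ij")
    return pd.DataFrame({
        "cell_row": cr.ravel(), "cell_col": cc.ravel(),
        "frame": frames.ravel(),
        "t_s": grid.times_s[frames.ravel()],
        "K_um2": grid.K.ravel(),
        "dK_over_K0": grid.dK_over_K0.ravel(),
        "degenerate": grid.degenerate.ravel(),
    })


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(COORD_HEADER)
        df.to_csv(fh, index=False)


def run_pipeline(input_path: str | Path,
                 outdir: str | Path,
                 pixel_width_um: float,
                 frame_interval_s: float,
                 config: RunConfig | None = None,
                 kinematics: bool = True) -> dict:
    """File-based pipeline: read, process, write all outputs.

    Writes corrected.tif and mask.tif, trajectories.csv,
    lambda_curve.csv, contraction.csv (when kinematics is on) and
    summary.json into ``outdir``; returns the summary dict.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stack = read_stack(input_path, pixel_width_um, frame_interval_s)
    result = process_stack(stack, config, kinematics=kinematics)

    write_stack(result.corrected.as_stack(), outdir / "corrected.tif")
    import tifffile
    tifffile.imwrite(outdir / "mask.tif",
                     result.corrected.mask.astype(np.uint8) * 255,
                     photometric="minisblack")

    _write_csv(trajectories_table(result), outdir / "trajectories.csv")
    curve = result.field.error_curve
    if curve is not None:
        _write_csv(pd.DataFrame(curve, columns=[
            "lambda_um", "mean_error_um", "normalized_error"]),
            outdir / "lambda_curve.csv")
    if result.contraction is not None:
        _write_csv(contraction_table(result.contraction),
                   outdir / "contraction.csv")

    summary = result.summary()
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary
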