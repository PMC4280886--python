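"""Run configuration shared by the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def default_lambda_grid() -> np.ndarray:
    """Log-spaced length-scale grid, 2-1024 um, 24 points."""
    return np.geomspace(2.0, 1024.0, 24)


@dataclass
class RunConfig:
    """Parameters of the motion-correction pipeline.

    Lengths are in the units noted; thresholds of the trajectory filter
    are scale-free (relative to per-dataset medians) where possible.
    """

    # landmark detection
    window_half_size: int = 3          # r; window is (2r+1) x (2r+1) px
    bandpass_small: float = 10.0       # smallest structure passed, px
    bandpass_large: float = 18.0       # largest structure passed, px
    gmm_seed: int = 0
    min_landmarks: int = 3

    # trajectory filter
    interframe_distance_factor: float = 3.0
    relative_position_factor: float = 3.0
    median_test_epsilon: float = 0.1   # px
    median_test_threshold: float = 2.0

    # length-scale optimisation (um)
    lambda_grid: np.ndarray = field(default_factory=default_lambda_grid)

    # kinematics
    grid_spacing_um: float = 10.0      # contraction grid; K0 = spacing^2
    baseline_method: str = "lowest_decile"

    def __post_init__(self) -> None:
        if self.window_half_size < 1:
            raise ValueError("window_half_size must be >= 1")
        if not self.bandpass_small < self.bandpass_large:
            raise ValueError("bandpass_small must be < bandpass_large")
        grid = np.asarray(self.lambda_grid, dtype=float)
        if grid.ndim != 1 or len(grid) < 1 or np.any(grid <= 0) or np.any(np.diff(grid) <= 0):
            raise ValueError("lambda_grid must be strictly increasing and positive")
        self.lambda_grid = grid
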