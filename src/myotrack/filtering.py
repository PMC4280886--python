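"""Four-stage removal of outlier and spurious trajectories.

Applied in order: (i) path intersections keep only the smoothest track,
(ii) excessive mean inter-frame distance, (iii) unstable position
relative to neighbouring landmarks, (iv) a per-frame normalized local
median test on displacement vectors with a persistence criterion.
Trajectories invalidated during tracking (boundary exit or lost fit)
are dropped before the four stages.  Filtering never modifies
positions; the output set is a subset of the input.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .tracking import Trajectory

log = logging.getLogger(__name__)

STAGES = ("boundary", "intersection", "interframe_distance",
          "relative_position", "local_median")

# neighbourhood sizes for stages (iii) and (iv)
K_RELATIVE = 5
K_MEDIAN = 8
# intersection: distance (px) under which two tracks count as crossing,
# and half-window (frames) of the smoothness comparison
INTERSECT_DIST = 1.0
SMOOTH_HALF_WINDOW = 5
# stage (iv): fraction of frames a residual must exceed the threshold
MEDIAN_PERSISTENCE = 0.10


@dataclass
class FilterReport:
    """Which stage (if any) removed each trajectory."""

    removed_by: dict[int, str] = field(default_factory=dict)

    def stage_counts(self) -> dict[str, int]:
        counts = {s: 0 for s in STAGES}
        for cause in self.removed_by.values():
            counts[cause] += 1
        return counts

    def cause(self, landmark_id: int) -> str:
        return self.removed_by.get(landmark_id, "none")


def _roughness(traj: Trajectory, frame: int) -> float:
    """Mean squared frame-to-frame acceleration near ``frame``."""
    lo = max(0, frame - SMOOTH_HALF_WINDOW)
    hi = min(traj.n_frames, frame + SMOOTH_HALF_WINDOW + 1)
    seg = traj.positions[lo:hi]
    if len(seg) < 3:
        seg = traj.positions
    acc = np.diff(seg, n=2, axis=0)
    if len(acc) == 0:
        return 0.0
    return float(np.mean(np.sum(acc**2, axis=1)))


def filter_intersections(trajectories: list[Trajectory],
                         report: FilterReport | None = None) -> list[Trajectory]:
    """Stage (i): where two paths cross, keep the smoother one.

    Two trajectories intersect when their positions in any common frame
    come within 1 px.  The rougher member of each intersecting pair --
    larger mean squared acceleration in the frames around the
    intersection -- is removed; pairs are visited in id order.
    """
    if report is None:
        report = FilterReport()
    alive = list(trajectories)
    removed: set[int] = set()
    for a_idx in range(len(alive)):
        a = alive[a_idx]
        if a.landmark_id in removed:
            continue
        for b_idx in range(a_idx + 1, len(alive)):
            b = alive[b_idx]
            if b.landmark_id in removed or a.landmark_id in removed:
                continue
            gap = np.linalg.norm(a.positions - b.positions, axis=1)
            hits = np.nonzero(gap < INTERSECT_DIST)[0]
            if len(hits) == 0:
                continue
            frame = int(hits[0])
            loser = a if _roughness(a, frame) > _roughness(b, frame) else b
            removed.add(loser.landmark_id)
            report.removed_by[loser.landmark_id] = "intersection"
    return [t for t in alive if t.landmark_id not in removed]


def filter_interframe_distance(trajectories: list[Trajectory],
                               factor: float = 3.0,
                               report: FilterReport | None = None
                               ) -> list[Trajectory]:
    """Stage (ii): drop tracks whose mean per-frame step is anomalous.

    The threshold is ``factor`` times the median of the mean step over
    all trajectories, so it is scale-free.
    """
    if report is None:
        report = FilterReport()
    if not trajectories:
        return []
    steps = np.array([
        float(np.mean(np.linalg.norm(np.diff(t.positions, axis=0), axis=1)))
        for t in trajectories
    ])
    cut = factor * np.median(steps)
    out = []
    for t, s in zip(trajectories, steps):
        if s > cut:
            report.removed_by[t.landmark_id] = "interframe_distance"
        else:
            out.append(t)
    return out


def _neighbour_indices(positions0: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k nearest neighbours (frame-1 distance) per point."""
    diff = positions0[:, None, :] - positions0[None, :, :]
    dist = np.sqrt(np.sum(diff**2, axis=-1))
    np.fill_diagonal(dist, np.inf)
    return np.argsort(dist, axis=1)[:, :k]


def filter_relative_position(trajectories: list[Trajectory],
                             factor: float = 3.0,
                             report: FilterReport | None = None
                             ) -> list[Trajectory]:
    """Stage (iii): drop tracks that move inconsistently with neighbours.

    For each trajectory, the displacement relative to the mean
    displacement of its 5 nearest frame-1 neighbours is computed per
    frame; tracks whose relative displacement varies (total standard
    deviation over time) more than ``factor`` times the median of that
    statistic are removed.  Under rigid motion the statistic is zero
    for every track.
    """
    if report is None:
        report = FilterReport()
    if len(trajectories) < K_RELATIVE + 1:
        warnings.warn("too few trajectories for relative-position filter; "
                      "stage skipped", stacklevel=2)
        return list(trajectories)
    disp = np.stack([t.displacements() for t in trajectories])  # (L, N, 2)
    pos0 = np.stack([t.positions[0] for t in trajectories])
    nbrs = _neighbour_indices(pos0, K_RELATIVE)
    rel = disp - disp[nbrs].mean(axis=1)               # (L, N, 2)
    stat = np.sqrt(np.sum(np.var(rel, axis=1), axis=-1))  # (L,)
    cut = factor * np.median(stat)
    out = []
    for t, s in zip(trajectories, stat):
        if s > cut:
            report.removed_by[t.landmark_id] = "relative_position"
        else:
            out.append(t)
    return out


def filter_local_median(trajectories: list[Trajectory],
                        epsilon: float = 0.1,
                        threshold: float = 2.0,
                        report: FilterReport | None = None
                        ) -> list[Trajectory]:
    """Stage (iv): per-frame normalized local median test with persistence.

    In every frame each displacement vector d is compared with the
    component-wise median m of its 8 nearest neighbours' displacements;
    with r_med the median of |d_neighbour - m|, the normalized residual
    is |d - m| / (r_med + epsilon).  A trajectory is removed when its
    residual exceeds ``threshold`` in more than 10% of frames, so
    single-frame glitches are tolerated.  epsilon (px) and the threshold
    of 2 follow standard particle-image-velocimetry practice.
    """
    if report is None:
        report = FilterReport()
    if len(trajectories) < 4:
        return list(trajectories)
    k = min(K_MEDIAN, len(trajectories) - 1)
    disp = np.stack([t.displacements() for t in trajectories])  # (L, N, 2)
    pos0 = np.stack([t.positions[0] for t in trajectories])
    nbrs = _neighbour_indices(pos0, k)

    nb_disp = disp[nbrs]                             # (L, k, N, 2)
    m = np.median(nb_disp, axis=1)                   # (L, N, 2)
    r_nb = np.linalg.norm(nb_disp - m[:, None], axis=-1)  # (L, k, N)
    r_med = np.median(r_nb, axis=1)                  # (L, N)
    resid = np.linalg.norm(disp - m, axis=-1) / (r_med + epsilon)
    bad_frac = np.mean(resid > threshold, axis=1)    # (L,)

    out = []
    for t, f in zip(trajectories, bad_frac):
        if f > MEDIAN_PERSISTENCE:
            report.removed_by[t.landmark_id] = "local_median"
        else:
            out.append(t)
    return out


def apply_filters(trajectories: list[Trajectory],
                  interframe_distance_factor: float = 3.0,
                  relative_position_factor: float = 3.0,
                  median_test_epsilon: float = 0.1,
                  median_test_threshold: float = 2.0,
                  ) -> tuple[list[Trajectory], FilterReport]:
    """Run boundary removal and the four stages in order."""
    report = FilterReport()
    alive = []
    for t in trajectories:
        if t.valid:
            alive.append(t)
        else:
            report.removed_by[t.landmark_id] = "boundary"
    if len(alive) >= 2:
        alive = filter_intersections(alive, report)
    alive = filter_interframe_distance(alive, interframe_distance_factor, report)
    if len(alive) >= 3:
        alive = filter_relative_position(alive, relative_position_factor, report)
    if len(alive) >= 4:
        alive = filter_local_median(alive, median_test_epsilon,
                                    median_test_threshold, report)
    log.info("filter kept %d of %d trajectories (%s)",
             len(alive), len(trajectories), report.stage_counts())
    return alive, report
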