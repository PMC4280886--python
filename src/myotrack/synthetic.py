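"""Ground-truth-annotated synthetic movies of contracting tissue.

The generator emulates the regime the tracker is designed for: bright
compact cell bodies (~15 um radius) on a darker smooth background,
displaced by a spatially heterogeneous but locally smooth warp while
their fluorescence is modulated by a calcium-transient programme that
leads the motion, plus intensity-dependent sensor noise.

The warp is a superposition of radial contraction kernels with Gaussian
spatial envelopes: one broad component (centre outside or at the edge of
the field, large scale) supplies the large bulk displacement seen over a
contraction, and several small-scale components of envelope scale L (the
homogeneity length) supply local heterogeneity.  Both follow smooth
contraction-relaxation time profiles.  Because the warp is analytic, the
ground-truth displacement of any material point is exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

from .stack import ImageStack


def raised_cosine_bump(t: np.ndarray, t_on: float, rise_s: float,
                       hold_s: float, fall_s: float) -> np.ndarray:
    """Smooth 0 -> 1 -> 0 activation profile.

    Zero before ``t_on``; half-cosine rise over ``rise_s``; plateau of
    ``hold_s``; half-cosine fall over ``fall_s``; zero after.
    """
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    s = (t - t_on) / rise_s
    rising = (s > 0) & (s < 1)
    out[rising] = 0.5 * (1 - np.cos(np.pi * s[rising]))
    t_fall = t_on + rise_s + hold_s
    out[(t >= t_on + rise_s) & (t < t_fall)] = 1.0
    f = (t - t_fall) / fall_s
    falling = (f >= 0) & (f < 1)
    out[falling] = 0.5 * (1 + np.cos(np.pi * f[falling]))
    return out


@dataclass
class SyntheticSpec:
    """Study conditions of a simulated recording.

    Geometry mirrors typical confocal recordings of tissue slices
    (hundreds of um field of view, a few um per pixel, 1 frame/s);
    landmark size and spacing mirror the small cell bodies used as
    fiducials.  Lengths in um, times in s.
    """

    shape: tuple[int, int] = (128, 128)
    pixel_width_um: float = 4.0
    frame_interval_s: float = 1.0
    n_frames: int = 60
    seed: int = 1

    # landmarks: jittered grid of Gaussian blobs
    landmark_spacing_um: float = 40.0
    landmark_jitter_um: float = 6.0
    margin_px: int = 8
    blob_sigma_um: float = 7.5        # ~15 um visible radius (2 sigma)
    blob_amplitude: float = 100.0

    # warp: one broad bulk component + n_local heterogeneous components,
    # plus an optional exactly uniform (rigid) translation
    global_peak_disp_um: float = 100.0  # max in-frame bulk displacement
    global_scale_um: float = 600.0
    rigid_translation_um: tuple[float, float] = (0.0, 0.0)
    local_peak_disp_um: float = 8.0
    homogeneity_scale_um: float = 40.0  # L, envelope of local components
    n_local: int = 4
    motion_onset_s: float = 14.0
    motion_rise_s: float = 16.0
    motion_hold_s: float = 0.0
    motion_fall_s: float = 24.0

    # intensity programme: calcium transient leading the motion
    ca_amplitude: float = 1.0          # fractional brightening at peak
    ca_lead_s: float = 4.0
    ca_rise_s: float = 6.0
    ca_hold_s: float = 10.0
    ca_fall_s: float = 15.0
    ca_region_range: tuple[float, float] = (0.8, 1.2)  # per-blob factors
    bg_ca_coupling: float = 0.5        # background transient relative to blobs
    stable_feature: bool = True        # keep one bright blob unmodulated

    # background and noise
    baseline: float = 20.0
    background_amplitude: float = 10.0
    background_scale_um: float = 100.0
    snr: float = 10.0                  # blob amplitude / noise std at peak;
                                       # inf disables noise

    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_s


@dataclass
class _WarpModel:
    """Analytic displacement field D(x0, t) in pixels."""

    centres_px: np.ndarray    # (K, 2) kernel centres
    scales_px: np.ndarray     # (K,)
    amps_px: np.ndarray       # (K,) signed radial amplitudes
    profile: np.ndarray       # (n_frames,) temporal activation in [0, 1]
    uniform_px: np.ndarray = field(
        default_factory=lambda: np.zeros(2))   # rigid translation term

    def spatial(self, points_px: np.ndarray) -> np.ndarray:
        """Time-independent part of the displacement, (P, 2)."""
        pts = np.atleast_2d(np.asarray(points_px, dtype=float))
        u = np.zeros_like(pts) + self.uniform_px
        for c, s, a in zip(self.centres_px, self.scales_px, self.amps_px):
            d = pts - c
            r2 = np.sum(d**2, axis=1, keepdims=True)
            u += -a * (d / s) * np.exp(-r2 / (2 * s**2))
        return u

    def displacement(self, points_px: np.ndarray,
                     frames: Sequence[int] | None = None) -> np.ndarray:
        """D(x0, t) for material points x0; shape (n_frames, P, 2)."""
        u = self.spatial(points_px)
        prof = self.profile if frames is None else self.profile[list(frames)]
        return prof[:, None, None] * u[None]


@dataclass
class SyntheticGroundTruth:
    """Everything the generator knows about the movie it emitted."""

    spec: SyntheticSpec
    centres0_px: np.ndarray        # (L, 2) frame-1 blob centres
    paths_px: np.ndarray           # (n_frames, L, 2) blob centres per frame
    blob_amps: np.ndarray          # (n_frames, L) rendered blob amplitudes
    warp: _WarpModel | None
    ca_profile: np.ndarray         # (n_frames,) transient activation
    feature_id: int | None         # bright stable blob, if any
    corrupt_ids: list[int] = field(default_factory=list)

    def true_displacement(self, points_px: np.ndarray) -> np.ndarray:
        """Exact displacement-from-frame-1 at material points, (N, P, 2)."""
        pts = np.atleast_2d(np.asarray(points_px, dtype=float))
        if self.warp is None:
            return np.zeros((self.spec.n_frames, len(pts), 2))
        return self.warp.displacement(pts)

    def dense_field(self) -> np.ndarray:
        """Exact dense field, (n_frames, H, W, 2) px."""
        H, W = self.spec.shape
        rows, cols = np.mgrid[0:H, 0:W].astype(float)
        pts = np.column_stack([rows.ravel(), cols.ravel()])
        D = self.true_displacement(pts)
        return D.reshape(self.spec.n_frames, H, W, 2)


def _landmark_grid(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    spacing_px = spec.landmark_spacing_um / spec.pixel_width_um
    jitter_px = spec.landmark_jitter_um / spec.pixel_width_um
    H, W = spec.shape
    m = spec.margin_px
    rows = np.arange(m, H - m, spacing_px)
    cols = np.arange(m, W - m, spacing_px)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    pts = np.column_stack([rr.ravel(), cc.ravel()])
    pts += rng.uniform(-jitter_px, jitter_px, pts.shape)
    pts[:, 0] = np.clip(pts[:, 0], m, H - 1 - m)
    pts[:, 1] = np.clip(pts[:, 1], m, W - 1 - m)
    sigma_px = spec.blob_sigma_um / spec.pixel_width_um
    diff = pts[:, None] - pts[None]
    dist = np.sqrt(np.sum(diff**2, axis=-1))
    np.fill_diagonal(dist, np.inf)
    if dist.min() < 2 * sigma_px:
        raise ValueError(
            "landmark packing infeasible: spacing/jitter place blobs "
            f"{dist.min():.2f} px apart for blob sigma {sigma_px:.2f} px")
    return pts


def _build_warp(spec: SyntheticSpec, rng: np.random.Generator,
                times: np.ndarray) -> _WarpModel | None:
    px = spec.pixel_width_um
    H, W = spec.shape
    centres, scales, amps = [], [], []

    if spec.global_peak_disp_um > 0:
        # bulk pull towards a point above the field; amplitude is scaled
        # so the maximum in-frame displacement equals global_peak_disp_um
        c = np.array([-0.5 * H, 0.5 * W])
        s = spec.global_scale_um / px
        centres.append(c)
        scales.append(s)
        amps.append(1.0)
    if spec.local_peak_disp_um > 0 and spec.n_local > 0:
        L = spec.homogeneity_scale_um / px
        for _ in range(spec.n_local):
            c = rng.uniform([0, 0], [H - 1, W - 1])
            centres.append(c)
            scales.append(L)
            amps.append(rng.choice([-1.0, 1.0]))
    uniform_px = np.asarray(spec.rigid_translation_um, dtype=float) / px
    if not centres and not np.any(uniform_px):
        return None

    profile = raised_cosine_bump(times, spec.motion_onset_s,
                                 spec.motion_rise_s, spec.motion_hold_s,
                                 spec.motion_fall_s)
    model = _WarpModel(np.array(centres).reshape(-1, 2),
                       np.array(scales), np.array(amps), profile,
                       uniform_px=uniform_px)

    # calibrate component amplitudes against the in-frame maxima
    rows, cols = np.mgrid[0:H:4, 0:W:4].astype(float)
    pts = np.column_stack([rows.ravel(), cols.ravel()])
    k = 0
    if spec.global_peak_disp_um > 0:
        solo = _WarpModel(model.centres_px[:1], model.scales_px[:1],
                          np.array([1.0]), profile)
        peak = np.max(np.linalg.norm(solo.spatial(pts), axis=1))
        model.amps_px[0] = (spec.global_peak_disp_um / px) / peak
        k = 1
    if spec.local_peak_disp_um > 0 and spec.n_local > 0:
        solo = _WarpModel(model.centres_px[k:], model.scales_px[k:],
                          model.amps_px[k:], profile)
        peak = np.max(np.linalg.norm(solo.spatial(pts), axis=1))
        if peak > 0:
            model.amps_px[k:] *= (spec.local_peak_disp_um / px) / peak
    return model


def _background(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """Smooth frame-1 background texture (baseline + slow structure)."""
    H, W = spec.shape
    scale_px = spec.background_scale_um / spec.pixel_width_um
    raw = rng.normal(size=(H, W))
    smooth = ndimage.gaussian_filter(raw, scale_px / 2.0, mode="reflect")
    if smooth.std() > 0:
        smooth = smooth / smooth.std()
    return spec.baseline + spec.background_amplitude * np.clip(smooth, -2, 2)


def _render(spec: SyntheticSpec,
            paths_px: np.ndarray,
            blob_amps: np.ndarray,
            warp: _WarpModel | None,
            ca_profile: np.ndarray,
            rng: np.random.Generator) -> np.ndarray:
    """Draw the movie: warped background, blobs at path positions, noise."""
    H, W = spec.shape
    n = spec.n_frames
    sigma_px = spec.blob_sigma_um / spec.pixel_width_um
    patch = int(np.ceil(5 * sigma_px))
    bg0 = _background(spec, rng)
    bg_mod = 1.0 + spec.bg_ca_coupling * spec.ca_amplitude * ca_profile

    rows, cols = np.mgrid[0:H, 0:W].astype(float)
    frames = np.empty((n, H, W))
    for t in range(n):
        if warp is None or warp.profile[t] == 0:
            bg = bg0
        else:
            # backward-sample the frame-1 texture (smooth background, so
            # using the forward field at the target point is adequate)
            pts = np.column_stack([rows.ravel(), cols.ravel()])
            D = warp.profile[t] * warp.spatial(pts)
            src = (pts - D).reshape(H, W, 2)
            bg = ndimage.map_coordinates(bg0, [src[..., 0], src[..., 1]],
                                         order=1, mode="nearest")
        frame = bg * bg_mod[t]
        for l in range(paths_px.shape[1]):
            cr, cc = paths_px[t, l]
            r0, r1 = int(np.floor(cr)) - patch, int(np.floor(cr)) + patch + 1
            c0, c1 = int(np.floor(cc)) - patch, int(np.floor(cc)) + patch + 1
            r0, r1 = max(r0, 0), min(r1, H)
            c0, c1 = max(c0, 0), min(c1, W)
            if r0 >= r1 or c0 >= c1:
                continue
            pr, pc = np.mgrid[r0:r1, c0:c1].astype(float)
            frame[r0:r1, c0:c1] += blob_amps[t, l] * np.exp(
                -((pr - cr) ** 2 + (pc - cc) ** 2) / (2 * sigma_px**2))
        frames[t] = frame

    if np.isfinite(spec.snr):
        peak = spec.baseline + spec.blob_amplitude * (1 + spec.ca_amplitude)
        gain = spec.blob_amplitude / (spec.snr * np.sqrt(peak))
        noise = rng.normal(size=frames.shape)
        frames = frames + gain * np.sqrt(np.maximum(frames, 0.0)) * noise
    return frames


def generate_movie(spec: SyntheticSpec
                   ) -> tuple[ImageStack, SyntheticGroundTruth]:
    """Render a movie and its exact ground truth.

    With a fixed ``spec.seed`` the output is bit-identical across calls.
    One blob (the one with the largest ground-truth excursion) is kept at
    a stable, brighter amplitude when ``spec.stable_feature`` is set,
    mimicking the trackable high-intensity features used to quantify
    stabilization.
    """
    rng = np.random.default_rng(spec.seed)
    times = spec.times_s()
    centres0 = _landmark_grid(spec, rng)
    L = len(centres0)
    warp = _build_warp(spec, rng, times)

    ca_profile = raised_cosine_bump(
        times, spec.motion_onset_s - spec.ca_lead_s,
        spec.ca_rise_s, spec.ca_hold_s, spec.ca_fall_s)

    if warp is None:
        paths = np.tile(centres0[None], (spec.n_frames, 1, 1))
    else:
        paths = centres0[None] + warp.displacement(centres0)

    region = rng.uniform(*spec.ca_region_range, size=L)
    feature_id = None
    if spec.stable_feature:
        excursion = np.linalg.norm(paths - paths[0], axis=-1).max(axis=0)
        feature_id = int(np.argmax(excursion))
    blob_amps = spec.blob_amplitude * (
        1.0 + spec.ca_amplitude * region[None, :] * ca_profile[:, None])
    if feature_id is not None:
        blob_amps[:, feature_id] = 1.5 * spec.blob_amplitude

    frames = _render(spec, paths, blob_amps, warp, ca_profile, rng)
    stack = ImageStack(frames, spec.pixel_width_um, spec.frame_interval_s)
    truth = SyntheticGroundTruth(spec, centres0, paths, blob_amps, warp,
                                 ca_profile, feature_id)
    return stack, truth


def inject_corruption(truth: SyntheticGroundTruth,
                      fraction: float,
                      mode: str = "jitter"
                      ) -> tuple[ImageStack, SyntheticGroundTruth]:
    """Re-render the movie with a fraction of blob tracks corrupted.

    Modes: ``jitter`` adds heavy-tailed per-frame positional noise to the
    selected blobs; ``drift`` sends each on an independent smooth random
    walk; ``swap`` makes one pair of blobs cross paths.  Corrupted blob
    ids are recorded on the returned ground truth.  ``fraction = 0``
    reproduces the original movie.
    """
    if not 0 <= fraction <= 0.5:
        raise ValueError("fraction must be in [0, 0.5]")
    spec = truth.spec
    rng = np.random.default_rng(spec.seed + 2**20)   # independent of render rng
    L = truth.paths_px.shape[1]
    n = spec.n_frames
    n_corrupt = int(round(fraction * L))
    paths = truth.paths_px.copy()
    corrupt_ids: list[int] = []

    if n_corrupt > 0:
        eligible = [i for i in range(L) if i != truth.feature_id]
        if mode == "swap":
            n_pairs = max(1, n_corrupt // 2)
            chosen = rng.choice(eligible, size=2 * n_pairs, replace=False)
            s = 0.5 * (1 - np.cos(np.pi * np.linspace(0, 1, n)))[:, None]
            for a, b in chosen.reshape(-1, 2):
                pa, pb = paths[:, a].copy(), paths[:, b].copy()
                paths[:, a] = (1 - s) * pa + s * pb
                paths[:, b] = (1 - s) * pb + s * pa
            corrupt_ids = [int(i) for i in chosen]
        elif mode in ("jitter", "drift"):
            chosen = rng.choice(eligible, size=n_corrupt, replace=False)
            for i in chosen:
                if mode == "jitter":
                    noise = rng.standard_t(df=2, size=(n, 2)) * 1.0
                    noise[0] = 0
                    paths[:, i] += noise
                else:
                    steps = rng.normal(scale=0.8, size=(n, 2))
                    steps[0] = 0
                    walk = ndimage.gaussian_filter1d(
                        np.cumsum(steps, axis=0), sigma=2, axis=0)
                    paths[:, i] += walk - walk[0]
            corrupt_ids = [int(i) for i in chosen]
        else:
            raise ValueError(f"unknown corruption mode {mode!r}")

    render_rng = np.random.default_rng(spec.seed)
    _ = _landmark_grid(spec, render_rng)        # keep rng stream aligned
    _ = _build_warp(spec, render_rng, spec.times_s())
    _ = render_rng.uniform(*spec.ca_region_range, size=L)
    frames = _render(spec, paths, truth.blob_amps, truth.warp,
                     truth.ca_profile, render_rng)
    stack = ImageStack(frames, spec.pixel_width_um, spec.frame_interval_s)
    new_truth = SyntheticGroundTruth(spec, truth.centres0_px.copy(), paths,
                                     truth.blob_amps.copy(), truth.warp,
                                     truth.ca_profile.copy(),
                                     truth.feature_id,
                                     corrupt_ids=corrupt_ids)
    return stack, new_truth


def preset(name: str, seed: int = 1, **overrides) -> SyntheticSpec:
    """Named study conditions: 'contracting', 'zero_motion', 'translation'.

    ``zero_motion`` keeps the calcium-transient intensity programme but
    no warp and no sensor noise, isolating the claim that processing a
    motionless movie must not alter it; the transient scales the whole
    frame uniformly (per-region factors and the stable feature would be
    a *differential* intensity change, which biases any tracker by a few
    hundredths of a pixel and is a different effect).  ``translation``
    is a rigid drift (uniform field).
    """
    if name == "contracting":
        spec = SyntheticSpec(seed=seed)
    elif name == "zero_motion":
        spec = SyntheticSpec(seed=seed, global_peak_disp_um=0.0,
                             local_peak_disp_um=0.0, snr=np.inf,
                             ca_region_range=(1.0, 1.0),
                             bg_ca_coupling=1.0, stable_feature=False)
    elif name == "translation":
        spec = SyntheticSpec(seed=seed, global_peak_disp_um=0.0,
                             local_peak_disp_um=0.0,
                             rigid_translation_um=(24.0, -16.0))
    else:
        raise ValueError(f"unknown preset {name!r}")
    return replace(spec, **overrides)
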