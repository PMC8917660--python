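"""Centroid tracking, movie clipping, and egocentric frame alignment.

The tracking stage operates on raw grayscale stacks of the full arena: a
static background is estimated as the per-pixel median of frames sampled
at random across the recording, each frame is background-subtracted,
down-sampled and Gaussian-blurred, and the animal's centroid is taken as
the intensity-weighted center of the connected bright region containing
the maximum.  A fixed-size clip window centered on the centroid is
recorded per frame (clamped at the borders).
"""

from __future__ import annotations

import logging
import math

import numpy as np
from scipy import ndimage
from skimage.transform import downscale_local_mean

from .types import CentroidTrack, KeypointTimeSeries

__all__ = [
    "median_background",
    "track_centroid",
    "align_egocentric",
    "centroid_kinematics",
]

logger = logging.getLogger(__name__)

CLIP_WINDOW_PX = 400  # side of the square window clipped around the centroid


def median_background(
    stack: np.ndarray, n_samples: int = 50, seed: int = 0
) -> np.ndarray:
    """Per-pixel median over ``n_samples`` randomly sampled frames.

    Random sampling across the recording ensures the moving animal is
    absent from the majority of samples at every pixel, so the median
    contains only the stationary background.
    """
    n = stack.shape[0]
    if n_samples > n:
        raise ValueError(f"n_samples={n_samples} exceeds stack length {n}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(n, size=n_samples, replace=False)
    return np.median(stack[np.sort(idx)].astype(float), axis=0)


def _frame_centroid(
    frame: np.ndarray,
    background: np.ndarray,
    downsample: int,
    blur_sigma: float,
    rel_threshold: float,
) -> tuple[float, float] | None:
    """Centroid of one frame in full-frame pixels, or None when empty."""
    diff = np.clip(frame.astype(float) - background, 0.0, None)
    small = downscale_local_mean(diff, (downsample, downsample))
    small = ndimage.gaussian_filter(small, blur_sigma)
    peak = small.max()
    if peak <= 0:
        return None
    mask = small >= rel_threshold * peak
    labels, _ = ndimage.label(mask)
    peak_label = labels[np.unravel_index(np.argmax(small), small.shape)]
    region = labels == peak_label
    weights = np.where(region, small, 0.0)
    cy, cx = ndimage.center_of_mass(weights)
    # map back to full-frame coordinates (pixel centers of the blocks)
    return (
        (cx + 0.5) * downsample - 0.5,
        (cy + 0.5) * downsample - 0.5,
    )


def track_centroid(
    stack: np.ndarray,
    background: np.ndarray,
    downsample: int = 4,
    blur_sigma: float = 2.0,
    rel_threshold: float = 0.5,
    pixels_per_meter: float | None = None,
    clip_window: int = CLIP_WINDOW_PX,
) -> CentroidTrack:
    """Track the bright-blob centroid across a background-subtracted stack.

    Frames whose background-subtracted image is entirely zero are flagged
    as missing and linearly interpolated from their neighbors.  The clip
    window origin is clamped so the window stays inside the frame.
    """
    if background.shape != stack.shape[1:]:
        raise ValueError("background shape must match frame shape")
    n = stack.shape[0]
    h, w = stack.shape[1:]
    centroids = np.full((n, 2), np.nan)
    missing = np.zeros(n, dtype=bool)
    for i in range(n):
        c = _frame_centroid(stack[i], background, downsample, blur_sigma, rel_threshold)
        if c is None:
            missing[i] = True
        else:
            centroids[i] = c
    if missing.all():
        raise ValueError("no frame produced a trackable centroid")
    if missing.any():
        logger.warning("interpolating %d missing-centroid frames", missing.sum())
        good = np.flatnonzero(~missing)
        for axis in range(2):
            centroids[missing, axis] = np.interp(
                np.flatnonzero(missing), good, centroids[good, axis]
            )

    half = clip_window // 2
    origin = np.empty((n, 2))
    origin[:, 0] = np.clip(np.round(centroids[:, 0]) - half, 0, max(w - clip_window, 0))
    origin[:, 1] = np.clip(np.round(centroids[:, 1]) - half, 0, max(h - clip_window, 0))
    n_clamped = int(np.sum(origin[:, 0] != np.round(centroids[:, 0]) - half)) + int(
        np.sum(origin[:, 1] != np.round(centroids[:, 1]) - half)
    )
    if n_clamped:
        logger.info("clip window clamped at the border on %d frame-axes", n_clamped)

    centroid_m = (
        centroids / pixels_per_meter if pixels_per_meter else np.full_like(centroids, np.nan)
    )
    return CentroidTrack(
        centroid_px=centroids,
        centroid_m=centroid_m,
        rotation_rad=np.full(n, np.nan),
        clip_origin_px=origin,
        missing=missing,
    )


def align_egocentric(
    kp: KeypointTimeSeries,
    snout: str = "snout",
    tail_base: str = "tail_base",
) -> tuple[KeypointTimeSeries, np.ndarray]:
    """Translate/rotate each frame into the body frame.

    Each frame is translated so the tail-base marker sits at the origin
    and rotated so the tail-base-to-snout vector lies along +y.  Returns
    the aligned series and the per-frame rotation angle (the heading of
    the tail-to-snout axis in the original frame, rad).  Frames with
    coincident snout and tail base reuse the previous frame's rotation.
    """
    si, ti = kp.index(snout), kp.index(tail_base)
    pos = kp.positions
    v = pos[:, si, :] - pos[:, ti, :]
    norm = np.hypot(v[:, 0], v[:, 1])
    degenerate = norm < 1e-12
    heading = np.arctan2(v[:, 1], v[:, 0])
    if degenerate.any():
        logger.warning("%d frames with coincident snout/tail base", degenerate.sum())
        idx = np.flatnonzero(degenerate)
        for i in idx:
            heading[i] = heading[i - 1] if i > 0 else 0.0
    # rotate by (pi/2 - heading) so the body axis maps onto +y
    ang = math.pi / 2.0 - heading
    c, s = np.cos(ang), np.sin(ang)
    centered = pos - pos[:, ti, :][:, None, :]
    aligned = np.empty_like(centered)
    aligned[..., 0] = c[:, None] * centered[..., 0] - s[:, None] * centered[..., 1]
    aligned[..., 1] = s[:, None] * centered[..., 0] + c[:, None] * centered[..., 1]
    out = KeypointTimeSeries(
        positions=aligned,
        marker_names=list(kp.marker_names),
        frame_rate=kp.frame_rate,
        unit=kp.unit,
        confidence=kp.confidence,
        pixels_per_meter=kp.pixels_per_meter,
    )
    return out, heading


def _smooth(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x
    kernel = np.ones(window) / window
    pad = window // 2
    xp = np.pad(x, pad, mode="edge")
    out = np.convolve(xp, kernel, mode="same")[pad : pad + len(x)]
    return out


def centroid_kinematics(
    centroid_m: np.ndarray,
    frame_rate: float,
    smoothing_window: int = 9,
    heading: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame speed (m/s) and angular velocity (rad/s).

    Speed comes from centered differences of the smoothed metric centroid.
    Angular velocity differentiates the (unwrapped) heading; when no
    heading is supplied it is derived from the direction of motion.
    """
    centroid_m = np.asarray(centroid_m, dtype=float)
    if len(centroid_m) < 2:
        raise ValueError("need at least two frames")
    sm = np.column_stack(
        [_smooth(centroid_m[:, 0], smoothing_window), _smooth(centroid_m[:, 1], smoothing_window)]
    )
    vel = np.gradient(sm, axis=0) * frame_rate
    speed = np.hypot(vel[:, 0], vel[:, 1])
    if heading is None:
        heading = np.arctan2(vel[:, 1], vel[:, 0])
        # hold heading through stationary stretches to avoid noise spikes
        still = speed < 1e-4
        if still.any() and not still.all():
            good = np.flatnonzero(~still)
            heading[still] = np.interp(np.flatnonzero(still), good, heading[good])
    unwrapped = np.unwrap(np.asarray(heading, dtype=float))
    ang_vel = np.gradient(_smooth(unwrapped, smoothing_window)) * frame_rate
    return speed, ang_vel
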