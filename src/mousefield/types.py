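"""Core data containers shared across the pipeline.

Coordinate conventions
----------------------
Arena coordinates are metric, with the origin at one arena corner and both
axes spanning ``[0, arena_side]``.  Pixel coordinates follow the camera
frame (x right, y down is *not* assumed; synthetic rendering maps
``px = m * pixels_per_meter`` on both axes).  Egocentric (body-frame)
coordinates place the tail base at the origin with the tail-to-snout axis
along +y, so +y is anterior.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = ["KeypointTimeSeries", "CentroidTrack", "Ethogram"]


@dataclass
class KeypointTimeSeries:
    """Per-frame 2-D positions of named body markers at a fixed frame rate.

    Parameters
    ----------
    positions : ndarray, shape (n_frames, n_markers, 2)
        Marker coordinates, in the unit given by ``unit``.
    marker_names : list of str
        Ordered marker names; order defines the marker axis.
    frame_rate : float
        Sampling rate in Hz.
    unit : {"px", "m"}
        Coordinate unit tag.
    confidence : ndarray, shape (n_frames, n_markers), optional
        Per-marker tracking confidence in [0, 1].
    pixels_per_meter : float, optional
        Scale needed to convert between the two unit systems.
    """

    positions: np.ndarray
    marker_names: list[str]
    frame_rate: float
    unit: str = "px"
    confidence: np.ndarray | None = None
    pixels_per_meter: float | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 2:
            raise ValueError("positions must have shape (n_frames, n_markers, 2)")
        if self.positions.shape[1] != len(self.marker_names):
            raise ValueError("marker_names length does not match positions")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.unit not in ("px", "m"):
            raise ValueError(f"unknown unit {self.unit!r}")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_markers(self) -> int:
        return self.positions.shape[1]

    def index(self, name: str) -> int:
        try:
            return self.marker_names.index(name)
        except ValueError:
            raise KeyError(f"unknown marker {name!r}") from None

    def marker(self, name: str) -> np.ndarray:
        """Trajectory of one marker, shape (n_frames, 2)."""
        return self.positions[:, self.index(name), :]

    def subset(self, markers: Sequence[str]) -> "KeypointTimeSeries":
        idx = [self.index(m) for m in markers]
        return KeypointTimeSeries(
            positions=self.positions[:, idx, :].copy(),
            marker_names=list(markers),
            frame_rate=self.frame_rate,
            unit=self.unit,
            confidence=None if self.confidence is None else self.confidence[:, idx].copy(),
            pixels_per_meter=self.pixels_per_meter,
        )

    def to_meters(self) -> "KeypointTimeSeries":
        if self.unit == "m":
            return self
        if self.pixels_per_meter is None:
            raise ValueError("pixels_per_meter required to convert px -> m")
        return KeypointTimeSeries(
            positions=self.positions / self.pixels_per_meter,
            marker_names=list(self.marker_names),
            frame_rate=self.frame_rate,
            unit="m",
            confidence=self.confidence,
            pixels_per_meter=self.pixels_per_meter,
        )


@dataclass
class CentroidTrack:
    """Centroid trajectory with clip-window bookkeeping.

    ``centroid_px`` is in full-frame pixels, ``centroid_m`` in arena meters.
    ``rotation_rad`` holds the egocentric alignment angle where available
    (NaN otherwise).  ``clip_origin_px`` is the top-left corner of the clip
    window recorded per frame; ``missing`` flags frames whose centroid had
    to be interpolated.
    """

    centroid_px: np.ndarray
    centroid_m: np.ndarray
    rotation_rad: np.ndarray
    clip_origin_px: np.ndarray
    missing: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = len(self.centroid_px)
        if self.missing is None:
            self.missing = np.zeros(n, dtype=bool)
        for name in ("centroid_m", "rotation_rad", "clip_origin_px", "missing"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length does not match centroid_px")

    @property
    def n_frames(self) -> int:
        return len(self.centroid_px)


@dataclass
class Ethogram:
    """Per-frame behavioral labels plus centroid kinematics.

    ``fine_labels`` are 1-based cluster ids (1..k); ``coarse_labels`` are
    1-based class ids (1..8) after applying the cluster-to-class map.
    """

    fine_labels: np.ndarray
    coarse_labels: np.ndarray
    speed: np.ndarray
    arena_xy: np.ndarray
    frame_rate: float
    class_names: dict[int, str] | None = None

    def __post_init__(self) -> None:
        n = len(self.fine_labels)
        for name in ("coarse_labels", "speed", "arena_xy"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length does not match fine_labels")

    @property
    def n_frames(self) -> int:
        return len(self.fine_labels)
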