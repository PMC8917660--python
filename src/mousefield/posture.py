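"""Rotation/translation-invariant posture representation.

Posture at each frame is encoded as the vector of Euclidean distances
between all pairs of tracked markers.  Unlike egocentric coordinates,
pairwise distances are exactly invariant to rigid transforms of the
camera frame, so no alignment axis has to be chosen (mouse bodies are not
rigid and any axis choice biases the representation toward the markers
that define it).  The distance vectors are then reduced to a small number
of postural modes by PCA, accumulated in streaming fashion over an entire
set of recordings.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .types import KeypointTimeSeries

__all__ = [
    "DEFAULT_POSTURE_MARKERS",
    "DistanceSeries",
    "PcaModel",
    "PostureProjection",
    "pairwise_distances",
    "StreamingPCA",
    "streaming_pca_fit",
    "project",
    "explained_variance",
]

#: Default 11-marker high-confidence subset (tail tip excluded).
DEFAULT_POSTURE_MARKERS = [
    "snout",
    "chin",
    "front_left_paw",
    "front_right_paw",
    "hind_left_paw",
    "hind_right_paw",
    "front_left_outer",
    "front_right_outer",
    "hind_left_outer",
    "hind_right_outer",
    "tail_base",
]

#: Confidence below which a marker is excluded when confidence is given.
CONFIDENCE_THRESHOLD = 0.85


@dataclass
class DistanceSeries:
    """Per-frame pairwise marker distances.

    ``values`` has one column per unordered marker pair (i < j), in
    row-major order over the pair index; ``pair_index`` records which
    markers each column refers to.  Column ordering is persisted with the
    PCA model so projections are bit-stable across sessions.
    """

    values: np.ndarray  # (n_frames, P)
    pair_index: list[tuple[int, int]]
    marker_names: list[str]
    frame_rate: float

    def __post_init__(self) -> None:
        m = len(self.marker_names)
        if self.values.shape[1] != m * (m - 1) // 2:
            raise ValueError("column count inconsistent with marker count")
        if np.any(self.values < 0):
            raise ValueError("distances must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass
class PcaModel:
    """Mean, eigenvectors and eigenvalues of the distance covariance."""

    mean: np.ndarray  # (P,)
    eigenvectors: np.ndarray  # (P, P), columns sorted by eigenvalue desc
    eigenvalues: np.ndarray  # (P,), descending, >= 0
    n_frames_seen: int
    pair_index: list[tuple[int, int]] | None = None
    marker_names: list[str] | None = None

    @property
    def n_features(self) -> int:
        return len(self.mean)


@dataclass
class PostureProjection:
    """Scores of each frame along the top postural modes."""

    scores: np.ndarray  # (n_frames, n_modes)
    frame_rate: float
    model_ref: str = ""

    @property
    def n_frames(self) -> int:
        return self.scores.shape[0]

    @property
    def n_modes(self) -> int:
        return self.scores.shape[1]


def pairwise_distances(
    kp: KeypointTimeSeries, markers: Sequence[str] | None = None
) -> DistanceSeries:
    """Distances between all marker pairs at every frame.

    Markers flagged low-confidence (median confidence below
    ``CONFIDENCE_THRESHOLD``) are dropped when confidence is available and
    no explicit subset is requested.
    """
    if markers is None:
        markers = [m for m in DEFAULT_POSTURE_MARKERS if m in kp.marker_names]
        if not markers:
            markers = list(kp.marker_names)
        if kp.confidence is not None:
            med = np.median(kp.confidence, axis=0)
            markers = [
                m for m in markers if med[kp.index(m)] >= CONFIDENCE_THRESHOLD
            ]
    if len(markers) < 3:
        raise ValueError("need at least three markers")
    idx = [kp.index(m) for m in markers]
    pos = kp.positions[:, idx, :]
    if np.isnan(pos).any():
        raise ValueError("NaN positions; preprocess before computing distances")
    m = len(idx)
    pairs = [(i, j) for i in range(m) for j in range(i + 1, m)]
    diffs = pos[:, [p[0] for p in pairs], :] - pos[:, [p[1] for p in pairs], :]
    values = np.hypot(diffs[..., 0], diffs[..., 1])
    return DistanceSeries(
        values=values,
        pair_index=pairs,
        marker_names=list(markers),
        frame_rate=kp.frame_rate,
    )


class StreamingPCA:
    """Online PCA via numerically stable batch merging.

    Accumulates exact counts, means and co-moments (Chan et al. pairwise
    update) over batches of frames, then eigendecomposes the final
    covariance.  The result is identical to PCA on the concatenated data
    up to floating-point error.
    """

    def __init__(self) -> None:
        self.n = 0
        self.mean: np.ndarray | None = None
        self.comoment: np.ndarray | None = None
        self.pair_index: list[tuple[int, int]] | None = None
        self.marker_names: list[str] | None = None

    def partial_fit(self, block: np.ndarray | DistanceSeries) -> "StreamingPCA":
        if isinstance(block, DistanceSeries):
            if self.pair_index is None:
                self.pair_index = list(block.pair_index)
                self.marker_names = list(block.marker_names)
            elif self.pair_index != list(block.pair_index):
                raise ValueError("batch pair ordering mismatch")
            x = block.values
        else:
            x = np.asarray(block, dtype=float)
        if x.ndim != 2 or x.shape[0] == 0:
            raise ValueError("each batch must be a non-empty 2-D array")
        nb = x.shape[0]
        mb = x.mean(axis=0)
        xc = x - mb
        cb = xc.T @ xc
        if self.mean is None:
            self.n, self.mean, self.comoment = nb, mb, cb
            return self
        if x.shape[1] != len(self.mean):
            raise ValueError("batch feature width mismatch")
        delta = mb - self.mean
        n_tot = self.n + nb
        self.comoment = self.comoment + cb + np.outer(delta, delta) * (self.n * nb / n_tot)
        self.mean = self.mean + delta * (nb / n_tot)
        self.n = n_tot
        return self

    def covariance(self, ddof: int = 1) -> np.ndarray:
        if self.n <= ddof:
            raise ValueError("not enough frames accumulated")
        return self.comoment / (self.n - ddof)

    def finalize(self) -> PcaModel:
        cov = self.covariance()
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        evals = np.clip(evals[order], 0.0, None)
        evecs = evecs[:, order]
        # sign convention: largest-magnitude loading of each mode positive
        flips = np.sign(evecs[np.argmax(np.abs(evecs), axis=0), np.arange(evecs.shape[1])])
        flips[flips == 0] = 1.0
        evecs = evecs * flips
        return PcaModel(
            mean=self.mean.copy(),
            eigenvectors=evecs,
            eigenvalues=evals,
            n_frames_seen=self.n,
            pair_index=self.pair_index,
            marker_names=self.marker_names,
        )


def streaming_pca_fit(batches: Iterable[DistanceSeries | np.ndarray]) -> PcaModel:
    """Fit posture PCA over an iterator of distance blocks."""
    acc = StreamingPCA()
    empty = True
    for block in batches:
        acc.partial_fit(block)
        empty = False
    if empty:
        raise ValueError("no batches supplied")
    if acc.n < len(acc.mean):
        raise ValueError("fewer frames than features; PCA would be degenerate")
    return acc.finalize()


def project(
    ds: DistanceSeries | np.ndarray, model: PcaModel, n_modes: int = 10
) -> PostureProjection:
    """Project distance vectors onto the top postural modes."""
    x = ds.values if isinstance(ds, DistanceSeries) else np.asarray(ds, dtype=float)
    if x.shape[1] != model.n_features:
        raise ValueError("feature width does not match the model")
    if n_modes > model.eigenvectors.shape[1]:
        raise ValueError("n_modes exceeds available eigenvectors")
    scores = (x - model.mean) @ model.eigenvectors[:, :n_modes]
    fr = ds.frame_rate if isinstance(ds, DistanceSeries) else float("nan")
    return PostureProjection(scores=scores, frame_rate=fr)


def explained_variance(model: PcaModel, n_modes: int) -> float:
    """Fraction of total variance captured by the top ``n_modes`` modes."""
    total = model.eigenvalues.sum()
    if total <= 0:
        return 0.0
    return float(model.eigenvalues[:n_modes].sum() / total)
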