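"""Behavioral vocabulary: template sampling, k-means, and reembedding.

Frame-wise wavelet features are heavily unbalanced — common behaviors
like steady locomotion would dominate any clustering fit directly on all
frames.  The vocabulary is therefore built in three stages:

1. *Template sampling.*  Each movie is embedded independently to 2-D, the
   embedding's density map is segmented by a watershed, and ~100 template
   frames per movie are drawn near-uniformly across density modes so that
   even rare behaviors are represented.
2. *k-means.*  The pooled templates (~40,000 at full scale) are clustered
   with k-means (default k=100, k-means++ init, 10 restarts).
3. *Reembedding.*  Every frame of every movie is assigned the cluster of
   its exact nearest training template (Euclidean; ties go to the lowest
   template index), which makes labeling new recordings cheap and
   deterministic.

The 100 fine clusters are mapped onto eight coarse behavioral classes by
a user-editable class map (a manual curation step at full scale; for
synthetic data :func:`class_map_from_truth` builds it automatically).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from sklearn.cluster import KMeans

from .synthetic import COARSE_CLASS_NAMES
from .dynamics import WaveletSpectrogram
from .types import Ethogram

__all__ = [
    "TemplateSet",
    "ClusterModel",
    "sample_templates",
    "fit_kmeans",
    "reembed",
    "apply_class_map",
    "annotation_agreement",
    "class_map_from_truth",
    "make_ethogram",
]

logger = logging.getLogger(__name__)


@dataclass
class TemplateSet:
    """Importance-sampled training frames pooled across movies."""

    features: np.ndarray  # (n_templates, n_features)
    source: list[tuple[str, int]]  # (trial id, frame index) per template

    def __post_init__(self) -> None:
        if len(self.source) != len(self.features):
            raise ValueError("source length must match features")
        if len(set(self.source)) != len(self.source):
            raise ValueError("duplicate (trial, frame) template entries")

    @property
    def n_templates(self) -> int:
        return len(self.features)

    @staticmethod
    def concatenate(parts: list["TemplateSet"]) -> "TemplateSet":
        return TemplateSet(
            features=np.vstack([p.features for p in parts]),
            source=[s for p in parts for s in p.source],
        )


@dataclass
class ClusterModel:
    """k-means vocabulary plus the fine-cluster -> coarse-class map."""

    centroids: np.ndarray  # (k, n_features)
    templates: np.ndarray  # (n_templates, n_features)
    assignments: np.ndarray  # (n_templates,) 1-based fine cluster ids
    seed: int
    class_map: dict[int, int] | None = None  # fine id -> coarse id (1..8)
    class_names: dict[int, str] = field(default_factory=lambda: dict(COARSE_CLASS_NAMES))

    @property
    def k(self) -> int:
        return len(self.centroids)

    def validate_class_map(self) -> None:
        if self.class_map is None:
            raise ValueError("class_map is unset")
        missing = set(range(1, self.k + 1)) - set(self.class_map)
        if missing:
            raise ValueError(f"class_map misses fine clusters {sorted(missing)}")


def _embed_2d(
    features: np.ndarray, method: str, perplexity: float, seed: int
) -> np.ndarray:
    if method == "tsne":
        from sklearn.manifold import TSNE

        perp = min(perplexity, max((len(features) - 1) / 3.0, 2.0))
        return TSNE(
            n_components=2, perplexity=perp, init="pca", random_state=seed
        ).fit_transform(features)
    if method == "pca":
        from sklearn.decomposition import PCA

        return PCA(n_components=2, random_state=seed).fit_transform(features)
    raise ValueError(f"unknown embedding method {method!r}")


def _watershed_segments(points: np.ndarray, n_bins: int = 64) -> np.ndarray:
    """Label each 2-D point by the watershed basin of the density map."""
    from skimage.feature import peak_local_max
    from skimage.segmentation import watershed

    lo = points.min(axis=0)
    hi = points.max(axis=0)
    span = np.where(hi - lo > 0, hi - lo, 1.0)
    ij = np.clip(((points - lo) / span * (n_bins - 1)).astype(int), 0, n_bins - 1)
    hist = np.zeros((n_bins, n_bins))
    np.add.at(hist, (ij[:, 0], ij[:, 1]), 1.0)
    density = ndimage.gaussian_filter(hist, sigma=2.0)
    peaks = peak_local_max(density, min_distance=3, exclude_border=False)
    if len(peaks) == 0:
        return np.zeros(len(points), dtype=int)
    markers = np.zeros_like(hist, dtype=int)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    basins = watershed(-density, markers)
    return basins[ij[:, 0], ij[:, 1]] - 1


def sample_templates(
    spectrogram: WaveletSpectrogram | np.ndarray,
    per_movie_target: int = 100,
    embed_params: dict | None = None,
    seed: int = 0,
    trial_id: str = "trial",
) -> TemplateSet:
    """Draw a density-stratified set of template frames from one movie.

    The movie's frames (subsampled to at most ``max_points``) are embedded
    to 2-D, the embedding density is segmented into modes by a watershed,
    and templates are drawn near-uniformly across segments — every
    segment contributes at least one template, which enriches rare
    behaviors relative to their frame count.
    """
    params = {"method": "tsne", "perplexity": 32.0, "max_points": 20000}
    params.update(embed_params or {})
    feats = spectrogram.power if isinstance(spectrogram, WaveletSpectrogram) else spectrogram
    n = len(feats)
    if n < per_movie_target:
        raise ValueError("movie shorter than the per-movie template target")
    stride = max(1, int(np.ceil(n / params["max_points"])))
    frame_idx = np.arange(0, n, stride)
    sub = feats[frame_idx]
    rng = np.random.default_rng(seed)

    if np.allclose(sub.std(axis=0), 0.0):
        logger.warning("degenerate embedding input; uniform template sampling")
        pick = rng.choice(len(sub), size=min(per_movie_target, len(sub)), replace=False)
    else:
        emb = _embed_2d(sub, params["method"], params["perplexity"], seed)
        segments = _watershed_segments(emb)
        seg_ids = np.unique(segments)
        # round-robin allocation across segments, rarest first
        order = seg_ids[np.argsort([np.sum(segments == s) for s in seg_ids])]
        pools = {s: rng.permutation(np.flatnonzero(segments == s)) for s in seg_ids}
        taken: list[int] = []
        cursor = {s: 0 for s in seg_ids}
        while len(taken) < min(per_movie_target, len(sub)):
            progressed = False
            for s in order:
                if cursor[s] < len(pools[s]):
                    taken.append(int(pools[s][cursor[s]]))
                    cursor[s] += 1
                    progressed = True
                    if len(taken) >= min(per_movie_target, len(sub)):
                        break
            if not progressed:
                break
        pick = np.array(sorted(taken))
    idx = frame_idx[pick]
    return TemplateSet(
        features=np.asarray(feats)[idx].copy(),
        source=[(trial_id, int(i)) for i in idx],
    )


def fit_kmeans(
    templates: TemplateSet, k: int = 100, seed: int = 0, n_init: int = 10
) -> ClusterModel:
    """k-means vocabulary on the pooled template set (class map unset)."""
    if templates.n_templates < k:
        raise ValueError("fewer templates than clusters")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(templates.features)
    return ClusterModel(
        centroids=km.cluster_centers_,
        templates=templates.features,
        assignments=labels + 1,
        seed=seed,
    )


def reembed(
    spectrogram: WaveletSpectrogram | np.ndarray,
    model: ClusterModel,
    chunk: int = 2048,
) -> np.ndarray:
    """Assign every frame the cluster of its nearest training template.

    Exact nearest neighbor under the Euclidean metric; equidistant
    templates resolve to the lowest template index, so the assignment is
    fully deterministic.
    """
    feats = spectrogram.power if isinstance(spectrogram, WaveletSpectrogram) else spectrogram
    feats = np.asarray(feats, dtype=float)
    if feats.shape[1] != model.templates.shape[1]:
        raise ValueError("feature width does not match the cluster model")
    t = model.templates
    t_sq = np.einsum("ij,ij->i", t, t)
    labels = np.empty(len(feats), dtype=int)
    for start in range(0, len(feats), chunk):
        block = feats[start : start + chunk]
        d2 = block @ t.T
        d2 *= -2.0
        d2 += t_sq[None, :]
        # np.argmin returns the first minimum -> lowest template index
        nn = np.argmin(d2, axis=1)
        labels[start : start + chunk] = model.assignments[nn]
    return labels


def apply_class_map(fine_labels: np.ndarray, class_map: dict[int, int]) -> np.ndarray:
    """Map fine cluster ids onto coarse class ids."""
    fine_labels = np.asarray(fine_labels)
    unmapped = set(np.unique(fine_labels)) - set(class_map)
    if unmapped:
        raise KeyError(f"fine clusters without a class mapping: {sorted(unmapped)}")
    lut_size = max(class_map) + 1
    lut = np.zeros(lut_size, dtype=int)
    for fine, coarse in class_map.items():
        lut[fine] = coarse
    return lut[fine_labels]


def annotation_agreement(
    labels_a: np.ndarray, labels_b: np.ndarray
) -> tuple[float, "np.ndarray", list]:
    """Frame-wise agreement fraction and class-by-class confusion table."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if len(a) != len(b):
        raise ValueError("label sequences differ in length")
    classes = sorted(set(np.unique(a)) | set(np.unique(b)))
    index = {c: i for i, c in enumerate(classes)}
    confusion = np.zeros((len(classes), len(classes)), dtype=int)
    ai = np.array([index[x] for x in a])
    bi = np.array([index[x] for x in b])
    np.add.at(confusion, (ai, bi), 1)
    agreement = float(np.mean(a == b))
    return agreement, confusion, classes


def class_map_from_truth(
    fine_labels: np.ndarray, coarse_truth: np.ndarray, k: int
) -> dict[int, int]:
    """Majority-vote class map for a synthetic vocabulary.

    At full scale the fine-to-coarse map is a manual curation step; on
    synthetic data the generator's ground-truth class of each frame
    stands in for the curator: each fine cluster maps to the most common
    true class among its frames.  Clusters never seen default to class 1.
    """
    fine_labels = np.asarray(fine_labels)
    coarse_truth = np.asarray(coarse_truth)
    cmap: dict[int, int] = {}
    for fine in range(1, k + 1):
        mask = fine_labels == fine
        if mask.any():
            vals, counts = np.unique(coarse_truth[mask], return_counts=True)
            cmap[fine] = int(vals[np.argmax(counts)])
        else:
            cmap[fine] = 1
    return cmap


def make_ethogram(
    fine_labels: np.ndarray,
    model: ClusterModel,
    speed: np.ndarray,
    arena_xy: np.ndarray,
    frame_rate: float,
) -> Ethogram:
    """Bundle labels and centroid kinematics into an ethogram."""
    model.validate_class_map()
    coarse = apply_class_map(fine_labels, model.class_map)
    return Ethogram(
        fine_labels=np.asarray(fine_labels),
        coarse_labels=coarse,
        speed=np.asarray(speed),
        arena_xy=np.asarray(arena_xy),
        frame_rate=frame_rate,
        class_names=dict(model.class_names),
    )
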