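"""End-to-end phenotyping: keypoints -> ethograms -> group statistics.

Convenience driver that chains the library stages at their defaults:
pairwise-distance posture representation, streaming PCA to 10 modes,
Morlet wavelet spectrograms (25 dyadic channels, 0.25-20 Hz), density
stratified template sampling, k-means vocabulary, nearest-template
reembedding, and per-trial ethograms with centroid kinematics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import clustering, dynamics, posture, tracking
from .synthetic import SyntheticTrial
from .types import Ethogram

__all__ = ["PipelineConfig", "PipelineResult", "run_phenotyping"]


@dataclass
class PipelineConfig:
    n_modes: int = 10
    f_min: float = 0.25
    f_max: float = 20.0
    n_freqs: int = 25
    omega0: float = 5.0
    per_movie_templates: int = 100
    k: int = 100
    kmeans_restarts: int = 10
    embed_params: dict = field(default_factory=dict)
    posture_markers: list[str] | None = None
    seed: int = 0


@dataclass
class PipelineResult:
    pca_model: posture.PcaModel
    cluster_model: clustering.ClusterModel
    ethograms: dict[str, Ethogram]
    spectrogram_width: int


def run_phenotyping(
    trials: dict[str, SyntheticTrial],
    config: PipelineConfig | None = None,
    truth_class_map: bool = True,
) -> PipelineResult:
    """Run the full clustering pipeline over a set of synthetic trials.

    With ``truth_class_map`` the fine-to-coarse class map is derived from
    the generator's ground truth by majority vote (the stand-in for the
    manual curation step); otherwise the map must be set on the returned
    cluster model before ethograms can be recomputed.
    """
    cfg = config or PipelineConfig()
    # posture representation and shared PCA across all trials
    distance_series = {}
    acc = posture.StreamingPCA()
    for tid, trial in trials.items():
        # posture features stay in pixel units: the -3 log-power floor is
        # calibrated for pixel-scale marker displacements
        ds = posture.pairwise_distances(trial.keypoints, cfg.posture_markers)
        distance_series[tid] = ds
        acc.partial_fit(ds)
    pca_model = acc.finalize()

    grid = dynamics.dyadic_frequencies(cfg.f_min, cfg.f_max, cfg.n_freqs)
    spectrograms = {}
    templates = []
    for i, (tid, trial) in enumerate(trials.items()):
        proj = posture.project(distance_series[tid], pca_model, cfg.n_modes)
        spec = dynamics.wavelet_transform(
            proj.scores, grid, trial.keypoints.frame_rate, omega0=cfg.omega0
        )
        spectrograms[tid] = spec
        templates.append(
            clustering.sample_templates(
                spec,
                per_movie_target=cfg.per_movie_templates,
                embed_params=cfg.embed_params,
                seed=cfg.seed + i,
                trial_id=tid,
            )
        )
    pooled = clustering.TemplateSet.concatenate(templates)
    model = clustering.fit_kmeans(pooled, k=cfg.k, seed=cfg.seed, n_init=cfg.kmeans_restarts)

    fine = {tid: clustering.reembed(spectrograms[tid], model) for tid in trials}
    if truth_class_map:
        all_fine = np.concatenate([fine[tid] for tid in trials])
        all_truth = np.concatenate([trials[tid].coarse_truth() for tid in trials])
        model.class_map = clustering.class_map_from_truth(all_fine, all_truth, model.k)

    ethograms = {}
    for tid, trial in trials.items():
        speed, _ = tracking.centroid_kinematics(
            trial.centroid_truth, trial.keypoints.frame_rate
        )
        ethograms[tid] = clustering.make_ethogram(
            fine[tid], model, speed, trial.centroid_truth, trial.keypoints.frame_rate
        )
    return PipelineResult(
        pca_model=pca_model,
        cluster_model=model,
        ethograms=ethograms,
        spectrogram_width=cfg.n_modes * cfg.n_freqs,
    )
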