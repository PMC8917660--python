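"""HDF5 / JSON / CSV persistence for pipeline artifacts.

Keypoint layout: ``/keypoints`` (frames x markers x 2) with ``/meta``
attributes (frame_rate, pixels_per_meter, marker names); synthetic ground
truth lives in a parallel ``/truth`` group.  Video stacks are stored as
``/frames``.  Models keep their arrays under short root-level datasets.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .clustering import ClusterModel
from .posture import PcaModel
from .types import CentroidTrack, Ethogram, KeypointTimeSeries

__all__ = [
    "save_keypoints",
    "load_keypoints",
    "save_video",
    "load_video",
    "save_track",
    "load_track",
    "save_pca_model",
    "load_pca_model",
    "save_cluster_model",
    "load_cluster_model",
    "save_class_map",
    "load_class_map",
    "save_ethogram",
    "load_ethogram",
]


def save_keypoints(path: str | Path, kp: KeypointTimeSeries, truth: dict | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("keypoints", data=kp.positions)
        meta = f.create_group("meta")
        meta.attrs["frame_rate"] = kp.frame_rate
        meta.attrs["unit"] = kp.unit
        meta.attrs["marker_names"] = [m.encode() for m in kp.marker_names]
        if kp.pixels_per_meter is not None:
            meta.attrs["pixels_per_meter"] = kp.pixels_per_meter
        if kp.confidence is not None:
            f.create_dataset("confidence", data=kp.confidence)
        if truth:
            g = f.create_group("truth")
            for key, val in truth.items():
                arr = np.asarray(val)
                if arr.dtype.kind == "U":
                    arr = arr.astype(h5py.string_dtype())
                g.create_dataset(key, data=arr)


def load_keypoints(path: str | Path) -> KeypointTimeSeries:
    with h5py.File(path, "r") as f:
        meta = f["meta"].attrs
        return KeypointTimeSeries(
            positions=f["keypoints"][:],
            marker_names=[
                m.decode() if isinstance(m, bytes) else str(m)
                for m in meta["marker_names"]
            ],
            frame_rate=float(meta["frame_rate"]),
            unit=str(meta.get("unit", "px")),
            confidence=f["confidence"][:] if "confidence" in f else None,
            pixels_per_meter=float(meta["pixels_per_meter"])
            if "pixels_per_meter" in meta
            else None,
        )


def save_video(path: str | Path, stack: np.ndarray, frame_rate: float = 80.0) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("frames", data=stack, compression="gzip")
        d.attrs["frame_rate"] = frame_rate


def load_video(path: str | Path) -> np.ndarray:
    with h5py.File(path, "r") as f:
        return f["frames"][:]


def save_track(path: str | Path, track: CentroidTrack) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("centroid_px", data=track.centroid_px)
        f.create_dataset("centroid_m", data=track.centroid_m)
        f.create_dataset("rotation_rad", data=track.rotation_rad)
        f.create_dataset("clip_origin_px", data=track.clip_origin_px)
        f.create_dataset("missing", data=track.missing)


def load_track(path: str | Path) -> CentroidTrack:
    with h5py.File(path, "r") as f:
        return CentroidTrack(
            centroid_px=f["centroid_px"][:],
            centroid_m=f["centroid_m"][:],
            rotation_rad=f["rotation_rad"][:],
            clip_origin_px=f["clip_origin_px"][:],
            missing=f["missing"][:].astype(bool),
        )


def save_pca_model(path: str | Path, model: PcaModel) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("mean", data=model.mean)
        f.create_dataset("eigenvectors", data=model.eigenvectors)
        f.create_dataset("eigenvalues", data=model.eigenvalues)
        f.attrs["n_frames_seen"] = model.n_frames_seen
        if model.pair_index is not None:
            f.create_dataset("pair_index", data=np.array(model.pair_index))
        if model.marker_names is not None:
            f.attrs["marker_names"] = [m.encode() for m in model.marker_names]


def load_pca_model(path: str | Path) -> PcaModel:
    with h5py.File(path, "r") as f:
        return PcaModel(
            mean=f["mean"][:],
            eigenvectors=f["eigenvectors"][:],
            eigenvalues=f["eigenvalues"][:],
            n_frames_seen=int(f.attrs["n_frames_seen"]),
            pair_index=[tuple(p) for p in f["pair_index"][:]]
            if "pair_index" in f
            else None,
            marker_names=[
                m.decode() if isinstance(m, bytes) else str(m)
                for m in f.attrs["marker_names"]
            ]
            if "marker_names" in f.attrs
            else None,
        )


def save_cluster_model(path: str | Path, model: ClusterModel) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("centroids", data=model.centroids)
        f.create_dataset("templates", data=model.templates)
        f.create_dataset("assignments", data=model.assignments)
        f.attrs["seed"] = model.seed
        if model.class_map is not None:
            f.attrs["class_map"] = json.dumps(model.class_map)
        f.attrs["class_names"] = json.dumps(model.class_names)


def load_cluster_model(path: str | Path) -> ClusterModel:
    with h5py.File(path, "r") as f:
        class_map = None
        if "class_map" in f.attrs:
            class_map = {int(k): int(v) for k, v in json.loads(f.attrs["class_map"]).items()}
        return ClusterModel(
            centroids=f["centroids"][:],
            templates=f["templates"][:],
            assignments=f["assignments"][:],
            seed=int(f.attrs["seed"]),
            class_map=class_map,
            class_names={int(k): v for k, v in json.loads(f.attrs["class_names"]).items()},
        )


def save_class_map(path: str | Path, class_map: dict[int, int]) -> None:
    Path(path).write_text(json.dumps({str(k): int(v) for k, v in class_map.items()}, indent=1))


def load_class_map(path: str | Path) -> dict[int, int]:
    return {int(k): int(v) for k, v in json.loads(Path(path).read_text()).items()}


def save_ethogram(path: str | Path, eth: Ethogram) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("fine_labels", data=eth.fine_labels)
        f.create_dataset("coarse_labels", data=eth.coarse_labels)
        f.create_dataset("speed", data=eth.speed)
        f.create_dataset("arena_xy", data=eth.arena_xy)
        f.attrs["frame_rate"] = eth.frame_rate
        if eth.class_names:
            f.attrs["class_names"] = json.dumps(eth.class_names)


def load_ethogram(path: str | Path) -> Ethogram:
    with h5py.File(path, "r") as f:
        names = None
        if "class_names" in f.attrs:
            names = {int(k): v for k, v in json.loads(f.attrs["class_names"]).items()}
        return Ethogram(
            fine_labels=f["fine_labels"][:],
            coarse_labels=f["coarse_labels"][:],
            speed=f["speed"][:],
            arena_xy=f["arena_xy"][:],
            frame_rate=float(f.attrs["frame_rate"]),
            class_names=names,
        )
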