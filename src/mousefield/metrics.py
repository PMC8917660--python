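"""Behavioral usage, habituation, spatial occupancy, and grooming modes.

Usage is the normalized histogram of behavioral labels over a trial (or a
sliding window of it): a composition over the 100 fine clusters or the 8
coarse classes that sums to one.  Spatial metrics quantify thigmotaxis —
time in the corner zones of the arena and the number of crossings through
its center.  Grooming decomposes into sub-modes (body; face/paw; small
quick movements; foot scratching; mixture) whose episode frequencies are
normalized per mouse.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import Ethogram

__all__ = [
    "ZoneConfig",
    "usage",
    "usage_over_time",
    "spatial_occupancy",
    "grooming_modes",
    "habituation_summary",
    "cohens_d",
    "episode_runs",
]

logger = logging.getLogger(__name__)


@dataclass
class ZoneConfig:
    """Arena zone geometry (meters).

    Defaults: a corner square of side ``arena_side/4`` in each corner and
    a concentric center square of side ``arena_side/2``; corner and
    center zones are disjoint by construction.
    """

    arena_side: float = 0.457
    corner_side: float | None = None
    center_side: float | None = None

    def __post_init__(self) -> None:
        if self.corner_side is None:
            self.corner_side = self.arena_side / 4.0
        if self.center_side is None:
            self.center_side = self.arena_side / 2.0
        if self.corner_side * 2 > self.arena_side - self.center_side:
            raise ValueError("corner and center zones overlap")

    def in_corner(self, xy: np.ndarray) -> np.ndarray:
        a, c = self.arena_side, self.corner_side
        x, y = xy[:, 0], xy[:, 1]
        near_x = (x <= c) | (x >= a - c)
        near_y = (y <= c) | (y >= a - c)
        return near_x & near_y

    def in_center(self, xy: np.ndarray) -> np.ndarray:
        a, c = self.arena_side, self.center_side
        lo, hi = (a - c) / 2.0, (a + c) / 2.0
        x, y = xy[:, 0], xy[:, 1]
        return (x >= lo) & (x <= hi) & (y >= lo) & (y <= hi)


def usage(eth: Ethogram, level: str = "coarse", n_labels: int | None = None) -> pd.Series:
    """Fraction of frames per behavioral label; sums to one.

    ``n_labels`` fixes the label axis (e.g. 8 coarse classes or 100 fine
    clusters) so rows from different trials align even when some labels
    never occur.
    """
    labels = eth.coarse_labels if level == "coarse" else eth.fine_labels
    if len(labels) == 0:
        raise ValueError("empty ethogram")
    if n_labels is None:
        n_labels = 8 if level == "coarse" else int(labels.max())
    counts = np.bincount(labels, minlength=n_labels + 1)[1 : n_labels + 1]
    frac = counts / counts.sum()
    return pd.Series(frac, index=np.arange(1, n_labels + 1), name=level)


def usage_over_time(
    eths: dict[str, Ethogram],
    window_s: float = 180.0,
    step_s: float = 30.0,
    level: str = "coarse",
    n_labels: int = 8,
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Sliding-window usage per mouse with a group mean and 95% CI.

    The CI at each window is a percentile bootstrap over mice (the
    between-animal variability is what matters for a group curve), with
    ``n_boot`` resamples.
    """
    if len(eths) < 2:
        raise ValueError("need at least two mice for a group CI")
    rng = np.random.default_rng(seed)
    rows = []
    per_mouse: dict[str, np.ndarray] = {}
    window = step = None
    for mouse, eth in eths.items():
        fs = eth.frame_rate
        window = int(round(window_s * fs))
        step = int(round(step_s * fs))
        labels = eth.coarse_labels if level == "coarse" else eth.fine_labels
        if window > len(labels):
            raise ValueError("window longer than the trial")
        starts = np.arange(0, len(labels) - window + 1, step)
        comp = np.empty((len(starts), n_labels))
        for wi, s in enumerate(starts):
            chunk = labels[s : s + window]
            counts = np.bincount(chunk, minlength=n_labels + 1)[1 : n_labels + 1]
            comp[wi] = counts / counts.sum()
        per_mouse[mouse] = comp
    n_windows = min(len(c) for c in per_mouse.values())
    stack = np.stack([c[:n_windows] for c in per_mouse.values()])  # (mice, win, class)
    mean = stack.mean(axis=0)
    n_mice = stack.shape[0]
    boot_idx = rng.integers(0, n_mice, size=(n_boot, n_mice))
    boot_means = stack[boot_idx].mean(axis=1)  # (n_boot, win, class)
    lo = np.percentile(boot_means, 2.5, axis=0)
    hi = np.percentile(boot_means, 97.5, axis=0)
    times = (np.arange(n_windows) * step + window / 2.0) / fs
    for wi in range(n_windows):
        for ci in range(n_labels):
            rows.append(
                {
                    "time_s": times[wi],
                    "label": ci + 1,
                    "mean": mean[wi, ci],
                    "ci_lo": lo[wi, ci],
                    "ci_hi": hi[wi, ci],
                }
            )
    df = pd.DataFrame(rows)
    df.attrs["per_mouse"] = per_mouse
    return df


def _crossings_with_hysteresis(
    inside: np.ndarray, frame_rate: float, hysteresis_s: float
) -> tuple[int, int]:
    """Count sustained entries/exits of a zone.

    A state flip only registers after membership persists for the
    hysteresis time, which suppresses boundary jitter.
    """
    h = max(int(round(hysteresis_s * frame_rate)), 1)
    entries = exits = 0
    state = bool(inside[0])
    run_val, run_len = bool(inside[0]), 0
    for v in inside:
        v = bool(v)
        if v == run_val:
            run_len += 1
        else:
            run_val, run_len = v, 1
        if run_val != state and run_len >= h:
            if run_val:
                entries += 1
            else:
                exits += 1
            state = run_val
    return entries, exits


def spatial_occupancy(
    eth: Ethogram,
    zones: ZoneConfig,
    grid: int = 20,
    hysteresis_s: float = 0.5,
) -> dict:
    """Per-class occupancy maps plus corner time and center crossings."""
    xy = np.asarray(eth.arena_xy, dtype=float)
    a = zones.arena_side
    out_of_arena = np.any((xy < 0) | (xy > a), axis=1)
    if out_of_arena.any():
        logger.warning("clipping %d out-of-arena coordinates", out_of_arena.sum())
        xy = np.clip(xy, 0.0, a)
    maps: dict[int, np.ndarray] = {}
    for cls in np.unique(eth.coarse_labels):
        mask = eth.coarse_labels == cls
        hist, _, _ = np.histogram2d(
            xy[mask, 0], xy[mask, 1], bins=grid, range=[[0, a], [0, a]]
        )
        total = hist.sum()
        maps[int(cls)] = hist / total if total > 0 else hist
    corner = zones.in_corner(xy)
    center = zones.in_center(xy)
    entries, exits = _crossings_with_hysteresis(center, eth.frame_rate, hysteresis_s)
    edge = ~corner & (
        (xy[:, 0] <= zones.corner_side)
        | (xy[:, 0] >= a - zones.corner_side)
        | (xy[:, 1] <= zones.corner_side)
        | (xy[:, 1] >= a - zones.corner_side)
    )
    return {
        "occupancy_maps": maps,
        "corner_fraction": float(corner.mean()),
        "center_fraction": float(center.mean()),
        "edge_fraction": float(edge.mean()),
        "remainder_fraction": float((~corner & ~center & ~edge).mean()),
        "center_crossings": entries,
        "center_exits": exits,
    }


def episode_runs(labels: np.ndarray, min_len: int) -> list[tuple[object, int, int]]:
    """Maximal runs after absorbing sub-threshold blips.

    Runs shorter than ``min_len`` are merged into their longer neighbor
    (ties go to the preceding run), so single-frame labeling blips do not
    split an episode.  Returns ``(value, start, end)`` triples.
    """
    labels = np.asarray(labels)
    if len(labels) == 0:
        return []
    runs: list[list] = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            runs.append([labels[start], start, i])
            start = i
    changed = True
    while changed and len(runs) > 1:
        changed = False
        for ri, run in enumerate(runs):
            if run[2] - run[1] < min_len:
                left = runs[ri - 1] if ri > 0 else None
                right = runs[ri + 1] if ri < len(runs) - 1 else None
                if left is None and right is None:
                    continue
                if right is None or (
                    left is not None and (left[2] - left[1]) >= (right[2] - right[1])
                ):
                    target = left
                else:
                    target = right
                target_idx = runs.index(target)
                lo = min(run[1], target[1])
                hi = max(run[2], target[2])
                target[1], target[2] = lo, hi
                runs.pop(ri)
                # merge adjacent runs that now share a value
                merged = [runs[0]]
                for r in runs[1:]:
                    if r[0] == merged[-1][0] and r[1] == merged[-1][2]:
                        merged[-1][2] = r[2]
                    else:
                        merged.append(r)
                runs = merged
                changed = True
                break
    return [(r[0], r[1], r[2]) for r in runs]


GROOM_MODES = ["body", "face_paw", "small_quick", "foot_scratch", "mixture"]


def grooming_modes(
    eth: Ethogram,
    groom_submap: dict[int, str],
    groom_class: int = 2,
    min_bout_s: float = 0.25,
) -> pd.Series:
    """Episode counts per grooming mode, raw and normalized.

    An episode is a maximal run of one mode lasting at least
    ``min_bout_s`` (250 ms, i.e. 20 frames at 80 Hz); shorter blips are
    absorbed into the surrounding episode.  Mice with zero grooming yield
    a flagged all-NaN normalized row.
    """
    groom_frames = eth.coarse_labels == groom_class
    covered = set(groom_submap) >= set(np.unique(eth.fine_labels[groom_frames]))
    if not covered:
        raise ValueError("groom_submap does not cover all grooming fine clusters")
    counts = {m: 0 for m in GROOM_MODES}
    if groom_frames.any():
        min_len = max(int(round(min_bout_s * eth.frame_rate)), 1)
        modes = np.array(
            ["" if not g else groom_submap[f] for g, f in zip(groom_frames, eth.fine_labels)]
        )
        for value, start, end in episode_runs(modes, min_len):
            if value and end - start >= min_len:
                counts[value] = counts.get(value, 0) + 1
    raw = pd.Series(counts, dtype=float)
    total = raw.sum()
    if total == 0:
        logger.warning("mouse with zero grooming; normalized row undefined")
        norm = raw * np.nan
    else:
        norm = raw / total
    out = pd.concat([raw.add_prefix("n_"), norm.add_prefix("frac_")])
    out["total_episodes"] = total
    return out


def cohens_d(x: np.ndarray, y: np.ndarray) -> float:
    """Cohen's d with the pooled-SD denominator."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise ValueError("need at least two observations per group")
    pooled = float(
        np.sqrt(((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2))
    )
    if pooled == 0:
        return 0.0 if x.mean() == y.mean() else float("inf")
    return float((x.mean() - y.mean()) / pooled)


def habituation_summary(
    tables: pd.DataFrame,
    day_pair: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Across-day usage trends with effect sizes.

    ``tables`` is tidy with columns (mouse, day, label, fraction).
    Returns per-label per-day group medians plus Cohen's d between the
    requested day pair (default first vs last day).
    """
    required = {"mouse", "day", "label", "fraction"}
    if not required <= set(tables.columns):
        raise ValueError(f"tables must have columns {sorted(required)}")
    days = sorted(tables["day"].unique())
    if len(days) < 2:
        raise ValueError("need at least two days")
    if day_pair is None:
        day_pair = (days[0], days[-1])
    rows = []
    for label, sub in tables.groupby("label"):
        medians = sub.groupby("day")["fraction"].median()
        a = sub.loc[sub["day"] == day_pair[0]].sort_values("mouse")["fraction"].values
        b = sub.loc[sub["day"] == day_pair[1]].sort_values("mouse")["fraction"].values
        d = cohens_d(b, a) if len(a) >= 2 and len(b) >= 2 else np.nan
        row = {"label": label, "cohens_d": d}
        for day in days:
            row[f"median_day{day}"] = medians.get(day, np.nan)
        rows.append(row)
    return pd.DataFrame(rows).set_index("label")
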