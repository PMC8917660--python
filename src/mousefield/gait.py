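"""Stride segmentation, limb phase, and walk/trot gait analysis.

Locomotion bouts (maximal runs of the Locomotion class longer than
500 ms) are analyzed limb by limb: each paw's anterior-posterior
body-frame trajectory is up-sampled x100, z-scored within the bout, and
stride starts are detected as peaks of the posterior-ward excursion (the
paw's most retracted point, i.e. the start of the swing; peaks must be
at least 80 ms apart with prominence >= 0.2 after z-scoring).  Phase
interpolates linearly from 0 to 2*pi between consecutive stride starts.

At every front-right (FR) cycle start the phase of the other three limbs
is sampled together with centroid speed, angular velocity and arena
position, yielding one stride event per FR cycle.  Strides classify as
*trot* when both diagonal pairs are synchronous within pi/4, as *walk*
when the four phases match the sequential quarter-cycle footfall pattern
(FR, HL, FL, HR) within pi/4, and as unclassified otherwise.  The
walk-to-trot transition speed is the 0.5 crossing of a logistic fit of
P(trot | speed) over classified strides.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.signal import find_peaks

from .tracking import align_egocentric, _smooth
from .types import Ethogram, KeypointTimeSeries
from .synthetic import LIMB_MARKERS

__all__ = [
    "LocomotionBout",
    "GaitSummary",
    "circular_mean",
    "wrap_signed",
    "extract_bouts",
    "segment_strides",
    "assign_phase",
    "stride_events",
    "classify_stride",
    "gait_summary",
    "analyze_gait",
]

logger = logging.getLogger(__name__)

_TWO_PI = 2.0 * math.pi
LOCOMOTION_CLASS = 8

#: Ideal limb phases at FR cycle starts for the walking gait
#: (footfall order FR, HL, FL, HR at successive quarter cycles).
WALK_PATTERN = {
    "hind_left_paw": 1.5 * math.pi,
    "front_left_paw": math.pi,
    "hind_right_paw": 0.5 * math.pi,
}

GAIT_TOLERANCE_RAD = math.pi / 4.0


def wrap_signed(a: np.ndarray | float) -> np.ndarray | float:
    """Wrap angles to (-pi, pi]."""
    return -((-np.asarray(a) + math.pi) % _TWO_PI - math.pi)


def circular_mean(angles: np.ndarray, axis=None) -> np.ndarray | float:
    """Circular mean in [0, 2*pi)."""
    a = np.asarray(angles, dtype=float)
    mean = np.arctan2(np.sin(a).mean(axis=axis), np.cos(a).mean(axis=axis))
    return np.mod(mean, _TWO_PI)


def circular_distance(a, b) -> np.ndarray | float:
    return np.abs(wrap_signed(np.asarray(a) - np.asarray(b)))


@dataclass
class LocomotionBout:
    """One locomotion bout with body-frame limb trajectories."""

    trial_id: str
    start: int  # first frame (inclusive)
    end: int  # past-the-end frame
    frame_rate: float
    limb_ap: dict[str, np.ndarray]  # limb -> anterior-posterior trace
    speed: np.ndarray  # m/s per frame
    ang_vel: np.ndarray  # rad/s per frame
    arena_xy: np.ndarray  # (n, 2) meters
    tail_ap: np.ndarray | None = None

    @property
    def n_frames(self) -> int:
        return self.end - self.start

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.start, self.end) / self.frame_rate


@dataclass
class GaitSummary:
    """Speed-binned circular phase statistics and gait classification."""

    per_bin: pd.DataFrame
    stride_gaits: pd.Series
    transition_speed: float  # m/s; NaN when undefined
    pooled_diag_lag: float  # rad, circular mean over events
    speed_bins: np.ndarray
    n_events: int
    notes: dict = field(default_factory=dict)


def extract_bouts(
    eth: Ethogram,
    kp: KeypointTimeSeries,
    min_ms: float = 500.0,
    trial_id: str = "trial",
    locomotion_class: int = LOCOMOTION_CLASS,
) -> list[LocomotionBout]:
    """Maximal locomotion runs strictly longer than ``min_ms``.

    Paw (and tail) trajectories are rotated into the body frame (snout to
    tail-base axis) and projected on the anterior-posterior axis.
    """
    if eth.n_frames != kp.n_frames:
        raise ValueError("ethogram and keypoints differ in length")
    fs = kp.frame_rate
    aligned, heading = align_egocentric(kp)
    unwrapped = np.unwrap(heading)
    ang_vel = np.gradient(_smooth(unwrapped, 9)) * fs
    is_loc = np.asarray(eth.coarse_labels) == locomotion_class
    min_frames = min_ms / 1000.0 * fs  # strict: duration must exceed min_ms
    bouts: list[LocomotionBout] = []
    i = 0
    n = len(is_loc)
    while i < n:
        if not is_loc[i]:
            i += 1
            continue
        j = i
        while j < n and is_loc[j]:
            j += 1
        if (j - i) > min_frames:
            limb_ap = {
                limb: aligned.marker(limb)[i:j, 1].copy()
                for limb in LIMB_MARKERS
                if limb in kp.marker_names
            }
            tail_ap = None
            if "tail_tip" in kp.marker_names:
                tail_ap = aligned.marker("tail_tip")[i:j, 0].copy()
            bouts.append(
                LocomotionBout(
                    trial_id=trial_id,
                    start=i,
                    end=j,
                    frame_rate=fs,
                    limb_ap=limb_ap,
                    speed=np.asarray(eth.speed)[i:j].copy(),
                    ang_vel=ang_vel[i:j].copy(),
                    arena_xy=np.asarray(eth.arena_xy)[i:j].copy(),
                    tail_ap=tail_ap,
                )
            )
        i = j
    return bouts


def segment_strides(
    bout: LocomotionBout,
    upsample: int = 100,
    min_sep_ms: float = 80.0,
    min_prominence: float = 0.2,
    interpolation: str = "cubic",
) -> dict[str, np.ndarray]:
    """Per-limb stride (cycle-start) times within one bout.

    Each limb's anterior-posterior trace is interpolated ``upsample``-fold
    (cubic by default), z-scored within the bout, and stride starts are
    peaks of the *posterior-ward* excursion subject to the separation and
    prominence constraints.  Limbs with fewer than two detected strides
    are dropped (and logged).
    """
    fs = bout.frame_rate
    t = bout.times
    t_up = np.arange(t[0], t[-1] + 1e-12, 1.0 / (fs * upsample))
    min_distance = max(int(round(min_sep_ms / 1000.0 * fs * upsample)), 1)
    out: dict[str, np.ndarray] = {}
    for limb, trace in bout.limb_ap.items():
        if interpolation == "cubic":
            up = CubicSpline(t, trace)(t_up)
        else:
            up = np.interp(t_up, t, trace)
        sd = up.std()
        if sd == 0:
            logger.info("flat limb trace for %s; limb dropped", limb)
            continue
        z = (up - up.mean()) / sd
        peaks, _ = find_peaks(-z, distance=min_distance, prominence=min_prominence)
        if len(peaks) < 2:
            logger.info("limb %s has < 2 strides in bout; dropped", limb)
            continue
        out[limb] = t_up[peaks]
    return out


def assign_phase(cycle_starts: np.ndarray, query_times: np.ndarray) -> np.ndarray:
    """Phase at query times: linear 0 -> 2*pi between consecutive starts.

    Queries outside the first/last cycle return NaN.
    """
    starts = np.asarray(cycle_starts, dtype=float)
    if len(starts) < 2:
        raise ValueError("need at least two cycle starts")
    if np.any(np.diff(starts) <= 0):
        raise ValueError("cycle starts must be strictly increasing")
    q = np.asarray(query_times, dtype=float)
    unwrapped = np.interp(q, starts, np.arange(len(starts)) * _TWO_PI)
    phase = np.mod(unwrapped, _TWO_PI)
    phase[(q < starts[0]) | (q > starts[-1])] = np.nan
    return phase


def stride_events(
    bout: LocomotionBout,
    cycle_starts: dict[str, np.ndarray] | None = None,
    reference: str = "front_right_paw",
) -> pd.DataFrame:
    """One event per FR cycle start, with the other limbs' phases.

    Events are kept only where every limb's phase is defined (interior to
    all limbs' first/last cycles).  Speed, angular velocity and arena
    position are linearly interpolated at the event time.
    """
    if cycle_starts is None:
        cycle_starts = segment_strides(bout)
    if reference not in cycle_starts or len(cycle_starts[reference]) < 2:
        return pd.DataFrame()
    others = [m for m in LIMB_MARKERS if m != reference]
    if any(m not in cycle_starts for m in others):
        return pd.DataFrame()
    fr_starts = cycle_starts[reference]
    t = bout.times
    rows = {"time_s": fr_starts}
    for limb in others:
        rows[f"phase_{limb}"] = assign_phase(cycle_starts[limb], fr_starts)
    rows["speed"] = np.interp(fr_starts, t, bout.speed)
    rows["ang_vel"] = np.interp(fr_starts, t, bout.ang_vel)
    rows["arena_x"] = np.interp(fr_starts, t, bout.arena_xy[:, 0])
    rows["arena_y"] = np.interp(fr_starts, t, bout.arena_xy[:, 1])
    df = pd.DataFrame(rows)
    df["trial_id"] = bout.trial_id
    phase_cols = [f"phase_{m}" for m in others]
    df = df.dropna(subset=phase_cols).reset_index(drop=True)
    # diagonal-pair lag: FL/HR pair vs FR/HL pair, relative to antiphase
    pair_ref = circular_mean(
        np.column_stack([np.zeros(len(df)), df["phase_hind_left_paw"]]), axis=1
    )
    pair_other = circular_mean(
        np.column_stack([df["phase_front_left_paw"], df["phase_hind_right_paw"]]), axis=1
    )
    df["diag_lag"] = wrap_signed(pair_other - pair_ref - math.pi)
    return df


def classify_stride(
    phase_hl: float, phase_fl: float, phase_hr: float, tol: float = GAIT_TOLERANCE_RAD
) -> str:
    """Label one stride as trot, walk, or unclassified."""
    trot = (
        circular_distance(phase_fl, phase_hr) <= tol
        and circular_distance(phase_hl, 0.0) <= tol
    )
    walk = (
        circular_distance(phase_hl, WALK_PATTERN["hind_left_paw"]) <= tol
        and circular_distance(phase_fl, WALK_PATTERN["front_left_paw"]) <= tol
        and circular_distance(phase_hr, WALK_PATTERN["hind_right_paw"]) <= tol
    )
    if trot and not walk:
        return "trot"
    if walk and not trot:
        return "walk"
    if trot and walk:
        return "trot"
    return "unclassified"


def _transition_speed(speeds: np.ndarray, is_trot: np.ndarray) -> float:
    """0.5 crossing of a logistic fit of P(trot | speed)."""
    from sklearn.linear_model import LogisticRegression

    if len(speeds) < 10 or is_trot.all() or (~is_trot).all():
        return float("nan")
    lr = LogisticRegression(C=100.0)
    lr.fit(speeds[:, None], is_trot.astype(int))
    coef = float(lr.coef_[0, 0])
    if coef <= 0:
        return float("nan")
    return float(-lr.intercept_[0] / coef)


def gait_summary(
    events: pd.DataFrame,
    speed_bins: np.ndarray | None = None,
) -> GaitSummary:
    """Speed-binned circular phase statistics plus gait classification."""
    if len(events) == 0:
        raise ValueError("no stride events")
    if speed_bins is None:
        speed_bins = np.arange(0.0, 0.45 + 1e-9, 0.05)
    speed_bins = np.asarray(speed_bins, dtype=float)
    gaits = events.apply(
        lambda r: classify_stride(
            r["phase_hind_left_paw"], r["phase_front_left_paw"], r["phase_hind_right_paw"]
        ),
        axis=1,
    )
    bin_idx = np.clip(
        np.digitize(events["speed"], speed_bins) - 1, 0, len(speed_bins) - 2
    )
    rows = []
    for b in range(len(speed_bins) - 1):
        mask = bin_idx == b
        row = {
            "speed_lo": speed_bins[b],
            "speed_hi": speed_bins[b + 1],
            "count": int(mask.sum()),
        }
        if mask.any():
            sub = events[mask]
            for limb in ("hind_left_paw", "front_left_paw", "hind_right_paw"):
                ph = sub[f"phase_{limb}"].values
                row[f"phase_mean_{limb}"] = circular_mean(ph)
                row[f"phase_R_{limb}"] = float(
                    np.hypot(np.sin(ph).mean(), np.cos(ph).mean())
                )
            # per-pair lags relative to antiphase, and pooled
            lag_fl = wrap_signed(sub["phase_front_left_paw"].values - math.pi)
            lag_hr = wrap_signed(sub["phase_hind_right_paw"].values - math.pi)
            row["diag_lag_fl"] = float(np.mod(circular_mean(lag_fl), _TWO_PI))
            row["diag_lag_hr"] = float(np.mod(circular_mean(lag_hr), _TWO_PI))
            row["diag_lag"] = float(circular_mean(sub["diag_lag"].values))
            row["frac_trot"] = float((gaits[mask] == "trot").mean())
            row["frac_walk"] = float((gaits[mask] == "walk").mean())
        rows.append(row)
    classified = gaits.isin(["walk", "trot"])
    transition = _transition_speed(
        events.loc[classified, "speed"].values, (gaits[classified] == "trot").values
    )
    pooled = float(circular_mean(events["diag_lag"].values))
    return GaitSummary(
        per_bin=pd.DataFrame(rows),
        stride_gaits=gaits,
        transition_speed=transition,
        pooled_diag_lag=pooled,
        speed_bins=speed_bins,
        n_events=len(events),
        notes={"n_classified": int(classified.sum())},
    )


def analyze_gait(
    eth: Ethogram,
    kp: KeypointTimeSeries,
    min_ms: float = 500.0,
    trial_id: str = "trial",
    speed_bins: np.ndarray | None = None,
) -> tuple[pd.DataFrame, GaitSummary | None]:
    """Full bout -> stride -> phase -> summary pipeline for one trial."""
    bouts = extract_bouts(eth, kp, min_ms=min_ms, trial_id=trial_id)
    frames = [stride_events(b) for b in bouts]
    frames = [f for f in frames if len(f)]
    if not frames:
        return pd.DataFrame(), None
    events = pd.concat(frames, ignore_index=True)
    return events, gait_summary(events, speed_bins=speed_bins)
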