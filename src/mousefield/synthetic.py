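"""Synthetic open-field trials with known behavioral and gait ground truth.

The generator emulates 20-min, 80 Hz open-field recordings of a single
mouse imaged from below: per-frame 2-D positions of named body markers,
a centroid trajectory inside a square arena, a per-frame behavioral state
label drawn from the eight-class open-field vocabulary (idle, groom, slow
and fast exploration, rear, climb, amble/turn, locomotion), and — inside
locomotion segments — per-limb gait cycles with programmable stride
frequency, speed, and inter-limb phase structure.

Gait phase convention
---------------------
Phase ``theta = 0`` marks the start of a limb's swing, i.e. the frame at
which the paw reaches its posterior-most position along the body's
anterior-posterior axis.  Limb phases are specified *at front-right (FR)
cycle starts*: a limb generated with phase ``phi`` is at phase ``phi`` of
its own cycle whenever FR is at phase 0.

Two canonical quadruped gaits are built in:

* ``walk`` — footfall order FR, HL, FL, HR at successive quarter cycles,
  giving phases (FR 0, HL 3pi/2, FL pi, HR pi/2) at FR cycle starts.
* ``trot`` — diagonal pairs move together: FR/HL at phase 0 and FL/HR at
  ``pi + diag_offset_rad``.  ``diag_offset_rad`` is the circular lag of
  the FL/HR pair relative to perfect antiphase with the FR/HL pair; it is
  the quantity the stride/phase pipeline re-estimates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .types import KeypointTimeSeries

__all__ = [
    "COARSE_CLASS_NAMES",
    "STATE_TO_CLASS",
    "DEFAULT_MARKERS",
    "LIMB_MARKERS",
    "GaitParams",
    "GroomParams",
    "SyntheticTrialSpec",
    "SyntheticTrial",
    "generate_trial",
    "render_video",
    "states_from_dwell_model",
    "walk_phases",
    "trot_phases",
]

#: Eight coarse behavioral classes of the open-field vocabulary, 1-based.
COARSE_CLASS_NAMES = {
    1: "Idle",
    2: "Groom",
    3: "Slow Explore",
    4: "Fast Explore",
    5: "Rear",
    6: "Climb",
    7: "Amble and Turn",
    8: "Locomotion",
}

#: Generator state label -> coarse class id.
STATE_TO_CLASS = {
    "idle": 1,
    "groom": 2,
    "slow_explore": 3,
    "fast_explore": 4,
    "rear": 5,
    "climb": 6,
    "amble_turn": 7,
    "locomotion": 8,
}

#: Default marker set: snout, chin, four inner paws, four outer paw points,
#: tail base and tail tip.  The posture stage drops tail_tip by default,
#: leaving an 11-marker high-confidence subset.
DEFAULT_MARKERS = [
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
    "tail_tip",
]

#: The four limbs used by the gait stage, in FR, HL, FL, HR order.
LIMB_MARKERS = [
    "front_right_paw",
    "hind_left_paw",
    "front_left_paw",
    "hind_right_paw",
]

# Resting body-frame marker layout (meters; +y anterior, tail base origin).
_BODY_LAYOUT = {
    "snout": (0.0, 0.080),
    "chin": (0.0, 0.065),
    "front_left_paw": (-0.015, 0.050),
    "front_right_paw": (0.015, 0.050),
    "hind_left_paw": (-0.013, 0.012),
    "hind_right_paw": (0.013, 0.012),
    "front_left_outer": (-0.022, 0.050),
    "front_right_outer": (0.022, 0.050),
    "hind_left_outer": (-0.020, 0.012),
    "hind_right_outer": (0.020, 0.012),
    "tail_base": (0.0, 0.0),
    "tail_tip": (0.0, -0.045),
}

#: Anterior-posterior stride amplitude of a paw in the body frame (m).
STRIDE_AMPLITUDE_M = 0.010

_TWO_PI = 2.0 * math.pi


def walk_phases() -> dict[str, float]:
    """Limb phases at FR cycle starts for the walking gait.

    Footfall order FR, HL, FL, HR at successive quarter cycles: a limb that
    will start its own cycle a quarter period after FR is three quarters of
    the way through its current cycle when FR starts.
    """
    return {
        "front_right_paw": 0.0,
        "hind_left_paw": 1.5 * math.pi,
        "front_left_paw": math.pi,
        "hind_right_paw": 0.5 * math.pi,
    }


def trot_phases(diag_offset_rad: float) -> dict[str, float]:
    """Limb phases at FR cycle starts for a trot with diagonal-pair lag."""
    lag = (math.pi + diag_offset_rad) % _TWO_PI
    return {
        "front_right_paw": 0.0,
        "hind_left_paw": 0.0,
        "front_left_paw": lag,
        "hind_right_paw": lag,
    }


@dataclass
class GaitParams:
    """Kinematics of one locomotion bout."""

    speed: float = 0.2  # m/s
    gait: str = "trot"  # "walk" | "trot"
    diag_offset_rad: float = 0.5  # trot diagonal-pair lag, rad
    stride_freq_hz: float = 4.0
    turn_radius_m: float = 0.15

    def limb_phases(self) -> dict[str, float]:
        if self.gait == "walk":
            return walk_phases()
        if self.gait == "trot":
            return trot_phases(self.diag_offset_rad)
        raise ValueError(f"unknown gait {self.gait!r}")


@dataclass
class GroomParams:
    """Oscillation parameters of one grooming mode."""

    mode: str = "face_paw"
    freq_hz: float = 5.5
    amplitude_m: float = 0.004


#: Default oscillation frequency (Hz) per grooming mode.
GROOM_MODE_FREQS = {
    "body": 3.0,
    "face_paw": 5.5,
    "small_quick": 8.0,
    "foot_scratch": 10.0,
    "mixture": 4.5,
}


@dataclass
class SyntheticTrialSpec:
    """Full description of one synthetic open-field trial.

    ``state_sequence`` lists ``(state, start_frame, end_frame)`` segments
    that must tile ``[0, n_frames)``; if omitted, a memoryless dwell model
    is sampled (see :func:`states_from_dwell_model`).  Successive
    locomotion segments take successive entries of ``gait_params``
    (cycled); grooming segments take successive ``groom_params``.
    """

    duration_s: float = 60.0
    frame_rate: float = 80.0
    arena_side: float = 0.457
    pixels_per_meter: float = 2188.2
    marker_names: list[str] = field(default_factory=lambda: list(DEFAULT_MARKERS))
    state_sequence: list[tuple[str, int, int]] | None = None
    state_probs: dict[str, float] | None = None
    mean_dwell_s: float = 2.0
    gait_params: GaitParams | list[GaitParams] = field(default_factory=GaitParams)
    groom_params: GroomParams | list[GroomParams] = field(default_factory=GroomParams)
    noise_sd_px: float = 0.5
    seed: int = 0

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.frame_rate))

    def gait_list(self) -> list[GaitParams]:
        g = self.gait_params
        return list(g) if isinstance(g, (list, tuple)) else [g]

    def groom_list(self) -> list[GroomParams]:
        g = self.groom_params
        return list(g) if isinstance(g, (list, tuple)) else [g]

    def validate(self) -> None:
        if self.duration_s <= 0 or self.frame_rate <= 0:
            raise ValueError("duration_s and frame_rate must be positive")
        for g in self.gait_list():
            if g.speed < 0:
                raise ValueError("gait speed must be >= 0")
            if not 0.0 <= g.diag_offset_rad < _TWO_PI:
                raise ValueError("diag_offset_rad must lie in [0, 2*pi)")
            if g.stride_freq_hz >= self.frame_rate / 2.0:
                raise ValueError(
                    f"stride frequency {g.stride_freq_hz} Hz exceeds the "
                    f"Nyquist limit at {self.frame_rate} Hz sampling"
                )
            if g.gait not in ("walk", "trot"):
                raise ValueError(f"unknown gait {g.gait!r}")
        if self.state_sequence is not None:
            seq = sorted(self.state_sequence, key=lambda s: s[1])
            cursor = 0
            for state, start, end in seq:
                if state not in STATE_TO_CLASS:
                    raise ValueError(f"unknown state label {state!r}")
                if start != cursor or end <= start:
                    raise ValueError(
                        "state segments must tile [0, n_frames) without overlap"
                    )
                cursor = end
            if cursor != self.n_frames:
                raise ValueError("state segments must cover exactly n_frames")


@dataclass
class SyntheticTrial:
    """A generated trial plus every piece of ground truth the tests need."""

    keypoints: KeypointTimeSeries
    centroid_truth: np.ndarray  # (n_frames, 2) arena meters
    heading_truth: np.ndarray  # (n_frames,) rad
    state_truth: np.ndarray  # (n_frames,) unicode state labels
    stride_truth: dict[str, np.ndarray]  # limb -> cycle-start times (s)
    limb_phase_truth: np.ndarray  # (n_frames, 4) rad, NaN outside locomotion
    segment_gaits: list[tuple[int, int, GaitParams]]
    spec: SyntheticTrialSpec

    @property
    def n_frames(self) -> int:
        return len(self.state_truth)

    def coarse_truth(self) -> np.ndarray:
        """Ground-truth coarse class ids (1..8) per frame."""
        return np.array([STATE_TO_CLASS[s] for s in self.state_truth])


def states_from_dwell_model(
    n_frames: int,
    frame_rate: float,
    state_probs: dict[str, float],
    mean_dwell_s: float,
    rng: np.random.Generator,
) -> list[tuple[str, int, int]]:
    """Sample a state sequence with geometric dwell times.

    States are drawn independently with the given probabilities (the
    simplest memoryless ethogram null), so expected frame occupancy per
    state matches ``state_probs``; consecutive draws of the same state
    merge into one longer segment.
    """
    states = list(state_probs)
    probs = np.array([state_probs[s] for s in states], dtype=float)
    probs = probs / probs.sum()
    mean_dwell_frames = max(mean_dwell_s * frame_rate, 1.0)
    p_exit = 1.0 / mean_dwell_frames
    seq: list[tuple[str, int, int]] = []
    cursor = 0
    while cursor < n_frames:
        state = states[rng.choice(len(states), p=probs)]
        dwell = int(rng.geometric(p_exit))
        end = min(cursor + max(dwell, 1), n_frames)
        if seq and seq[-1][0] == state:
            seq[-1] = (state, seq[-1][1], end)
        else:
            seq.append((state, cursor, end))
        cursor = end
    return seq


def _advance_path(
    n: int,
    dt: float,
    pos0: np.ndarray,
    heading0: float,
    speed: float,
    turn_rate: float,
    heading_jitter_sd: float,
    arena_side: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate a constant-speed path with wall-avoiding steering."""
    margin = 0.06
    center = np.array([arena_side / 2.0, arena_side / 2.0])
    pos = np.empty((n, 2))
    heading = np.empty(n)
    p = pos0.astype(float).copy()
    h = float(heading0)
    for i in range(n):
        h = h + turn_rate * dt
        if heading_jitter_sd > 0:
            h += rng.normal(0.0, heading_jitter_sd) * math.sqrt(dt)
        step = np.array([math.cos(h), math.sin(h)]) * speed * dt
        nxt = p + step
        if np.any(nxt < margin) or np.any(nxt > arena_side - margin):
            # steer toward the arena center; keeps speed constant
            h = math.atan2(center[1] - p[1], center[0] - p[0])
            nxt = p + np.array([math.cos(h), math.sin(h)]) * speed * dt
        p = nxt
        pos[i] = p
        heading[i] = h
    return pos, heading


def generate_trial(spec: SyntheticTrialSpec) -> SyntheticTrial:
    """Generate one synthetic trial; bit-deterministic given ``spec.seed``."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_frames
    fs = spec.frame_rate
    dt = 1.0 / fs
    markers = list(spec.marker_names)
    m_idx = {name: i for i, name in enumerate(markers)}
    n_markers = len(markers)

    if spec.state_sequence is not None:
        segments = sorted(spec.state_sequence, key=lambda s: s[1])
    else:
        probs = spec.state_probs or {
            "idle": 0.15,
            "groom": 0.10,
            "slow_explore": 0.15,
            "fast_explore": 0.12,
            "rear": 0.08,
            "climb": 0.08,
            "amble_turn": 0.12,
            "locomotion": 0.20,
        }
        segments = states_from_dwell_model(n, fs, probs, spec.mean_dwell_s, rng)

    t = np.arange(n) * dt
    state_truth = np.empty(n, dtype="U16")
    body = np.empty((n, n_markers, 2))
    base = np.array([_BODY_LAYOUT.get(m, (0.0, 0.0)) for m in markers])
    body[:] = base[None, :, :]
    centroid = np.empty((n, 2))
    heading = np.empty(n)
    limb_phase = np.full((n, len(LIMB_MARKERS)), np.nan)
    stride_truth: dict[str, list[float]] = {m: [] for m in LIMB_MARKERS}
    segment_gaits: list[tuple[int, int, GaitParams]] = []

    pos = np.array([spec.arena_side / 2.0, spec.arena_side / 2.0])
    head = float(rng.uniform(0.0, _TWO_PI))
    gaits = spec.gait_list()
    grooms = spec.groom_list()
    i_gait = 0
    i_groom = 0

    for state, start, end in segments:
        sl = slice(start, end)
        ns = end - start
        ts = t[sl] - t[start]
        state_truth[sl] = state

        if state == "locomotion":
            gp = gaits[i_gait % len(gaits)]
            i_gait += 1
            segment_gaits.append((start, end, gp))
            turn = gp.speed / gp.turn_radius_m * (1 if rng.random() < 0.5 else -1)
            centroid[sl], heading[sl] = _advance_path(
                ns, dt, pos, head, gp.speed, turn, 0.0, spec.arena_side, rng
            )
            phases = gp.limb_phases()
            f = gp.stride_freq_hz
            for k, limb in enumerate(LIMB_MARKERS):
                phi = phases[limb]
                theta = (_TWO_PI * f * ts + phi) % _TWO_PI
                limb_phase[sl, k] = theta
                if limb in m_idx:
                    body[sl, m_idx[limb], 1] += STRIDE_AMPLITUDE_M * (-np.cos(theta))
                # cycle starts: theta == 0 within the segment
                first = ((-phi) % _TWO_PI) / (_TWO_PI * f)
                starts = t[start] + np.arange(first, ts[-1] + dt, 1.0 / f)
                stride_truth[limb].extend(starts[starts <= t[end - 1] + 1e-12])
            if "tail_tip" in m_idx:
                theta_fr = (_TWO_PI * f * ts) % _TWO_PI
                body[sl, m_idx["tail_tip"], 0] += 0.008 * np.sin(theta_fr)
        elif state in ("slow_explore", "fast_explore"):
            speed = 0.02 if state == "slow_explore" else 0.05
            jit = 0.6 if state == "slow_explore" else 1.5
            centroid[sl], heading[sl] = _advance_path(
                ns, dt, pos, head, speed, 0.0, jit, spec.arena_side, rng
            )
            f_head = 0.7 if state == "slow_explore" else 5.0
            amp = 0.010 if state == "slow_explore" else 0.008
            sweep = amp * np.sin(_TWO_PI * f_head * ts)
            for mk in ("snout", "chin"):
                if mk in m_idx:
                    body[sl, m_idx[mk], 0] += sweep
        elif state == "amble_turn":
            turn = 0.8 * (1 if rng.random() < 0.5 else -1)
            centroid[sl], heading[sl] = _advance_path(
                ns, dt, pos, head, 0.07, turn, 0.3, spec.arena_side, rng
            )
            # irregular steps: stride-like oscillation with wandering phase
            jitter = np.cumsum(rng.normal(0.0, 0.25, ns))
            for k, limb in enumerate(LIMB_MARKERS):
                if limb in m_idx:
                    theta = _TWO_PI * 1.5 * ts + jitter + k * math.pi / 2.0
                    body[sl, m_idx[limb], 1] += 0.006 * (-np.cos(theta))
        else:
            centroid[sl] = pos
            heading[sl] = head
            if state == "groom":
                gr = grooms[i_groom % len(grooms)]
                i_groom += 1
                freq = gr.freq_hz or GROOM_MODE_FREQS.get(gr.mode, 5.5)
                osc = gr.amplitude_m * np.sin(_TWO_PI * freq * ts)
                if gr.mode == "foot_scratch":
                    parts = ("hind_left_paw", "hind_right_paw")
                elif gr.mode == "body":
                    parts = ("front_left_paw", "front_right_paw", "chin", "snout")
                else:
                    parts = ("front_left_paw", "front_right_paw", "chin")
                for mk in parts:
                    if mk in m_idx:
                        body[sl, m_idx[mk], 1] += osc
            elif state in ("rear", "climb"):
                # body-length contraction with elevated nose dynamics
                contraction = 0.30 * (1.0 - np.cos(_TWO_PI * 0.5 * ts)) / 2.0
                for mk in ("snout", "chin"):
                    if mk in m_idx:
                        body[sl, m_idx[mk], 1] *= 1.0 - contraction
                if "snout" in m_idx:
                    body[sl, m_idx["snout"], 0] += 0.006 * np.sin(_TWO_PI * 2.0 * ts)
                if state == "climb":
                    for k, limb in enumerate(LIMB_MARKERS):
                        if limb in m_idx:
                            theta = _TWO_PI * 6.0 * ts + k * math.pi / 2.0
                            body[sl, m_idx[limb], 1] += 0.005 * np.sin(theta)
        pos = centroid[end - 1].copy()
        head = float(heading[end - 1])

    # project body frame into the arena frame: +y (anterior) -> heading
    alpha = heading - math.pi / 2.0
    ca, sa = np.cos(alpha), np.sin(alpha)
    x_b, y_b = body[..., 0], body[..., 1]
    arena_xy = np.empty_like(body)
    arena_xy[..., 0] = centroid[:, None, 0] + ca[:, None] * x_b - sa[:, None] * y_b
    arena_xy[..., 1] = centroid[:, None, 1] + sa[:, None] * x_b + ca[:, None] * y_b

    positions_px = arena_xy * spec.pixels_per_meter
    if spec.noise_sd_px > 0:
        positions_px = positions_px + rng.normal(0.0, spec.noise_sd_px, positions_px.shape)

    kp = KeypointTimeSeries(
        positions=positions_px,
        marker_names=markers,
        frame_rate=fs,
        unit="px",
        pixels_per_meter=spec.pixels_per_meter,
    )
    return SyntheticTrial(
        keypoints=kp,
        centroid_truth=centroid,
        heading_truth=heading,
        state_truth=state_truth,
        stride_truth={m: np.array(v) for m, v in stride_truth.items()},
        limb_phase_truth=limb_phase,
        segment_gaits=segment_gaits,
        spec=spec,
    )


def truth_ethogram(trial: SyntheticTrial) -> "Ethogram":
    """Ethogram built from generator ground truth.

    Uses the true state labels as both fine and coarse labels, with speed
    estimated from the true centroid; lets the gait and metrics stages run
    without the clustering stage.
    """
    from .tracking import centroid_kinematics
    from .types import Ethogram

    fs = trial.keypoints.frame_rate
    speed, _ = centroid_kinematics(trial.centroid_truth, fs)
    coarse = trial.coarse_truth()
    return Ethogram(
        fine_labels=coarse,
        coarse_labels=coarse,
        speed=speed,
        arena_xy=trial.centroid_truth,
        frame_rate=fs,
        class_names=dict(COARSE_CLASS_NAMES),
    )


def render_video(
    trial: SyntheticTrial,
    spec: SyntheticTrialSpec,
    frame_shape: tuple[int, int] | None = None,
    blob_peak: float = 150.0,
    video_noise_sd: float = 2.0,
    background_seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Render a grayscale image stack with a bright mouse-like blob.

    The blob is an anisotropic Gaussian elongated along the nose-tail axis
    placed at the true centroid over a static textured background with
    additive pixel noise.  Returns ``(stack, centroid_px_truth)`` where
    ``stack`` is ``uint8`` of shape ``(n_frames, h, w)``.
    """
    ppm = spec.pixels_per_meter
    if frame_shape is None:
        side = int(math.ceil(spec.arena_side * ppm))
        frame_shape = (side, side)
    h, w = frame_shape
    rng = np.random.default_rng(spec.seed if background_seed is None else background_seed)

    centroid_px = trial.centroid_truth * ppm
    sig_long = max(0.022 * ppm, 2.0)
    sig_short = max(0.011 * ppm, 1.0)
    pad = 2.0 * sig_short
    if np.any(centroid_px < pad) or np.any(centroid_px[:, 0] > w - pad) or np.any(
        centroid_px[:, 1] > h - pad
    ):
        raise ValueError("blob would leave the frame; enlarge frame_shape")

    background = gaussian_filter(rng.uniform(30.0, 70.0, (h, w)), sigma=4.0)
    yy, xx = np.mgrid[0:h, 0:w]
    stack = np.empty((trial.n_frames, h, w), dtype=np.uint8)
    for i in range(trial.n_frames):
        cx, cy = centroid_px[i]
        hd = trial.heading_truth[i]
        c, s = math.cos(hd), math.sin(hd)
        u = c * (xx - cx) + s * (yy - cy)  # along-body coordinate
        v = -s * (xx - cx) + c * (yy - cy)
        blob = blob_peak * np.exp(-0.5 * ((u / sig_long) ** 2 + (v / sig_short) ** 2))
        frame = background + blob
        if video_noise_sd > 0:
            frame = frame + rng.normal(0.0, video_noise_sd, frame.shape)
        stack[i] = np.clip(frame, 0.0, 255.0).astype(np.uint8)
    return stack, centroid_px
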