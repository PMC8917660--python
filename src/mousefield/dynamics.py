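"""Time-frequency representation of posture dynamics.

Each postural-mode (or body-part coordinate) channel is decomposed with a
continuous Morlet wavelet transform over a dyadically spaced grid of
frequencies (default 25 channels from 0.25 to 20 Hz).  Amplitudes are
normalized so that a unit-amplitude sinusoid at a channel frequency
yields a peak response of ~1; the spectrogram stores log10 power with a
floor at -3.  The transform is computed by frequency-domain convolution
with reflective edge padding, which avoids spurious boundary power.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .types import KeypointTimeSeries

__all__ = [
    "FrequencyGrid",
    "WaveletSpectrogram",
    "Fingerprint",
    "dyadic_frequencies",
    "wavelet_transform",
    "fingerprint",
]

logger = logging.getLogger(__name__)

OMEGA0_DEFAULT = 5.0  # Morlet nondimensional frequency
LOG_FLOOR = -3.0


@dataclass
class FrequencyGrid:
    """Dyadically spaced analysis frequencies (Hz, ascending)."""

    freqs: np.ndarray

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("frequencies must be strictly ascending")

    @property
    def n_freqs(self) -> int:
        return len(self.freqs)


@dataclass
class WaveletSpectrogram:
    """Per-frame log10 wavelet power over (channels x frequencies).

    ``power`` columns are channel-major: the block of ``n_freqs`` columns
    for channel 0 comes first, then channel 1, and so on.
    """

    power: np.ndarray  # (n_frames, n_channels * n_freqs)
    channel_names: list[str]
    grid: FrequencyGrid
    frame_rate: float
    floor: float = LOG_FLOOR

    @property
    def n_frames(self) -> int:
        return self.power.shape[0]

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    def channel_block(self, channel: int) -> np.ndarray:
        f = self.grid.n_freqs
        return self.power[:, channel * f : (channel + 1) * f]


@dataclass
class Fingerprint:
    """Mean log-power spectrum per body-part channel for one class."""

    class_label: int
    mean_power: np.ndarray  # (n_channels, n_freqs)
    channel_names: list[str]
    grid: FrequencyGrid
    n_frames: int


def dyadic_frequencies(
    f_min: float = 0.25,
    f_max: float = 20.0,
    n: int = 25,
    frame_rate: float | None = None,
) -> FrequencyGrid:
    """Geometric (dyadic) frequency grid with exact endpoints."""
    if not 0 < f_min < f_max:
        raise ValueError("need 0 < f_min < f_max")
    if n < 2:
        raise ValueError("need at least two frequencies")
    if frame_rate is not None and f_max > frame_rate / 2.0:
        raise ValueError(
            f"f_max={f_max} Hz exceeds the Nyquist frequency at {frame_rate} Hz"
        )
    exponents = np.linspace(0.0, math.log2(f_max / f_min), n)
    freqs = f_min * np.exp2(exponents)
    freqs[0], freqs[-1] = f_min, f_max  # endpoints exact
    return FrequencyGrid(freqs=freqs)


def _morlet_scale(freq_hz: float, omega0: float) -> float:
    """Scale mapping a Morlet wavelet's peak response to ``freq_hz``."""
    return (omega0 + math.sqrt(2.0 + omega0 ** 2)) / (4.0 * math.pi * freq_hz)


def wavelet_transform(
    signal: np.ndarray,
    grid: FrequencyGrid,
    frame_rate: float,
    omega0: float = OMEGA0_DEFAULT,
    channel_names: list[str] | None = None,
    floor: float = LOG_FLOOR,
) -> WaveletSpectrogram:
    """Morlet wavelet spectrogram of a multi-channel signal.

    Parameters
    ----------
    signal : ndarray, shape (n_frames,) or (n_frames, n_channels)
        Input time series (postural-mode projections or aligned body-part
        coordinates).
    grid : FrequencyGrid
        Analysis frequencies; must respect the Nyquist limit.
    frame_rate : float
        Sampling rate in Hz.
    omega0 : float
        Morlet nondimensional frequency (width/frequency trade-off).
    floor : float
        Lower clamp applied to log10 power.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if np.isnan(x).any():
        raise ValueError("NaN input; preprocess before the wavelet transform")
    n, n_ch = x.shape
    if grid.freqs[-1] > frame_rate / 2.0:
        raise ValueError("grid exceeds the Nyquist frequency")
    s_max = _morlet_scale(grid.freqs[0], omega0)
    support = int(math.ceil(2.0 * s_max * frame_rate))
    if n <= support:
        raise ValueError(
            f"{n} frames is shorter than the wavelet support (~{support} frames) "
            f"at f_min={grid.freqs[0]} Hz"
        )
    pad = min(n - 1, 2 * support)
    xp = np.pad(x, ((pad, pad), (0, 0)), mode="reflect")
    m = xp.shape[0]
    fft = np.fft.fft(xp, axis=0)
    ang = 2.0 * math.pi * np.fft.fftfreq(m, d=1.0 / frame_rate)  # rad/s

    # amplitude of the analytic Morlet response to a unit cosine at the
    # channel frequency: 1/2 * pi^{-1/4} * exp(-((s*2*pi*f - omega0)^2)/2);
    # s*2*pi*f at the matched frequency is the same for every channel.
    matched = (omega0 + math.sqrt(2.0 + omega0 ** 2)) / 2.0
    unit_response = 0.5 * math.pi ** -0.25 * math.exp(-0.5 * (matched - omega0) ** 2)

    n_freqs = grid.n_freqs
    power = np.empty((n, n_ch * n_freqs))
    for fi, f in enumerate(grid.freqs):
        s = _morlet_scale(f, omega0)
        psi_hat = np.where(
            ang > 0, math.pi ** -0.25 * np.exp(-0.5 * (s * ang - omega0) ** 2), 0.0
        )
        w = np.fft.ifft(fft * psi_hat[:, None], axis=0)[pad : pad + n]
        amp = np.abs(w) / unit_response
        # column c*n_freqs + fi <- channel c at frequency fi (channel-major)
        power[:, fi::n_freqs] = amp ** 2
    with np.errstate(divide="ignore"):
        logp = np.log10(power)
    logp = np.maximum(logp, floor)
    if channel_names is None:
        channel_names = [f"ch{c}" for c in range(n_ch)]
    return WaveletSpectrogram(
        power=logp,
        channel_names=list(channel_names),
        grid=grid,
        frame_rate=frame_rate,
        floor=floor,
    )


def fingerprint(
    bodyparts: KeypointTimeSeries | np.ndarray,
    labels: np.ndarray,
    grid: FrequencyGrid,
    frame_rate: float | None = None,
    channel_names: list[str] | None = None,
    omega0: float = OMEGA0_DEFAULT,
) -> list[Fingerprint]:
    """Per-class mean wavelet spectrum over body-part channels.

    The wavelet decomposition is recomputed on raw egocentric body-part
    coordinates (x and y of each marker as separate channels) instead of
    postural modes, which makes the per-class mean spectra directly
    interpretable: a 4 Hz peak in a limb channel means that limb
    oscillates at 4 Hz during that behavior.  Classes with zero frames
    are omitted (and logged).
    """
    if isinstance(bodyparts, KeypointTimeSeries):
        n = bodyparts.n_frames
        sig = bodyparts.positions.reshape(n, -1)
        channel_names = [
            f"{m}_{ax}" for m in bodyparts.marker_names for ax in ("x", "y")
        ]
        frame_rate = bodyparts.frame_rate
    else:
        sig = np.asarray(bodyparts, dtype=float)
        if frame_rate is None:
            raise ValueError("frame_rate required for array input")
    labels = np.asarray(labels)
    if len(labels) != sig.shape[0]:
        raise ValueError("labels length must equal n_frames")
    spec = wavelet_transform(
        sig, grid, frame_rate, omega0=omega0, channel_names=channel_names
    )
    n_ch, n_freqs = spec.n_channels, grid.n_freqs
    out: list[Fingerprint] = []
    for lab in np.unique(labels):
        mask = labels == lab
        if not mask.any():
            continue
        mean = spec.power[mask].mean(axis=0).reshape(n_ch, n_freqs)
        out.append(
            Fingerprint(
                class_label=int(lab) if np.issubdtype(labels.dtype, np.integer) else lab,
                mean_power=mean,
                channel_names=spec.channel_names,
                grid=grid,
                n_frames=int(mask.sum()),
            )
        )
    return out
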