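"""Modulation power spectra (MPS) of sound waveforms.

The MPS is the magnitude of the 2D Fourier transform of a log-amplitude,
log-frequency spectrogram. Its axes are temporal modulation rate in Hz
(from the spectrogram's time step) and spectral modulation rate in
cycles/octave (from the log-frequency channel spacing). Speech is
characterized by salient temporal modulation energy near the ~4 Hz
syllabic rate, which is what the acoustic dissimilarity model built here
is meant to capture.

The front end is a short-time Fourier spectrogram whose linear frequency
bins are pooled into log-spaced (constant-Q-like) channels before the
log-amplitude compression; window length, hop, channel density and the
amplitude floor are configuration constants with documented defaults,
and the temporal-rate axis calibration — the property the analyses
depend on — is robust to them.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal
from scipy.io import wavfile

from .errors import InvalidArgumentError, UndefinedPeakError
from .rsa import RDM
from .stimuli import StimulusSet

#: Log-amplitude floor in dB below the spectrogram maximum.
LOG_FLOOR_DB = -80.0


@dataclass(frozen=True)
class SpectrogramParams:
    """Front-end configuration.

    window_s : STFT window length in seconds (20 ms default trades
        temporal-rate bandwidth against frequency resolution).
    hop_s : STFT hop in seconds; sets the temporal-rate Nyquist
        (4 ms -> +/- 125 Hz).
    channels_per_octave : density of the pooled log-frequency axis.
    fmin_hz / fmax_hz : range of the log-frequency axis; fmax defaults
        to 0.45 x sample rate.
    """

    window_s: float = 0.020
    hop_s: float = 0.004
    channels_per_octave: int = 12
    fmin_hz: float = 125.0
    fmax_hz: float | None = None


@dataclass
class Spectrogram:
    values: np.ndarray  # channels x frames, log amplitude (dB)
    times_s: np.ndarray
    freqs_hz: np.ndarray  # log-spaced channel centers
    hop_s: float
    channels_per_octave: int


@dataclass
class MPSGrid:
    amplitudes: np.ndarray  # spectral rates x temporal rates, >= 0
    temporal_rates_hz: np.ndarray  # signed, monotone
    spectral_rates_cpo: np.ndarray  # cycles/octave, signed, monotone
    stimulus_id: str = ""

    def __post_init__(self):
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.amplitudes.shape != (
            len(self.spectral_rates_cpo),
            len(self.temporal_rates_hz),
        ):
            raise InvalidArgumentError("MPS grid shape must match its axes")
        if np.any(~np.isfinite(self.amplitudes)) or self.amplitudes.min() < 0:
            raise InvalidArgumentError("MPS amplitudes must be finite and >= 0")
        if np.any(np.diff(self.temporal_rates_hz) <= 0) or np.any(
            np.diff(self.spectral_rates_cpo) <= 0
        ):
            raise InvalidArgumentError("MPS axes must be strictly increasing")

    @property
    def temporal_rate_step_hz(self) -> float:
        return float(self.temporal_rates_hz[1] - self.temporal_rates_hz[0])

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            self.amplitudes,
            index=self.spectral_rates_cpo,
            columns=self.temporal_rates_hz,
        ).to_csv(path, sep="\t")


def compute_spectrogram(
    waveform: np.ndarray,
    sample_rate_hz: float,
    params: SpectrogramParams = SpectrogramParams(),
) -> Spectrogram:
    """Log-amplitude spectrogram on a log-spaced frequency axis."""
    waveform = np.asarray(waveform, dtype=float).ravel()
    if waveform.size == 0:
        raise InvalidArgumentError("waveform is empty")
    nperseg = max(8, int(round(params.window_s * sample_rate_hz)))
    hop = max(1, int(round(params.hop_s * sample_rate_hz)))
    if waveform.size < nperseg:
        waveform = np.pad(waveform, (0, nperseg - waveform.size))
    freqs, times, stft = signal.stft(
        waveform,
        fs=sample_rate_hz,
        nperseg=nperseg,
        noverlap=nperseg - hop,
        boundary=None,
        padded=False,
    )
    power = np.abs(stft)

    fmax = params.fmax_hz or 0.45 * sample_rate_hz
    n_oct = np.log2(fmax / params.fmin_hz)
    n_chan = max(2, int(np.floor(n_oct * params.channels_per_octave)) + 1)
    centers = params.fmin_hz * 2.0 ** (
        np.arange(n_chan) / params.channels_per_octave
    )
    # pool linear bins into log channels by triangular interpolation weights
    pooled = np.empty((n_chan, power.shape[1]))
    log_f = np.log2(np.maximum(freqs, 1e-6))
    log_c = np.log2(centers)
    width = 1.0 / params.channels_per_octave
    for i, lc in enumerate(log_c):
        w = np.clip(1.0 - np.abs(log_f - lc) / width, 0.0, None)
        w[freqs <= 0] = 0.0
        wsum = w.sum()
        pooled[i] = (w @ power) / wsum if wsum > 0 else 0.0

    ref = pooled.max()
    floor = max(ref, 1e-300) * 10.0 ** (LOG_FLOOR_DB / 20.0)
    log_amp = 20.0 * np.log10(np.maximum(pooled, floor) / max(ref, 1e-300))
    return Spectrogram(
        values=log_amp,
        times_s=times,
        freqs_hz=centers,
        hop_s=hop / sample_rate_hz,
        channels_per_octave=params.channels_per_octave,
    )


def compute_mps(spec: Spectrogram, stimulus_id: str = "") -> MPSGrid:
    """Modulus of the 2D FFT of the mean-subtracted log spectrogram."""
    if spec.hop_s <= 0 or spec.channels_per_octave <= 0:
        raise InvalidArgumentError("spectrogram axis steps unknown")
    x = spec.values - spec.values.mean()
    mps = np.abs(np.fft.fftshift(np.fft.fft2(x)))
    n_chan, n_frames = x.shape
    temporal = np.fft.fftshift(np.fft.fftfreq(n_frames, d=spec.hop_s))
    spectral = np.fft.fftshift(
        np.fft.fftfreq(n_chan, d=1.0 / spec.channels_per_octave)
    )
    return MPSGrid(
        amplitudes=mps,
        temporal_rates_hz=temporal,
        spectral_rates_cpo=spectral,
        stimulus_id=stimulus_id,
    )


def peak_temporal_modulation(
    mps: MPSGrid,
    dc_exclusion_hz: float | None = None,
    prominence_factor: float = 2.0,
) -> float:
    """Dominant temporal modulation rate in Hz.

    The spectral-rate axis is marginalized (summed), and the argmax is
    taken over positive temporal rates above a DC-exclusion floor
    (default: one temporal-rate bin, so the stationary-energy peak at
    0 Hz cannot win). A candidate only counts as a peak if it rises at
    least ``prominence_factor`` above the median of the searched
    marginal; stationary noise has a flat marginal (no rate beats the
    background by that factor) and raises :class:`UndefinedPeakError`,
    as does an all-zero grid.
    """
    marginal = mps.amplitudes.sum(axis=0)
    if dc_exclusion_hz is None:
        dc_exclusion_hz = mps.temporal_rate_step_hz
    ok = mps.temporal_rates_hz > dc_exclusion_hz
    if not ok.any() or np.all(marginal[ok] == 0):
        raise UndefinedPeakError("no temporal-modulation energy above the DC floor")
    rates, vals = mps.temporal_rates_hz[ok], marginal[ok]
    best = int(np.argmax(vals))
    if vals[best] < prominence_factor * np.median(vals):
        raise UndefinedPeakError(
            "no temporal-modulation rate rises above the stationary background"
        )
    return float(rates[best])


def _common_grid_mps(
    waves: list[np.ndarray], sample_rate_hz: float, params: SpectrogramParams
) -> list[MPSGrid]:
    """Zero-pad to the longest waveform so all MPS grids share axes."""
    n_max = max(w.size for w in waves)
    grids = []
    for w in waves:
        padded = np.pad(np.asarray(w, float).ravel(), (0, n_max - w.size))
        grids.append(compute_mps(compute_spectrogram(padded, sample_rate_hz, params)))
    return grids


def load_waveform(path: str | Path) -> tuple[np.ndarray, float]:
    """Read a WAV file to a float mono waveform in [-1, 1]."""
    rate, data = wavfile.read(str(path))
    data = np.asarray(data)
    if data.ndim > 1:
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data / float(np.iinfo(data.dtype).max)
    return data.astype(float), float(rate)


def save_waveform(path: str | Path, waveform: np.ndarray, sample_rate_hz: float) -> None:
    wavfile.write(str(path), int(sample_rate_hz), np.asarray(waveform, np.float32))


def mps_rdm(
    stimulus_set: StimulusSet,
    params: SpectrogramParams = SpectrogramParams(),
    waveforms: dict[str, tuple[np.ndarray, float]] | None = None,
    distance: str = "euclidean",
) -> RDM:
    """Acoustic RDM: pairwise distance between vectorized log-MPS grids.

    Waveforms are read from each stimulus's ``waveform_ref`` unless an
    in-memory ``{stimulus_id: (waveform, rate)}`` mapping is supplied.
    All stimuli are zero-padded to the set maximum and must share a
    sample rate. ``distance`` is Euclidean on log amplitudes by default;
    ``"correlation"`` is available as an alternative.
    """
    waves, rates = [], []
    for s in stimulus_set:
        if waveforms is not None and s.stimulus_id in waveforms:
            w, r = waveforms[s.stimulus_id]
        elif s.waveform_ref:
            w, r = load_waveform(s.waveform_ref)
        else:
            raise InvalidArgumentError(f"stimulus {s.stimulus_id!r} has no waveform")
        waves.append(np.asarray(w, float).ravel())
        rates.append(r)
    if len(set(rates)) > 1:
        raise InvalidArgumentError("all waveforms must share a sample rate")
    grids = _common_grid_mps(waves, rates[0], params)
    eps = 1e-12
    vecs = np.vstack([np.log(g.amplitudes.ravel() + eps) for g in grids])
    if distance == "euclidean":
        mat = squareform_pdist(vecs, "euclidean")
    elif distance == "correlation":
        mat = squareform_pdist(vecs, "correlation")
    else:
        raise InvalidArgumentError(f"unknown distance {distance!r}")
    return RDM(
        condition_labels=stimulus_set.ids,
        matrix=mat,
        metric_tag="mps_distance",
        name="mps",
    )


def squareform_pdist(vecs: np.ndarray, metric: str) -> np.ndarray:
    from scipy.spatial.distance import pdist, squareform

    mat = squareform(pdist(vecs, metric=metric))
    np.fill_diagonal(mat, 0.0)
    return mat
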