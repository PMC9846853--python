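"""Synthetic data with the statistical structure the analysis assumes.

The generative model for a beta value of event ``e`` at voxel ``v`` is

    beta_ev = (mu_v + a * s_v * 1[e is vocal]) * (1 + g * 1[e is speech])
              + noise_ev

where ``mu_v`` is a positive per-voxel baseline, ``a`` (``vocal_effect``)
scales a fixed signed selectivity pattern ``s_v in {-1, +1}`` carried by a
random subset of voxels, and ``g`` (``speech_gain``) is a multiplicative
gain applied *uniformly across voxels* to speech events. The gain encodes
the hypothesis that speech drives voice-selective cortex in the same
topography as other vocal sounds, only more strongly: because it is
voxel-uniform, z-scoring each event along the voxel dimension removes it
exactly, while z-scoring each voxel along the event dimension preserves
it. Noise is i.i.d. Gaussian across events and voxels — betas, not time
series, are modelled, so no temporal autocorrelation is simulated.

Default parameters describe a voice-selective ROI of 57 voxels scanned in
two runs: baseline betas of order 1, a selectivity pattern of amplitude
0.6 on half the voxels, a speech gain that doubles activation (g = 1),
and noise of 0.4 beta units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidArgumentError
from .patterns import ActivityPattern
from .stimuli import StimulusSet
from .volumes import VolumeMap


@dataclass(frozen=True)
class GenerativeConfig:
    """Parameters of the synthetic beta-pattern generator.

    n_voxels : ROI size (the analyses use 57).
    vocal_effect : amplitude of the signed vocal-selectivity pattern, beta units.
    speech_gain : voxel-uniform multiplicative gain for speech events (>= 0);
        1.0 doubles the activation of speech events.
    noise_sd : sd of the additive Gaussian noise on each beta.
    selectivity_fraction : fraction of voxels carrying the vocal pattern.
    n_runs : scanning runs, each presenting every stimulus once.
    seed : master seed; identical config implies bit-identical output.
    """

    n_voxels: int = 57
    vocal_effect: float = 0.6
    speech_gain: float = 1.0
    noise_sd: float = 0.4
    selectivity_fraction: float = 0.5
    n_runs: int = 2
    seed: int = 0
    baseline_range: tuple[float, float] = (0.5, 1.5)

    def __post_init__(self):
        if self.n_voxels < 1:
            raise InvalidArgumentError("n_voxels must be positive")
        if self.speech_gain < 0:
            raise InvalidArgumentError("speech_gain must be >= 0")
        if self.noise_sd < 0:
            raise InvalidArgumentError("noise_sd must be >= 0")
        if not (0 < self.selectivity_fraction <= 1):
            raise InvalidArgumentError("selectivity_fraction must be in (0, 1]")
        if self.n_runs < 1:
            raise InvalidArgumentError("n_runs must be positive")


def generate_beta_patterns(
    stimulus_set: StimulusSet, config: GenerativeConfig, participant_id: str = "sim"
) -> ActivityPattern:
    """One beta row per stimulus per run (rows = |stimuli| x n_runs).

    Rows are grouped by run (run 0 first), each run presenting the
    stimuli in catalog order, with run labels attached.
    """
    if len(stimulus_set) == 0:
        raise InvalidArgumentError("stimulus set is empty")
    rng = np.random.default_rng(config.seed)
    nv = config.n_voxels

    mu = rng.uniform(*config.baseline_range, size=nv)
    n_sel = max(1, round(config.selectivity_fraction * nv))
    sel = rng.choice(nv, size=n_sel, replace=False)
    s = np.zeros(nv)
    s[sel] = rng.choice([-1.0, 1.0], size=n_sel)

    is_vocal = stimulus_set.is_vocal().astype(float)
    is_speech = np.array(
        [st.subcategory == "speech" for st in stimulus_set], dtype=float
    )
    # stimulus-by-voxel mean response, identical across runs
    signal = (mu[None, :] + config.vocal_effect * np.outer(is_vocal, s)) * (
        1.0 + config.speech_gain * is_speech[:, None]
    )

    n_stim = len(stimulus_set)
    rows = np.tile(signal, (config.n_runs, 1))
    rows = rows + rng.normal(0.0, config.noise_sd, size=rows.shape)
    run_labels = np.repeat(np.arange(config.n_runs), n_stim)
    row_labels = stimulus_set.ids * config.n_runs
    return ActivityPattern(
        values=rows,
        row_labels=row_labels,
        run_labels=run_labels,
        participant_id=participant_id,
    )


def generate_volume_maps(
    shape: tuple[int, int, int],
    centers: list[tuple[int, int, int]],
    peak_values: list[float],
    kind: str = "probability",
    seed: int = 0,
    bump_sd_voxels: float = 3.0,
    noise_sd: float | None = None,
    affine: np.ndarray | None = None,
) -> VolumeMap:
    """Smooth unimodal Gaussian bump around each center, plus small noise.

    The value at each listed center is guaranteed to be a strict local
    maximum; probability-kind maps are clipped to [0, 1]. ``noise_sd``
    defaults to 0.5% of the smallest peak so noise never creates spurious
    maxima near a bump.
    """
    shape = tuple(int(s) for s in shape)
    if len(centers) != len(peak_values):
        raise InvalidArgumentError("need one peak value per center")
    for c in centers:
        if any(ci < 0 or ci >= si for ci, si in zip(c, shape)):
            raise InvalidArgumentError(f"center {c} lies outside grid {shape}")
    rng = np.random.default_rng(seed)
    ii, jj, kk = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    grid = np.zeros(shape)
    for (ci, cj, ck), peak in zip(centers, peak_values):
        d2 = (ii - ci) ** 2 + (jj - cj) ** 2 + (kk - ck) ** 2
        grid += peak * np.exp(-d2 / (2.0 * bump_sd_voxels**2))
    if noise_sd is None:
        noise_sd = 0.005 * min(abs(p) for p in peak_values) if peak_values else 0.0
    grid += rng.normal(0.0, noise_sd, size=shape)
    # pin each requested center to a strict local maximum of its neighborhood
    for (ci, cj, ck), peak in zip(centers, peak_values):
        sl = tuple(
            slice(max(0, c - 1), min(s, c + 2)) for c, s in zip((ci, cj, ck), shape)
        )
        grid[ci, cj, ck] = max(grid[ci, cj, ck], grid[sl].max() + abs(noise_sd) + 1e-9)
    if kind == "probability":
        grid = np.clip(grid, 0.0, 1.0)
    return VolumeMap(
        grid=grid,
        affine=np.eye(4) if affine is None else np.asarray(affine, float),
        kind=kind,
    )


def generate_am_noise(
    mod_rate_hz: float,
    duration_s: float,
    sample_rate_hz: float = 16000.0,
    seed: int = 0,
) -> np.ndarray:
    """White-noise carrier with sinusoidal amplitude modulation.

    The envelope is ``(1 + sin(2 pi f t)) / 2``; the waveform is peak
    normalized to 1. A fixture for calibrating the temporal-rate axis of
    the modulation power spectrum (speech carries salient modulation
    energy near the ~4 Hz syllabic rate).
    """
    if mod_rate_hz <= 0:
        raise InvalidArgumentError("mod_rate_hz must be > 0")
    if duration_s <= 0:
        raise InvalidArgumentError("duration_s must be > 0")
    if mod_rate_hz >= sample_rate_hz / 2:
        raise InvalidArgumentError("mod_rate_hz must be below Nyquist")
    n = int(round(duration_s * sample_rate_hz))
    t = np.arange(n) / sample_rate_hz
    rng = np.random.default_rng(seed)
    carrier = rng.standard_normal(n)
    envelope = (1.0 + np.sin(2.0 * np.pi * mod_rate_hz * t)) / 2.0
    wave = carrier * envelope
    peak = np.abs(wave).max()
    return wave / peak if peak > 0 else wave
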