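"""Filtering, Morlet time-frequency analysis and Hilbert band power.

The time-frequency decomposition uses a five-cycle Morlet wavelet at 40
log-spaced frequencies spanning 2-70 Hz.  Power is normalized per time
point by the sum across frequencies ("relative" mode, applied before the
log transform for positivity; a "literal" mode that logs first is retained
behind a switch) so the statistic is a relative power fraction, invariant
to global amplitude scaling.  Movement-onset power in [-0.5, 0.5] s is
baseline corrected by stationary power in [0, 1] s, and the scalar theta
contrast averages the 4-10 Hz bins.  Continuous band power is the analytic
signal magnitude of zero-phase band-passed data, Z-scored per voxel within
each task block.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from mne.time_frequency import tfr_array_morlet
from scipy import signal

from .errors import InvalidArgumentError
from .navio import VoxelSeries
from .epochs import (EpochSet, MOVEMENT_ANALYSIS_WINDOW,
                     STATIONARY_ANALYSIS_WINDOW)

__all__ = [
    "DEFAULT_FREQS",
    "THETA_BAND",
    "CONTROL_BANDS",
    "Spectrogram",
    "BandPowerSeries",
    "preprocess_filter",
    "morlet_spectrogram",
    "epoch_spectrograms",
    "normalize_power",
    "movement_vs_stationary_contrast",
    "hilbert_band_power",
]

N_CYCLES = 5
DEFAULT_FREQS = np.logspace(np.log10(2.0), np.log10(70.0), 40)
THETA_BAND = (4.0, 10.0)
CONTROL_BANDS = {
    "delta": (2.0, 4.0),
    "theta": (4.0, 10.0),
    "alpha": (12.0, 20.0),
    "beta": (20.0, 35.0),
    "gamma": (40.0, 70.0),
}


@dataclass
class Spectrogram:
    """Per-epoch power: epochs x frequencies x times."""

    freqs: np.ndarray      # Hz, ascending
    times: np.ndarray      # s relative to onset
    power: np.ndarray      # (n_epochs, n_freqs, n_times); NaN where edge-contaminated
    mode: str = "raw"      # "raw" | "relative" | "literal"

    def band_indices(self, band):
        return np.flatnonzero((self.freqs >= band[0]) & (self.freqs <= band[1]))


@dataclass
class BandPowerSeries:
    """Z-scored Hilbert envelope of band-passed data, per voxel."""

    band: tuple
    sample_rate: float
    start_time: float
    values: np.ndarray     # voxels x samples, Z-units
    mean: np.ndarray       # per-voxel envelope mean used for Z-scoring
    sd: np.ndarray         # per-voxel envelope SD
    block_id: str = "0"

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.values.shape[1]) / self.sample_rate


# ---------------------------------------------------------------------------
# filtering

def preprocess_filter(series: VoxelSeries, highpass: float = 1.0,
                      notch: tuple = (48.0, 52.0), order: int = 5) -> VoxelSeries:
    """Zero-phase 5th-order Butterworth 1 Hz high-pass and 48-52 Hz band-stop."""
    if series.sample_rate <= 2 * notch[1]:
        raise InvalidArgumentError(
            f"sample rate {series.sample_rate} Hz too low for the {notch} Hz notch")
    sos_hp = signal.butter(order, highpass, btype="highpass",
                           fs=series.sample_rate, output="sos")
    sos_bs = signal.butter(order, notch, btype="bandstop",
                           fs=series.sample_rate, output="sos")
    out = signal.sosfiltfilt(sos_hp, series.values, axis=1)
    out = signal.sosfiltfilt(sos_bs, out, axis=1)
    return VoxelSeries(series.sample_rate, series.start_time, out,
                       list(series.labels), series.block_id)


# ---------------------------------------------------------------------------
# Morlet spectrograms

def morlet_spectrogram(data: np.ndarray, sample_rate: float,
                       times: np.ndarray | None = None,
                       freqs: np.ndarray = DEFAULT_FREQS) -> Spectrogram:
    """Five-cycle Morlet wavelet power of epoched data.

    ``data`` is (n_epochs, n_times).  Samples closer than half a wavelet
    (``n_cycles / freq / 2``) to an epoch edge are set to NaN per frequency
    and excluded from downstream averages.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    n_times = data.shape[1]
    min_len = int(np.ceil(N_CYCLES / freqs[0] * sample_rate))
    if n_times < min_len:
        raise InvalidArgumentError(
            f"epoch of {n_times} samples shorter than one {freqs[0]:g} Hz wavelet"
            f" ({min_len} samples)")
    power = tfr_array_morlet(data[:, None, :], sfreq=sample_rate, freqs=freqs,
                             n_cycles=N_CYCLES, output="power", zero_mean=True)
    power = power[:, 0]  # drop channel axis -> (epochs, freqs, times)
    idx = np.arange(n_times)
    for fi, f in enumerate(freqs):
        half = int(np.ceil(N_CYCLES / f * sample_rate / 2.0))
        edge = (idx < half) | (idx >= n_times - half)
        power[:, fi, edge] = np.nan
    if times is None:
        times = np.arange(n_times) / sample_rate
    return Spectrogram(np.asarray(freqs, dtype=float), np.asarray(times, dtype=float),
                       power, mode="raw")


def epoch_spectrograms(series: VoxelSeries, epochset: EpochSet, voxel: int = 0,
                       freqs: np.ndarray = DEFAULT_FREQS,
                       exclude_mask: np.ndarray | None = None) -> Spectrogram:
    """Morlet spectrograms of all accepted epochs of one voxel.

    ``exclude_mask`` (bool, per signal sample) NaN-masks overlap-excluded
    samples after the transform so they drop out of averages.
    """
    fs = series.sample_rate
    lo, hi = epochset.window
    n_win = int(round((hi - lo) * fs)) + 1
    t = series.times
    rows, masks = [], []
    for onset, acc in zip(epochset.onsets, epochset.accepted):
        if not acc:
            continue
        i0 = int(round((onset + lo - series.start_time) * fs))
        if i0 < 0 or i0 + n_win > series.n_samples:
            continue
        rows.append(series.values[voxel, i0:i0 + n_win])
        if exclude_mask is not None:
            masks.append(exclude_mask[i0:i0 + n_win])
    if not rows:
        raise InvalidArgumentError(f"no accepted {epochset.kind} epochs")
    rel_times = lo + np.arange(n_win) / fs
    spec = morlet_spectrogram(np.array(rows), fs, times=rel_times, freqs=freqs)
    if masks:
        mask = np.broadcast_to(np.array(masks)[:, None, :], spec.power.shape)
        spec.power[mask] = np.nan
    return spec


def normalize_power(spec: Spectrogram, mode: str = "relative") -> Spectrogram:
    """Normalize by the per-time sum across frequencies, then log.

    ``relative`` (default): power fractions (sum to 1 across frequencies),
    then log10 — scale invariant and positivity safe.  ``literal``: log
    transform first, then divide by the per-time sum of log values (the
    literal stated order; ambiguous when logs are negative, kept as an
    explicit option).
    """
    if spec.mode != "raw":
        raise InvalidArgumentError("spectrogram already normalized")
    p = spec.power
    finite = np.isfinite(p)
    if np.any(p[finite] <= 0):
        raise InvalidArgumentError("power must be strictly positive")
    # only times where all frequencies are uncontaminated are normalizable
    all_ok = finite.all(axis=1, keepdims=True)
    if mode == "relative":
        tot = np.where(all_ok, np.sum(np.where(finite, p, 0.0), axis=1, keepdims=True), np.nan)
        out = np.log10(p / tot)
    elif mode == "literal":
        lp = np.log(p)
        tot = np.where(all_ok, np.sum(np.where(finite, lp, 0.0), axis=1, keepdims=True), np.nan)
        out = lp / tot
    else:
        raise InvalidArgumentError(f"unknown normalization mode {mode!r}")
    out = np.where(all_ok & finite, out, np.nan)
    return Spectrogram(spec.freqs, spec.times, out, mode=mode)


# ---------------------------------------------------------------------------
# contrasts

@dataclass
class SpectralContrast:
    freqs: np.ndarray
    per_freq: np.ndarray       # movement-window mean minus stationary baseline
    theta: float               # scalar mean over the theta band
    tf: np.ndarray             # freqs x movement times, baseline corrected
    times: np.ndarray          # movement epoch times


def movement_vs_stationary_contrast(move_spec: Spectrogram, stat_spec: Spectrogram,
                                    band: tuple = THETA_BAND,
                                    move_window: tuple = MOVEMENT_ANALYSIS_WINDOW,
                                    stat_window: tuple = STATIONARY_ANALYSIS_WINDOW,
                                    ) -> SpectralContrast:
    """Baseline-corrected movement-onset power.

    Per frequency: mean normalized power over movement epochs and the
    movement analysis window minus the mean over stationary epochs and the
    stationary analysis window.  The scalar contrast averages the 4-10 Hz
    bins; the full time-frequency contrast subtracts the per-frequency
    stationary baseline at every movement time point.
    """
    if move_spec.mode == "raw" or stat_spec.mode == "raw":
        raise InvalidArgumentError("normalize spectrograms before contrasting")
    mt = (move_spec.times >= move_window[0]) & (move_spec.times <= move_window[1])
    st = (stat_spec.times >= stat_window[0]) & (stat_spec.times <= stat_window[1])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN edge columns
        move_pf = np.nanmean(move_spec.power[:, :, mt], axis=(0, 2))
        base_pf = np.nanmean(stat_spec.power[:, :, st], axis=(0, 2))
        per_freq = move_pf - base_pf
        bidx = move_spec.band_indices(band)
        theta = float(np.nanmean(per_freq[bidx]))
        tf = np.nanmean(move_spec.power, axis=0) - base_pf[:, None]
    return SpectralContrast(move_spec.freqs, per_freq, theta, tf, move_spec.times)


# ---------------------------------------------------------------------------
# Hilbert band power

def hilbert_band_power(series: VoxelSeries, band: tuple = THETA_BAND,
                       order: int = 5) -> BandPowerSeries:
    """Z-scored analytic-signal magnitude of band-passed data.

    Band-pass is a zero-phase Butterworth (order ``order``, forward-backward)
    matching the preprocessing filter family.  Z-scoring is per voxel within
    the block, equating signal amplitude across voxels; the mean/SD used are
    retained so the envelope can be de-standardized.
    """
    nyq = series.sample_rate / 2.0
    if not (0.0 < band[0] < band[1] < nyq):
        raise InvalidArgumentError(f"band {band} outside (0, {nyq}) Hz")
    sos = signal.butter(order, band, btype="bandpass",
                        fs=series.sample_rate, output="sos")
    filt = signal.sosfiltfilt(sos, series.values, axis=1)
    env = np.abs(signal.hilbert(filt, axis=1))
    mean = env.mean(axis=1)
    sd = env.std(axis=1)
    sd_safe = np.where(sd == 0, 1.0, sd)
    z = (env - mean[:, None]) / sd_safe[:, None]
    return BandPowerSeries(tuple(band), series.sample_rate, series.start_time,
                           z, mean, sd, block_id=series.block_id)
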