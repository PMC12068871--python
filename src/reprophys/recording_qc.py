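"""Whole-recording quality metrics: unit yield, AP-band noise, and the LFP
power-spectral-density depth profile with its derivative criterion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

__all__ = [
    "LfpProfile",
    "yield_metric",
    "ap_rms_pass",
    "lfp_psd",
    "lfp_profile_from_psd",
    "lfp_derivative_pass",
]


@dataclass
class LfpProfile:
    """Per-channel LFP power spectra (dB) and band power along the probe."""

    channel_depths: np.ndarray        # um
    freqs: np.ndarray                 # Hz
    psd_db: np.ndarray                # channels x frequencies
    band: tuple                       # (low, high) Hz
    band_power_per_channel: np.ndarray  # dB; -inf flags silent channels


def yield_metric(
    n_passing_units: int, n_channels: int, threshold: float = 0.1
) -> tuple[float, bool]:
    """QC-passing units per electrode channel; passes at >= ``threshold``."""
    if n_channels <= 0:
        raise ValueError("n_channels must be positive")
    y = n_passing_units / n_channels
    return y, bool(y >= threshold)


def ap_rms_pass(
    ap_rms_per_channel: np.ndarray, threshold: float = 40.0
) -> tuple[float, bool]:
    """Median AP-band RMS across channels; passes strictly below ``threshold`` uV."""
    rms = np.asarray(ap_rms_per_channel, dtype=float)
    if len(rms) == 0:
        raise ValueError("ap_rms_per_channel must be non-empty")
    med = float(np.median(rms))
    return med, bool(med < threshold)


def _band_power(psd_db: np.ndarray, freqs: np.ndarray, band: tuple) -> np.ndarray:
    mask = (freqs >= band[0]) & (freqs <= band[1])
    if not mask.any():
        raise ValueError(f"no frequency bins inside band {band}")
    return psd_db[:, mask].mean(axis=1)


def lfp_psd(
    lfp: np.ndarray,
    fs: float,
    channel_depths: np.ndarray | None = None,
    nperseg: int = 1024,
    band: tuple = (20.0, 80.0),
) -> LfpProfile:
    """Per-channel power spectral density of raw LFP traces.

    Uses Welch's method with Hann windows of ``nperseg`` samples and 50%
    overlap, converted to decibels as ``10 * log10(PSD)``. Channels with
    zero power in a frequency bin get ``-inf`` there; an all-zero channel
    therefore carries a ``-inf`` band power, flagging it as silent.
    """
    lfp = np.atleast_2d(np.asarray(lfp, dtype=float))
    if lfp.shape[1] < nperseg:
        raise ValueError("need at least nperseg samples per channel")
    if fs <= 2 * band[1]:
        raise ValueError("sampling rate too low for the requested band")
    freqs, psd = signal.welch(
        lfp, fs=fs, window="hann", nperseg=nperseg, noverlap=nperseg // 2, axis=1
    )
    with np.errstate(divide="ignore"):
        psd_db = 10.0 * np.log10(psd)
    if channel_depths is None:
        channel_depths = np.arange(lfp.shape[0], dtype=float)
    return LfpProfile(
        channel_depths=np.asarray(channel_depths, dtype=float),
        freqs=freqs,
        psd_db=psd_db,
        band=band,
        band_power_per_channel=_band_power(psd_db, freqs, band),
    )


def lfp_profile_from_psd(
    psd_db: np.ndarray,
    freqs: np.ndarray,
    channel_depths: np.ndarray,
    band: tuple = (20.0, 80.0),
) -> LfpProfile:
    """Build an :class:`LfpProfile` from a precomputed dB spectrum table."""
    psd_db = np.asarray(psd_db, dtype=float)
    freqs = np.asarray(freqs, dtype=float)
    return LfpProfile(
        channel_depths=np.asarray(channel_depths, dtype=float),
        freqs=freqs,
        psd_db=psd_db,
        band=band,
        band_power_per_channel=_band_power(psd_db, freqs, band),
    )


def lfp_derivative_pass(
    profile: LfpProfile, threshold: float = 0.05
) -> tuple[float, bool]:
    """Median absolute depth-derivative of LFP band power (dB/um).

    Finite differences along channel depth (central in the interior,
    one-sided at the ends); the absolute value is used because the sign of
    the gradient depends only on probe orientation. Passes strictly below
    ``threshold``.
    """
    depths = profile.channel_depths
    power = profile.band_power_per_channel
    if len(depths) < 2 or np.ptp(depths) == 0:
        raise ValueError("need >= 2 channels at distinct depths")
    deriv = np.gradient(power, depths)
    med = float(np.median(np.abs(deriv)))
    return med, bool(med < threshold)
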