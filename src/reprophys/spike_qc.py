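"""Single-unit quality metrics.

Three computed criteria decide whether a sorted unit enters analysis:

* a sliding refractory-period test, which asks — for every candidate
  refractory length — whether the observed count of short inter-spike
  intervals is improbably low under exactly 10% contamination, assuming
  Poisson spiking;
* an amplitude-cutoff test, which detects truncation of the spike
  amplitude histogram (evidence of missed low-amplitude spikes) without
  assuming a Gaussian shape;
* a median spike amplitude threshold (50 uV).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

from .io_core import CriterionResult, QCReport, UnitRecord

__all__ = [
    "RPResult",
    "CutoffResult",
    "sliding_rp_confidence",
    "amplitude_cutoff",
    "median_amplitude_pass",
    "unit_qc",
]


@dataclass
class RPResult:
    """Contamination confidence across a grid of refractory-period lengths."""

    rp_grid: np.ndarray
    confidence_per_rp: np.ndarray
    max_confidence: float
    passed: bool
    reason: Optional[str] = None


@dataclass
class CutoffResult:
    """Amplitude-histogram truncation evidence."""

    sd_distance: float
    low_bin_fraction: float
    passed: bool
    reason: Optional[str] = None


def sliding_rp_confidence(
    spike_times: np.ndarray,
    duration: float,
    rp_min: float = 0.0005,
    rp_max: float = 0.010,
    n_rp: int = 50,
    max_contamination: float = 0.1,
    confidence_threshold: float = 0.9,
) -> RPResult:
    """Confidence that a unit is below ``max_contamination`` contamination.

    For each refractory length ``t_r`` on a logarithmic grid, the observed
    violations ``k`` are the consecutive inter-spike intervals shorter than
    ``t_r``. Under exactly ``max_contamination`` contamination, violations
    are Poisson with mean ``2 * t_r * max_contamination * N * r`` (each
    contaminating spike can violate against either neighbour), where ``N``
    is the spike count and ``r = N / duration``. The confidence is the
    probability of seeing strictly more than ``k`` violations,
    ``P[Poisson(lam) > k]``; the unit passes if any refractory length
    reaches confidence above ``confidence_threshold``.
    """
    spike_times = np.asarray(spike_times, dtype=float)
    if duration <= 0:
        raise ValueError("duration must be positive")
    grid = np.geomspace(rp_min, rp_max, n_rp)
    if len(spike_times) < 2:
        return RPResult(
            rp_grid=grid,
            confidence_per_rp=np.zeros_like(grid),
            max_confidence=0.0,
            passed=False,
            reason="insufficient spikes",
        )
    isi = np.sort(np.diff(spike_times))
    k = np.searchsorted(isi, grid, side="left")  # count of ISIs < t_r
    n = len(spike_times)
    rate = n / duration
    lam = 2.0 * grid * max_contamination * n * rate
    confidence = stats.poisson.sf(k, lam)
    max_conf = float(confidence.max())
    return RPResult(
        rp_grid=grid,
        confidence_per_rp=confidence,
        max_confidence=max_conf,
        passed=bool(max_conf > confidence_threshold),
    )


def amplitude_cutoff(
    amplitudes: np.ndarray,
    n_bins: int = 100,
    sd_threshold: float = 5.0,
    low_frac_threshold: float = 0.1,
    min_spikes: int = 50,
) -> CutoffResult:
    """Detect a truncated amplitude distribution (missed low spikes).

    The amplitude histogram's lowest bin is compared with the bins in the
    highest quantile of the distribution — the top quarter (by bin index)
    of the bins above the histogram peak. The unit fails if the low bin
    sits ``sd_threshold`` or more SDs above the mean of those high bins,
    or if it exceeds ``low_frac_threshold`` of the peak bin's height.
    """
    amps = np.asarray(amplitudes, dtype=float)
    if len(amps) < min_spikes:
        return CutoffResult(np.nan, np.nan, False, reason="insufficient spikes")
    if np.ptp(amps) == 0:
        return CutoffResult(np.nan, np.nan, False, reason="degenerate distribution")
    hist, _ = np.histogram(amps, bins=n_bins)
    peak = int(np.argmax(hist))
    above = hist[peak + 1 :]
    if len(above) == 0:
        # Peak in the last bin: nothing above it to compare against.
        return CutoffResult(np.inf, 1.0, False, reason="degenerate distribution")
    n_high = max(1, int(np.ceil(len(above) / 4)))
    high = above[-n_high:].astype(float)
    h_low = float(hist[0])
    mean_high = float(high.mean())
    sd_high = float(high.std())
    if sd_high == 0:
        sd_distance = 0.0 if h_low == mean_high else np.inf
    else:
        sd_distance = (h_low - mean_high) / sd_high
    low_bin_fraction = h_low / float(hist[peak])
    passed = bool(sd_distance < sd_threshold and low_bin_fraction < low_frac_threshold)
    return CutoffResult(sd_distance, low_bin_fraction, passed)


def median_amplitude_pass(
    amplitudes: np.ndarray, threshold: float = 50.0
) -> tuple[bool, float]:
    """Median amplitude criterion: the median must exceed ``threshold`` uV
    (strict inequality). Returns ``(passed, median)``."""
    amps = np.asarray(amplitudes, dtype=float)
    if len(amps) == 0:
        return False, np.nan
    med = float(np.median(amps))
    return med > threshold, med


def unit_qc(
    unit: UnitRecord,
    duration: float,
    median_threshold: float = 50.0,
    **rp_kwargs,
) -> QCReport:
    """Run all three single-unit criteria and combine them into a report.

    The overall verdict is the conjunction of the three criteria; failures
    are reported with reasons, never raised.
    """
    report = QCReport()

    rp = sliding_rp_confidence(unit.spike_times, duration, **rp_kwargs)
    report.add(
        CriterionResult(
            name="refractory_period",
            value=rp.max_confidence,
            threshold=0.9,
            passed=rp.passed,
            reason=rp.reason,
        )
    )

    cut = amplitude_cutoff(unit.amplitudes)
    report.add(
        CriterionResult(
            name="amplitude_cutoff",
            value=cut.sd_distance,
            threshold=5.0,
            passed=cut.passed,
            reason=cut.reason,
        )
    )

    passed, med = median_amplitude_pass(unit.amplitudes, threshold=median_threshold)
    report.add(
        CriterionResult(
            name="median_amplitude",
            value=med,
            threshold=median_threshold,
            passed=passed,
            reason=None if len(unit.amplitudes) else "no spikes",
        )
    )
    return report
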