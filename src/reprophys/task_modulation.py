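"""Window-comparison tests of task modulation and the movement-window Fano
factor.

Six tests compare firing rates between task-related time windows on
correct, non-zero-contrast trials: paired pre/post comparisons use the
Wilcoxon signed-rank test; unpaired left-versus-right comparisons use the
rank-sum (Mann-Whitney) test. A unit counts as modulated on a test when
p < 0.05 with no unit-level multiple-test correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import UnitRecord

__all__ = [
    "ModulationResult",
    "DEFAULT_WINDOWS",
    "trial_window_rates",
    "modulation_tests",
    "fano_factor",
    "proportion_modulated",
]

#: The six tests: paired tests give (align, pre-window, post-window);
#: split tests give (align, window, column to split trials by).
DEFAULT_WINDOWS: dict = {
    "stimulus": {
        "paired": True, "align": "stim_on", "pre": (-0.2, 0.0), "post": (0.0, 0.4),
    },
    "movement_initiation": {
        "paired": True, "align": "first_move", "pre": (-0.2, 0.0), "post": (0.0, 0.2),
    },
    "left_vs_right_movement": {
        "paired": False, "align": "first_move", "window": (0.0, 0.2), "split": "choice",
    },
    "feedback": {
        "paired": True, "align": "feedback_time", "pre": (-0.2, 0.0), "post": (0.0, 0.2),
    },
    "stimulus_left_vs_right": {
        "paired": False, "align": "stim_on", "window": (0.0, 0.4), "split": "side",
    },
    "movement_vs_baseline": {
        "paired": True, "align_pre": "stim_on", "pre": (-0.2, 0.0),
        "align": "first_move", "post": (0.0, 0.4),
    },
}


@dataclass
class ModulationResult:
    """Outcome of one task-modulation test for one unit.

    ``modulated`` is None when the test is undetermined (too few usable
    trials); such units are excluded from modulated-proportion summaries.
    ``magnitude`` is the firing-rate difference in spikes/s (post minus
    pre, or left minus right).
    """

    test: str
    p_value: float
    modulated: Optional[bool]
    magnitude: float
    n_trials: int


def trial_window_rates(
    spike_times: np.ndarray, events: np.ndarray, window: tuple
) -> np.ndarray:
    """Per-trial firing rate in a half-open window around each event.

    ``rate_i = #spikes in [event_i + w0, event_i + w1) / (w1 - w0)``.
    Events that are NaN (missing) yield NaN rates, preserving trial
    alignment for paired comparisons.
    """
    w0, w1 = window
    if not w1 > w0:
        raise ValueError("window width must be positive")
    spike_times = np.asarray(spike_times, dtype=float)
    events = np.asarray(events, dtype=float)
    rates = np.full(len(events), np.nan)
    ok = np.isfinite(events)
    starts = events[ok] + w0
    stops = events[ok] + w1
    counts = np.searchsorted(spike_times, stops, side="left") - np.searchsorted(
        spike_times, starts, side="left"
    )
    rates[ok] = counts / (w1 - w0)
    return rates


def _signed_rank_p(pre: np.ndarray, post: np.ndarray) -> float:
    diff = post - pre
    if np.all(diff == 0):
        return 1.0
    try:
        return float(stats.wilcoxon(post, pre, zero_method="wilcox", correction=True).pvalue)
    except ValueError:
        return 1.0


def _rank_sum_p(a: np.ndarray, b: np.ndarray) -> float:
    return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)


def modulation_tests(
    unit: UnitRecord | np.ndarray,
    trials: pd.DataFrame,
    alpha: float = 0.05,
    min_trials: int = 5,
    windows: Optional[dict] = None,
) -> dict:
    """Run the six window-comparison tests on one unit.

    Trials are first filtered to correct (rewarded) trials with non-zero
    contrast. A test with fewer than ``min_trials`` usable trials on
    either side is reported as undetermined (``modulated=None``).
    """
    spikes = unit.spike_times if isinstance(unit, UnitRecord) else np.asarray(unit)
    windows = DEFAULT_WINDOWS if windows is None else windows
    use = trials[(trials["feedback_type"] == "reward") & (trials["contrast"] > 0)]

    results = {}
    for name, spec in windows.items():
        if spec["paired"]:
            align_pre = spec.get("align_pre", spec["align"])
            pre = trial_window_rates(spikes, use[align_pre].to_numpy(), spec["pre"])
            post = trial_window_rates(spikes, use[spec["align"]].to_numpy(), spec["post"])
            ok = np.isfinite(pre) & np.isfinite(post)
            pre, post = pre[ok], post[ok]
            n = len(pre)
            if n < min_trials:
                results[name] = ModulationResult(name, np.nan, None, np.nan, n)
                continue
            p = _signed_rank_p(pre, post)
            mag = float(post.mean() - pre.mean())
        else:
            rates = trial_window_rates(
                spikes, use[spec["align"]].to_numpy(), spec["window"]
            )
            grp = use[spec["split"]].to_numpy()
            ok = np.isfinite(rates)
            left = rates[ok & (grp == "left")]
            right = rates[ok & (grp == "right")]
            n = len(left) + len(right)
            if min(len(left), len(right)) < min_trials:
                results[name] = ModulationResult(name, np.nan, None, np.nan, n)
                continue
            p = _rank_sum_p(left, right)
            mag = float(left.mean() - right.mean())
        results[name] = ModulationResult(name, p, bool(p < alpha), mag, n)
    return results


def fano_factor(
    unit: UnitRecord | np.ndarray,
    trials: pd.DataFrame,
    window: tuple = (0.040, 0.200),
) -> float:
    """Fano factor of movement-window spike counts.

    Counts are taken in ``window`` after first-movement onset on correct
    trials with full-contrast right-side stimuli; FF is the unbiased
    variance over the mean of those counts (1 for a Poisson process).
    Returns NaN when fewer than two qualifying trials exist or the mean
    count is zero.
    """
    spikes = unit.spike_times if isinstance(unit, UnitRecord) else np.asarray(unit)
    use = trials[
        (trials["feedback_type"] == "reward")
        & (trials["contrast"] == 1.0)
        & (trials["side"] == "right")
    ]
    if len(use) < 2:
        return np.nan
    w0, w1 = window
    events = use["first_move"].to_numpy()
    counts = np.searchsorted(spikes, events + w1, side="left") - np.searchsorted(
        spikes, events + w0, side="left"
    )
    mean = counts.mean()
    if mean == 0:
        return np.nan
    return float(counts.var(ddof=1) / mean)


def proportion_modulated(
    unit_results: list,
    test: str,
    min_units: int = 4,
) -> float:
    """Fraction of determined units modulated on ``test`` within one
    session-region group.

    ``unit_results`` is a list of per-unit dictionaries as returned by
    :func:`modulation_tests`. Groups with fewer than ``min_units`` units
    (the good-units-per-region inclusion rule) or with no determined unit
    return NaN.
    """
    if len(unit_results) < min_units:
        return np.nan
    verdicts = [r[test].modulated for r in unit_results if r[test].modulated is not None]
    if not verdicts:
        return np.nan
    return float(np.mean(verdicts))
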