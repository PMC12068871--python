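"""Synthetic data generators with the statistical structure the analyses
assume: Poisson-like spike trains with absolute refractory periods and
controllable contamination, unimodal amplitude distributions optionally
truncated from below, biased-block trial tables, event-locked firing-rate
modulation per region, and hierarchical multi-lab populations with
injectable per-lab shifts.

Every generator is deterministic given its seed (or Generator); the
multi-lab generator derives per-session streams from the configured seed
with ``numpy.random.SeedSequence`` spawning, so output is bit-identical
across runs with the same configuration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd

from .geometry import PLANNED_REPEATED_SITE, Trajectory
from .io_core import REGIONS, SessionRecord, UnitRecord

__all__ = [
    "SynthConfig",
    "REGION_TEMPLATES",
    "gen_spike_train",
    "gen_event_locked_train",
    "gen_amplitudes",
    "gen_trial_table",
    "gen_multilab_population",
    "gen_lab_feature_values",
]

CONTRAST_SET = (0.0, 0.0625, 0.125, 0.25, 1.0)

#: Depth of each region's centre along the probe, um (superficial to deep).
REGION_DEPTHS = {"VISa/am": 500.0, "CA1": 1200.0, "DG": 1800.0, "LP": 2600.0, "PO": 3300.0}


def _bump(center: float, width: float, amp: float) -> Callable[[np.ndarray], np.ndarray]:
    return lambda t: amp * np.exp(-0.5 * ((t - center) / width) ** 2) * (t >= -3 * width)


def _step(lo: float, hi: float, amp: float) -> Callable[[np.ndarray], np.ndarray]:
    return lambda t: amp * ((t >= lo) & (t < hi))


def _ramp(length: float, amp: float) -> Callable[[np.ndarray], np.ndarray]:
    return lambda t: amp * np.clip(t / length, 0.0, 1.0) * (t >= 0) * (t < length)


#: Movement-aligned firing-rate templates (added rate in spikes/s as a
#: function of time since movement onset). A minimal basis of distinct
#: shapes — step, transient, ramp — sufficient to make the five regions
#: separable in a low-dimensional embedding of their trial-averaged
#: responses.
REGION_TEMPLATES: dict = {
    "VISa/am": _step(0.0, 0.4, 8.0),
    "CA1": _bump(0.10, 0.05, 12.0),
    "DG": _ramp(1.0, 8.0),
    "LP": _step(0.0, 1.0, 6.0),
    "PO": _bump(0.35, 0.12, 10.0),
}


@dataclass
class SynthConfig:
    """Study conditions for the multi-lab population generator.

    Defaults mirror the study design: 10 labs, 4 mice per lab, one
    repeated-site insertion per mouse, ~20 units in each of the five
    target regions, 400-trial behavioral sessions, and a mean reaction
    time of 0.15 s. ``lab_effects`` maps a lab name to additive shifts on
    named features (``firing_rate`` in spikes/s, ``amplitude`` in uV,
    ``ap_rms`` in uV, ``lfp_power`` in dB); absent, labs are exchangeable.
    """

    seed: int = 0
    n_labs: int = 10
    mice_per_lab: int = 4
    sessions_per_mouse: int = 1
    units_per_region: dict = field(
        default_factory=lambda: {r: 20 for r in REGIONS}
    )
    base_rate: float = 10.0          # spikes/s
    refractory: float = 0.002        # s
    contamination: float = 0.0       # fraction of spikes from other neurons
    amp_mean: float = 150.0          # uV
    amp_sd: float = 30.0             # uV across units
    amp_truncation: Optional[float] = None  # uV detection floor, or None
    lab_effects: Optional[dict] = None
    n_trials: int = 400
    rt_mean: float = 0.15            # s
    n_channels: int = 384

    def __post_init__(self) -> None:
        if not 0.0 <= self.contamination < 1.0:
            raise ValueError("contamination must be in [0, 1)")
        if self.refractory <= 0:
            raise ValueError("refractory must be positive")
        for name in ("n_labs", "mice_per_lab", "sessions_per_mouse", "n_trials"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if any(v < 0 for v in self.units_per_region.values()):
            raise ValueError("unit counts must be non-negative")


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _homogeneous_poisson(rate: float, duration: float, rng: np.random.Generator) -> np.ndarray:
    n = rng.poisson(rate * duration)
    return np.sort(rng.uniform(0.0, duration, n))


def _enforce_refractory(times: np.ndarray, refractory: float) -> np.ndarray:
    """Thin a train by deleting any spike closer than ``refractory`` to its
    predecessor, repeating until no violation remains."""
    while len(times) > 1:
        bad = np.diff(times) < refractory
        if not bad.any():
            break
        times = np.delete(times, np.nonzero(bad)[0] + 1)
    return times


def gen_spike_train(
    rate: float,
    duration: float,
    refractory: float = 0.002,
    contamination: float = 0.0,
    seed=None,
) -> np.ndarray:
    """Poisson spike train with an absolute refractory period and an
    optional contaminating fraction.

    The clean process is homogeneous Poisson at ``rate`` thinned to respect
    the refractory period; contamination is an independent homogeneous
    Poisson process at ``contamination / (1 - contamination) * rate`` with
    no refractory constraint, merged in — the model under which
    refractory-violation contamination estimates are derived.
    """
    if rate < 0 or duration <= 0:
        raise ValueError("rate must be >= 0 and duration > 0")
    if not 0.0 <= contamination < 1.0:
        raise ValueError("contamination must be in [0, 1)")
    if refractory <= 0:
        raise ValueError("refractory must be positive")
    rng = _as_rng(seed)
    clean = _enforce_refractory(_homogeneous_poisson(rate, duration, rng), refractory)
    if contamination > 0:
        contam = _homogeneous_poisson(
            rate * contamination / (1.0 - contamination), duration, rng
        )
        clean = np.sort(np.concatenate([clean, contam]))
    return np.unique(clean)


def gen_event_locked_train(
    base_rate: float,
    events: np.ndarray,
    template: Callable[[np.ndarray], np.ndarray],
    duration: float,
    refractory: float = 0.002,
    contamination: float = 0.0,
    seed=None,
) -> np.ndarray:
    """Inhomogeneous Poisson train whose rate is ``base_rate`` plus an
    event-locked template response, generated by thinning.

    ``template(dt)`` gives the added rate as a function of time since the
    most recent event; it must be non-negative with bounded support.
    """
    if base_rate < 0 or duration <= 0:
        raise ValueError("base_rate must be >= 0 and duration > 0")
    rng = _as_rng(seed)
    events = np.sort(np.asarray(events, dtype=float))
    grid = np.linspace(-0.5, 2.0, 501)
    peak = float(np.max(template(grid))) if len(events) else 0.0
    rmax = base_rate + max(peak, 0.0)
    if rmax == 0:
        return np.empty(0)
    cand = _homogeneous_poisson(rmax, duration, rng)
    if len(events):
        idx = np.searchsorted(events, cand, side="right") - 1
        dt = np.where(idx >= 0, cand - events[np.clip(idx, 0, None)], np.inf)
        lam = base_rate + np.where(np.isfinite(dt), template(dt), 0.0)
    else:
        lam = np.full(len(cand), base_rate)
    keep = rng.uniform(0.0, rmax, len(cand)) < lam
    times = _enforce_refractory(cand[keep], refractory)
    if contamination > 0:
        mean_rate = max(len(times) / duration, 1e-9)
        contam = _homogeneous_poisson(
            mean_rate * contamination / (1.0 - contamination), duration, rng
        )
        times = np.sort(np.concatenate([times, contam]))
    return np.unique(times)


def gen_amplitudes(
    n: int,
    mean: float,
    sd: float,
    truncation: Optional[float] = None,
    seed=None,
) -> np.ndarray:
    """``n`` Gaussian amplitude draws (uV); draws below ``truncation`` are
    discarded (not redrawn), emulating a detection floor, so the returned
    vector may be shorter than ``n``."""
    if n < 0 or sd < 0:
        raise ValueError("n and sd must be non-negative")
    rng = _as_rng(seed)
    amps = rng.normal(mean, sd, n)
    if truncation is not None:
        amps = amps[amps >= truncation]
    return amps


def gen_trial_table(
    n_trials: int,
    rt_mean: float = 0.15,
    seed=None,
    performance: float = 0.8,
    unbiased_trials: int = 90,
) -> pd.DataFrame:
    """Trial table with biased-block structure and log-normal reaction times.

    The first ``unbiased_trials`` trials draw the stimulus side with equal
    probability; subsequent blocks of 20-100 trials alternate between
    20:80 and 80:20 left:right regimes. Reaction times are log-normal with
    mean ``rt_mean`` (the split point between fast and slow trials in the
    embedding analyses), so both fast and slow trials occur. Event times
    satisfy ``stim_on < first_move < feedback_time`` on every trial.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = _as_rng(seed)

    p_left = np.empty(n_trials)
    i = min(unbiased_trials, n_trials)
    p_left[:i] = 0.5
    regimes = (0.2, 0.8) if rng.uniform() < 0.5 else (0.8, 0.2)
    block = 0
    while i < n_trials:
        block_len = int(rng.integers(20, 101))
        j = min(i + block_len, n_trials)
        p_left[i:j] = regimes[block % 2]
        block += 1
        i = j

    left = rng.uniform(size=n_trials) < p_left
    side = np.where(left, "left", "right")
    contrast = rng.choice(CONTRAST_SET, size=n_trials)

    sigma = 0.6
    mu = math.log(rt_mean) - sigma**2 / 2.0
    rt = rng.lognormal(mu, sigma, n_trials)

    correct = rng.uniform(size=n_trials) < performance
    choice = np.where(correct, side, np.where(left, "right", "left"))
    feedback_type = np.where(choice == side, "reward", "error")

    iti = rng.uniform(1.0, 2.0, n_trials)
    move_to_feedback = rng.uniform(0.05, 0.15, n_trials)
    stim_on = np.empty(n_trials)
    t = 2.0
    for k in range(n_trials):
        stim_on[k] = t
        t = stim_on[k] + rt[k] + move_to_feedback[k] + iti[k]
    first_move = stim_on + rt
    feedback_time = first_move + move_to_feedback

    return pd.DataFrame(
        {
            "stim_on": stim_on,
            "contrast": contrast,
            "side": side,
            "block_p_left": p_left,
            "first_move": first_move,
            "choice": choice,
            "feedback_type": feedback_type,
            "feedback_time": feedback_time,
            "reaction_time": rt,
        }
    )


def _lab_shift(config: SynthConfig, lab: str, feature: str) -> float:
    if not config.lab_effects:
        return 0.0
    return float(config.lab_effects.get(lab, {}).get(feature, 0.0))


def _make_session(
    config: SynthConfig,
    lab: str,
    subject: str,
    session_id: str,
    rng: np.random.Generator,
) -> SessionRecord:
    trials = gen_trial_table(config.n_trials, config.rt_mean, seed=rng)
    duration = float(trials["feedback_time"].iloc[-1] + 2.0)
    events = trials["first_move"].to_numpy()

    rate_shift = _lab_shift(config, lab, "firing_rate")
    amp_shift = _lab_shift(config, lab, "amplitude")

    units = []
    uid = 0
    for region in REGIONS:
        template = REGION_TEMPLATES[region]
        z0 = REGION_DEPTHS[region]
        for _ in range(config.units_per_region.get(region, 0)):
            base = max(
                0.1,
                config.base_rate * rng.lognormal(0.0, 0.3) + rate_shift,
            )
            times = gen_event_locked_train(
                base,
                events,
                template,
                duration,
                refractory=config.refractory,
                contamination=config.contamination,
                seed=rng,
            )
            unit_amp = rng.normal(config.amp_mean + amp_shift, config.amp_sd)
            amps = rng.normal(unit_amp, 0.05 * abs(unit_amp) + 1.0, len(times))
            if config.amp_truncation is not None:
                keep = amps >= config.amp_truncation
                times, amps = times[keep], amps[keep]
            units.append(
                UnitRecord(
                    unit_id=uid,
                    spike_times=times,
                    amplitudes=amps,
                    position=np.array(
                        [
                            rng.normal(2000.0, 150.0),
                            rng.normal(-2240.0, 150.0),
                            rng.normal(z0, 120.0),
                        ]
                    ),
                    ptt_duration=float(np.clip(rng.normal(0.45, 0.1), 0.1, 1.2)),
                    region=region,
                )
            )
            uid += 1

    n_ch = config.n_channels
    depths = np.arange(n_ch) * 10.0
    ap_rms = rng.normal(20.0 + _lab_shift(config, lab, "ap_rms"), 3.0, n_ch)
    freqs = np.arange(1.0, 101.0)
    psd_db = rng.normal(-120.0 + _lab_shift(config, lab, "lfp_power"), 0.5, (n_ch, len(freqs)))
    # Elevated 20-80 Hz power on channels passing through the dentate gyrus.
    dg_channels = np.abs(depths - REGION_DEPTHS["DG"]) < 200.0
    band = (freqs >= 20) & (freqs <= 80)
    psd_db[np.ix_(dg_channels, band)] += 15.0

    per_region = n_ch // len(REGIONS)
    n_channels_per_region = {r: per_region for r in REGIONS}

    # Histology angle scatters a few degrees around the planned insertion
    # axis (small random tilt, not a re-drawn azimuth).
    tilt = rng.normal(0.0, 0.1, 2)  # radians, AP and ML components
    hist_dir = PLANNED_REPEATED_SITE.direction + np.array([tilt[0], tilt[1], 0.0])
    histology = Trajectory(
        entry=PLANNED_REPEATED_SITE.entry + np.array([*rng.normal(0.0, 250.0, 2), 0.0]),
        direction=hist_dir,
        source="histology",
    )
    micro = Trajectory(
        entry=PLANNED_REPEATED_SITE.entry + np.array([*rng.normal(0.0, 80.0, 2), 0.0]),
        direction=PLANNED_REPEATED_SITE.direction,
        source="micromanipulator",
    )

    return SessionRecord(
        lab_id=lab,
        subject_id=subject,
        session_id=session_id,
        units=units,
        n_channels_per_region=n_channels_per_region,
        channel_depths=depths,
        ap_rms_per_channel=ap_rms,
        lfp_psd=psd_db,
        lfp_freqs=freqs,
        trial_table=trials,
        duration=duration,
        planned_traj=PLANNED_REPEATED_SITE,
        micro_traj=micro,
        histology_traj=histology,
        exclusion_ledger={},
    )


def gen_multilab_population(config: SynthConfig) -> list:
    """Hierarchical lab -> mouse -> session population of synthetic
    recordings.

    With ``lab_effects`` absent, per-mouse feature values are exchangeable
    across labs (the reproducibility null); with shifts set, the named
    lab's features are displaced additively (the alternative). Each unit
    carries an event-locked response drawn from its region's template.
    """
    base = np.random.SeedSequence(config.seed)
    n_sessions = config.n_labs * config.mice_per_lab * config.sessions_per_mouse
    children = base.spawn(max(n_sessions, 1))
    sessions = []
    k = 0
    for li in range(config.n_labs):
        lab = f"lab_{li:02d}"
        for mi in range(config.mice_per_lab):
            subject = f"{lab}_mouse_{mi:02d}"
            for si in range(config.sessions_per_mouse):
                rng = np.random.default_rng(children[k])
                k += 1
                sessions.append(
                    _make_session(config, lab, subject, f"{subject}_s{si:02d}", rng)
                )
    return sessions


def gen_lab_feature_values(
    n_labs: int,
    mice_per_lab: int,
    seed=None,
    lab_shifts: Optional[dict] = None,
    mean: float = 0.0,
    sd: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """One Gaussian feature value per mouse across labs — light feedstock
    for permutation-test calibration and power analysis.

    Returns ``(values, labels)``. With ``lab_shifts`` absent the labs are
    exchangeable (the null); ``lab_shifts`` maps lab index or name to an
    additive displacement.
    """
    rng = _as_rng(seed)
    values = rng.normal(mean, sd, n_labs * mice_per_lab)
    labels = np.repeat([f"lab_{i:02d}" for i in range(n_labs)], mice_per_lab)
    if lab_shifts:
        for key, shift in lab_shifts.items():
            name = f"lab_{key:02d}" if isinstance(key, (int, np.integer)) else key
            values[labels == name] += shift
    return values, labels
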