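"""On-disk data model for one-session electrophysiology summaries.

A session directory holds columnar tables (CSV or Parquet) for units,
spikes, channels, the LFP power spectrum and the trial table, plus a JSON
metadata file carrying identifiers, trajectories and the QC exclusion
ledger. The layout follows a one-object-one-file convention.

The module also implements the ordered session exclusion cascade used to
decide which recordings enter cross-lab analyses.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .geometry import Trajectory

__all__ = [
    "FormatError",
    "UnitRecord",
    "SessionRecord",
    "CriterionResult",
    "QCReport",
    "REGIONS",
    "CASCADE_CRITERIA",
    "validate_trial_table",
    "write_session",
    "read_session",
    "exclusion_cascade",
]

#: The five target regions of the repeated-site insertion.
REGIONS = ("VISa/am", "CA1", "DG", "LP", "PO")

#: Fixed order in which session exclusion criteria are applied. A session is
#: tallied against the first criterion it fails.
CASCADE_CRITERIA = (
    "hardware",          # incomplete acquisition: hardware failure
    "histology",         # incomplete acquisition: missing histology
    "drift",             # visually assessed RIGOR criteria
    "noisy_channels",
    "artefacts",
    "epileptiform",
    "low_yield",         # computed RIGOR criteria
    "noise_level",
    "behavior",          # >= min_trials completed trials
    "lab_session_count", # >= min sessions per lab for across-lab tests
)

TRIAL_COLUMNS = (
    "stim_on",
    "contrast",
    "side",
    "block_p_left",
    "first_move",
    "choice",
    "feedback_type",
    "feedback_time",
    "reaction_time",
)


class FormatError(ValueError):
    """A session directory is missing a file or a file is malformed."""


@dataclass
class UnitRecord:
    """One sorted unit: spike train, amplitudes, position and waveform shape."""

    unit_id: int
    spike_times: np.ndarray        # seconds from session start, sorted
    amplitudes: np.ndarray         # uV, one per spike
    position: np.ndarray           # (x, y, z) um in the atlas frame
    ptt_duration: float            # peak-to-trough duration, ms
    region: str
    qc_flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        self.position = np.asarray(self.position, dtype=float)
        if len(self.spike_times) != len(self.amplitudes):
            raise ValueError("spike_times and amplitudes must have equal length")
        if len(self.spike_times) and (
            np.any(np.diff(self.spike_times) <= 0) or self.spike_times[0] < 0
        ):
            raise ValueError("spike_times must be strictly increasing and >= 0")

    @property
    def n_spikes(self) -> int:
        return len(self.spike_times)


@dataclass
class SessionRecord:
    """One probe insertion: units, channel summaries, trials and metadata."""

    lab_id: str
    subject_id: str
    session_id: str
    units: list
    n_channels_per_region: dict
    channel_depths: np.ndarray      # um along the probe
    ap_rms_per_channel: np.ndarray  # uV
    lfp_psd: np.ndarray             # channels x frequencies, dB
    lfp_freqs: np.ndarray           # Hz
    trial_table: Optional[pd.DataFrame]
    duration: float                 # seconds of recording
    planned_traj: Optional[Trajectory] = None
    micro_traj: Optional[Trajectory] = None
    histology_traj: Optional[Trajectory] = None
    exclusion_ledger: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.channel_depths = np.asarray(self.channel_depths, dtype=float)
        self.ap_rms_per_channel = np.asarray(self.ap_rms_per_channel, dtype=float)
        self.lfp_psd = np.asarray(self.lfp_psd, dtype=float)
        self.lfp_freqs = np.asarray(self.lfp_freqs, dtype=float)

    @property
    def n_trials(self) -> int:
        return 0 if self.trial_table is None else len(self.trial_table)


@dataclass
class CriterionResult:
    """Measured value, threshold and verdict for one QC criterion."""

    name: str
    value: float
    threshold: float
    passed: bool
    reason: Optional[str] = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class QCReport:
    """Collection of criterion results; passes overall iff all criteria pass."""

    criteria: dict = field(default_factory=dict)

    def add(self, result: CriterionResult) -> None:
        self.criteria[result.name] = result

    @property
    def overall_pass(self) -> bool:
        return all(c.passed for c in self.criteria.values())

    def to_dict(self) -> dict:
        return {
            "criteria": {k: v.to_dict() for k, v in self.criteria.items()},
            "overall_pass": self.overall_pass,
        }


def validate_trial_table(trials: pd.DataFrame) -> None:
    """Check the per-trial invariants: columns present, event order, rt > 0."""
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise FormatError(f"trial table is missing columns: {missing}")
    if len(trials) == 0:
        return
    if not (
        (trials["stim_on"] < trials["first_move"]).all()
        and (trials["first_move"] < trials["feedback_time"]).all()
    ):
        raise FormatError("trial events must satisfy stim_on < first_move < feedback_time")
    if not (trials["reaction_time"] > 0).all():
        raise FormatError("reaction_time must be positive")


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _traj_to_dict(traj: Optional[Trajectory]) -> Optional[dict]:
    if traj is None:
        return None
    return {
        "entry": traj.entry.tolist(),
        "direction": traj.direction.tolist(),
        "source": traj.source,
    }


def _traj_from_dict(d: Optional[dict]) -> Optional[Trajectory]:
    if d is None:
        return None
    return Trajectory(entry=d["entry"], direction=d["direction"], source=d["source"])


def _write_table(df: pd.DataFrame, path: Path, fmt: str) -> None:
    if fmt == "parquet":
        df.to_parquet(path.with_suffix(".parquet"), index=False)
    else:
        df.to_csv(path.with_suffix(".csv"), index=False)


def _read_table(stem: Path, required: tuple = ()) -> pd.DataFrame:
    for suffix, reader in ((".csv", pd.read_csv), (".parquet", pd.read_parquet)):
        path = stem.with_suffix(suffix)
        if path.exists():
            try:
                df = reader(path)
            except Exception as exc:  # malformed file
                raise FormatError(f"could not parse {path.name}: {exc}") from exc
            missing = [c for c in required if c not in df.columns]
            if missing:
                raise FormatError(f"{path.name} is missing columns: {missing}")
            return df
    raise FormatError(f"missing table {stem.name}.csv/.parquet in {stem.parent}")


def write_session(session: SessionRecord, path: str | Path, fmt: str = "csv") -> Path:
    """Write one session directory; the inverse of :func:`read_session`."""
    if fmt not in ("csv", "parquet"):
        raise ValueError("fmt must be 'csv' or 'parquet'")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    meta = {
        "lab_id": session.lab_id,
        "subject_id": session.subject_id,
        "session_id": session.session_id,
        "duration": session.duration,
        "n_channels_per_region": session.n_channels_per_region,
        "exclusion_ledger": session.exclusion_ledger,
        "trajectories": {
            "planned": _traj_to_dict(session.planned_traj),
            "micromanipulator": _traj_to_dict(session.micro_traj),
            "histology": _traj_to_dict(session.histology_traj),
        },
        "has_trials": session.trial_table is not None,
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=2))

    units_df = pd.DataFrame(
        {
            "unit_id": [u.unit_id for u in session.units],
            "x": [u.position[0] for u in session.units],
            "y": [u.position[1] for u in session.units],
            "z": [u.position[2] for u in session.units],
            "ptt_duration": [u.ptt_duration for u in session.units],
            "region": [u.region for u in session.units],
            "qc_flags": [json.dumps(u.qc_flags) for u in session.units],
        }
    )
    _write_table(units_df, path / "units", fmt)

    if session.units:
        spikes_df = pd.DataFrame(
            {
                "unit_id": np.concatenate(
                    [np.full(u.n_spikes, u.unit_id, dtype=int) for u in session.units]
                ),
                "time": np.concatenate([u.spike_times for u in session.units]),
                "amplitude": np.concatenate([u.amplitudes for u in session.units]),
            }
        )
    else:
        spikes_df = pd.DataFrame({"unit_id": [], "time": [], "amplitude": []})
    _write_table(spikes_df, path / "spikes", fmt)

    channels_df = pd.DataFrame(
        {"depth": session.channel_depths, "ap_rms": session.ap_rms_per_channel}
    )
    _write_table(channels_df, path / "channels", fmt)

    lfp_df = pd.DataFrame(
        session.lfp_psd.T,
        columns=[f"ch{idx:03d}" for idx in range(session.lfp_psd.shape[0])],
    )
    lfp_df.insert(0, "frequency", session.lfp_freqs)
    _write_table(lfp_df, path / "lfp_psd", fmt)

    if session.trial_table is not None:
        _write_table(session.trial_table, path / "trials", fmt)
    return path


def read_session(path: str | Path) -> SessionRecord:
    """Read a session directory written by :func:`write_session`."""
    path = Path(path)
    meta_path = path / "meta.json"
    if not meta_path.exists():
        raise FormatError(f"missing meta.json in {path}")
    try:
        meta = json.loads(meta_path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"could not parse meta.json: {exc}") from exc

    units_df = _read_table(
        path / "units",
        required=("unit_id", "x", "y", "z", "ptt_duration", "region"),
    )
    spikes_df = _read_table(path / "spikes", required=("unit_id", "time", "amplitude"))
    channels_df = _read_table(path / "channels", required=("depth", "ap_rms"))
    lfp_df = _read_table(path / "lfp_psd", required=("frequency",))

    spikes_by_unit = dict(tuple(spikes_df.groupby("unit_id", sort=False)))
    units = []
    for row in units_df.itertuples(index=False):
        grp = spikes_by_unit.get(row.unit_id)
        if grp is None:
            times = np.empty(0)
            amps = np.empty(0)
        else:
            times = grp["time"].to_numpy()
            amps = grp["amplitude"].to_numpy()
        units.append(
            UnitRecord(
                unit_id=int(row.unit_id),
                spike_times=times,
                amplitudes=amps,
                position=np.array([row.x, row.y, row.z]),
                ptt_duration=float(row.ptt_duration),
                region=str(row.region),
                qc_flags=json.loads(row.qc_flags) if row.qc_flags else {},
            )
        )

    trials = None
    if meta.get("has_trials", False):
        trials = _read_table(path / "trials", required=TRIAL_COLUMNS)
        validate_trial_table(trials)

    lfp_freqs = lfp_df["frequency"].to_numpy()
    lfp_psd = lfp_df.drop(columns="frequency").to_numpy().T
    trajs = meta.get("trajectories", {})
    return SessionRecord(
        lab_id=meta["lab_id"],
        subject_id=meta["subject_id"],
        session_id=meta["session_id"],
        units=units,
        n_channels_per_region=meta.get("n_channels_per_region", {}),
        channel_depths=channels_df["depth"].to_numpy(),
        ap_rms_per_channel=channels_df["ap_rms"].to_numpy(),
        lfp_psd=lfp_psd,
        lfp_freqs=lfp_freqs,
        trial_table=trials,
        duration=float(meta["duration"]),
        planned_traj=_traj_from_dict(trajs.get("planned")),
        micro_traj=_traj_from_dict(trajs.get("micromanipulator")),
        histology_traj=_traj_from_dict(trajs.get("histology")),
        exclusion_ledger=dict(meta.get("exclusion_ledger", {})),
    )


# ---------------------------------------------------------------------------
# Exclusion cascade
# ---------------------------------------------------------------------------

def exclusion_cascade(
    sessions: list,
    min_trials: int = 400,
    min_sessions_per_lab: int = 3,
) -> tuple[list, dict]:
    """Apply the ordered session-exclusion criteria.

    Each session is tallied against the first criterion it fails, in the
    fixed order of :data:`CASCADE_CRITERIA`: acquisition completeness,
    visually assessed recording quality, computed recording quality, the
    behavioral trial minimum, and finally the per-lab session count needed
    for across-lab comparisons.

    The ledger on each session maps criterion name to a pass/fail boolean
    (missing entries count as passes). The behavior criterion is computed
    from the trial table when one is attached, otherwise taken from the
    ledger. Returns ``(survivors, tally)`` with
    ``len(survivors) + sum(tally.values()) == len(sessions)``.
    """
    tally = {c: 0 for c in CASCADE_CRITERIA}
    remaining = []
    for s in sessions:
        failed = None
        for crit in CASCADE_CRITERIA[:8]:
            if not s.exclusion_ledger.get(crit, True):
                failed = crit
                break
        if failed is None:
            if s.trial_table is not None:
                ok = len(s.trial_table) >= min_trials
            else:
                ok = s.exclusion_ledger.get("behavior", True)
            if not ok:
                failed = "behavior"
        if failed is None:
            remaining.append(s)
        else:
            tally[failed] += 1

    lab_counts: dict = {}
    for s in remaining:
        lab_counts[s.lab_id] = lab_counts.get(s.lab_id, 0) + 1
    survivors = []
    for s in remaining:
        if lab_counts[s.lab_id] >= min_sessions_per_lab:
            survivors.append(s)
        else:
            tally["lab_session_count"] += 1
    return survivors, tally
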