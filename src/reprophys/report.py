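"""Combined RIGOR report for one session: recording-level criteria plus the
per-unit criteria rolled up into region yields.
"""

from __future__ import annotations

import numpy as np

from .io_core import CriterionResult, QCReport, SessionRecord
from .recording_qc import ap_rms_pass, lfp_derivative_pass, lfp_profile_from_psd, yield_metric
from .spike_qc import unit_qc

__all__ = ["session_rigor_report"]

VISUAL_CRITERIA = ("drift", "noisy_channels", "artefacts", "epileptiform")


def session_rigor_report(
    session: SessionRecord,
    yield_threshold: float = 0.1,
    ap_rms_threshold: float = 40.0,
    lfp_deriv_threshold: float = 0.05,
) -> QCReport:
    """Run the whole-recording criteria on one session.

    Unit criteria are computed per unit (stored on each unit's
    ``qc_flags``); the yield criterion then counts QC-passing units per
    channel in each region and passes only when every region with
    channels assigned meets the threshold. Visually assessed criteria are
    read from the exclusion ledger (manual flags), not computed.
    """
    report = QCReport()

    passing_by_region: dict = {}
    for u in session.units:
        uq = unit_qc(u, session.duration)
        u.qc_flags = {k: c.passed for k, c in uq.criteria.items()}
        if uq.overall_pass:
            passing_by_region[u.region] = passing_by_region.get(u.region, 0) + 1

    region_yields = {}
    all_pass = True
    for region, n_ch in session.n_channels_per_region.items():
        if n_ch <= 0:
            continue
        y, ok = yield_metric(passing_by_region.get(region, 0), n_ch, yield_threshold)
        region_yields[region] = y
        all_pass = all_pass and ok
    report.add(
        CriterionResult(
            name="yield",
            value=min(region_yields.values()) if region_yields else np.nan,
            threshold=yield_threshold,
            passed=bool(region_yields) and all_pass,
            reason=None if region_yields else "no channel-region map",
        )
    )

    med, ok = ap_rms_pass(session.ap_rms_per_channel, ap_rms_threshold)
    report.add(CriterionResult("noise_level", med, ap_rms_threshold, ok))

    profile = lfp_profile_from_psd(
        session.lfp_psd, session.lfp_freqs, session.channel_depths
    )
    deriv, ok = lfp_derivative_pass(profile, lfp_deriv_threshold)
    report.add(CriterionResult("lfp_derivative", deriv, lfp_deriv_threshold, ok))

    for crit in VISUAL_CRITERIA:
        passed = bool(session.exclusion_ledger.get(crit, True))
        report.add(
            CriterionResult(
                name=crit,
                value=float(passed),
                threshold=1.0,
                passed=passed,
                reason="manually assessed flag",
            )
        )
    return report
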