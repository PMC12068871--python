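"""Single-unit quality metrics on three synthetic units.

Builds a clean unit, a heavily contaminated unit, and a unit whose
amplitude histogram is truncated by a detection threshold, then runs the
three unit-level criteria: sliding refractory-period confidence,
amplitude-cutoff detection, and the median-amplitude threshold.
"""

import numpy as np

from reprophys import (
    UnitRecord,
    gen_amplitudes,
    gen_spike_train,
    unit_qc,
)

DURATION = 600.0  # seconds of recording


def make_unit(contamination=0.0, truncation=None, amp_mean=120.0, seed=0):
    times = gen_spike_train(20.0, DURATION, contamination=contamination, seed=seed)
    amps = gen_amplitudes(len(times), amp_mean, 15.0, truncation=truncation, seed=seed)
    n = min(len(times), len(amps))
    return UnitRecord(0, times[:n], amps[:n], np.zeros(3), 0.5, "LP")


for label, unit in [
    ("clean unit", make_unit()),
    ("30% contaminated", make_unit(contamination=0.3, seed=1)),
    ("amplitude-truncated", make_unit(truncation=120.0, seed=2)),
    ("low amplitude (40 uV)", make_unit(amp_mean=40.0, seed=3)),
]:
    report = unit_qc(unit, DURATION)
    verdict = "PASS" if report.overall_pass else "FAIL"
    print(f"\n{label}: {verdict}")
    for name, crit in report.criteria.items():
        print(f"  {name:20s} value={crit.value:8.3f}  passed={crit.passed}")

print(
    "\nThe refractory value is the best confidence (over refractory lengths)"
    "\nthat contamination is below 10%; it must exceed 0.9. The cutoff value"
    "\nis how many SDs the lowest amplitude bin sits above the high tail"
    "\n(must be < 5), and the median amplitude must exceed 50 uV."
)
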