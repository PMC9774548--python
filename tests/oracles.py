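"""Independent brute-force oracles used by the test suite.

These re-derive expected results by literal rule application, structured
differently from the library code so they cannot share its bugs.
"""

from __future__ import annotations

import math


def oracle_segment(t, x, y, dispersion=37.0, min_samples=3, rate=60.0, gap_tol=2.0):
    """Literal lead-sample rule: walk the timeline; the first measurement is
    a lead; every following measurement within ``dispersion`` of the lead
    joins the candidate fixation until one falls outside (or the recording
    gaps), and that measurement starts the next candidate.

    Returns a list of (lead, start, end) index triples of the runs with at
    least ``min_samples`` members.
    """
    interval = 1000.0 / rate
    runs = []
    i, n = 0, len(t)
    while i < n:
        lead = i
        j = i + 1
        while j < n:
            whole_gaps = round((t[j] - t[j - 1]) / interval)
            dist = math.hypot(x[j] - x[lead], y[j] - y[lead])
            if whole_gaps > gap_tol or dist > dispersion:
                break
            j += 1
        if j - i >= min_samples:
            runs.append((lead, i, j - 1))
        i = j
    return runs


def oracle_aoi_tally(t, x, y, aois, dispersion=37.0, min_samples=3, rate=60.0):
    """Per-AOI fixation count and total time from first principles."""
    runs = oracle_segment(t, x, y, dispersion, min_samples, rate)
    out = {a.name: {"n": 0, "ms": 0.0} for a in aois}
    for _, s, e in runs:
        touched = set()
        for k in range(s, e + 1):
            for a in aois:
                if a.x0 <= x[k] < a.x1 and a.y0 <= y[k] < a.y1:
                    touched.add(a.name)
        dur = (e - s + 1) * 1000.0 / rate
        for name in touched:
            out[name]["n"] += 1
            out[name]["ms"] += dur
    return out
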