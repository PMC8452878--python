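"""Readers and writers for trace CSVs and cohort JSON.

Trace CSV schema: columns ``time_s, right_mm, left_mm, illumination,
quality``; blink/missing samples may carry empty diameter cells.
Validation reports malformed rows with their line numbers.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np

from .protocol import Illumination
from .trace import QUALITY_OK, PupilTrace, TraceError, _QUALITIES

TRACE_COLUMNS = ["time_s", "right_mm", "left_mm", "illumination", "quality"]


def write_trace(trace: PupilTrace, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["# sample_rate_hz", repr(float(trace.sample_rate_hz))])
        w.writerow(TRACE_COLUMNS)
        for i in range(len(trace)):
            r, l = trace.right_mm[i], trace.left_mm[i]
            w.writerow(
                [
                    repr(float(trace.time_s[i])),
                    "" if np.isnan(r) else repr(float(r)),
                    "" if np.isnan(l) else repr(float(l)),
                    trace.illumination[i],
                    trace.quality[i],
                ]
            )


def read_trace(path: str | Path) -> PupilTrace:
    """Read and validate a trace CSV.

    Raises TraceError naming the first offending line for malformed rows,
    non-monotone timestamps or unknown labels.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if not rows:
        raise TraceError(f"{path}: empty file")
    idx = 0
    sample_rate = None
    if rows[0] and rows[0][0].startswith("#"):
        try:
            sample_rate = float(rows[0][1])
        except (IndexError, ValueError) as err:
            raise TraceError(f"{path}:1: malformed sample-rate header") from err
        idx = 1
    if idx >= len(rows) or rows[idx] != TRACE_COLUMNS:
        raise TraceError(
            f"{path}:{idx + 1}: header must be {','.join(TRACE_COLUMNS)}"
        )
    time_s, right, left, ill, qual = [], [], [], [], []
    for lineno, row in enumerate(rows[idx + 1 :], start=idx + 2):
        if not row:
            continue
        if len(row) != 5:
            raise TraceError(f"{path}:{lineno}: expected 5 columns, got {len(row)}")
        t_s, r_s, l_s, il, q = row
        try:
            t = float(t_s)
        except ValueError as err:
            raise TraceError(f"{path}:{lineno}: bad time {t_s!r}") from err
        if time_s and t <= time_s[-1]:
            raise TraceError(f"{path}:{lineno}: time_s not strictly increasing")
        if il not in {i.value for i in Illumination}:
            raise TraceError(f"{path}:{lineno}: unknown illumination label {il!r}")
        if q not in _QUALITIES:
            raise TraceError(f"{path}:{lineno}: unknown quality flag {q!r}")
        try:
            r = float(r_s) if r_s else float("nan")
            l = float(l_s) if l_s else float("nan")
        except ValueError as err:
            raise TraceError(f"{path}:{lineno}: bad diameter value") from err
        if q == QUALITY_OK and (np.isnan(r) or np.isnan(l)):
            raise TraceError(f"{path}:{lineno}: ok sample with missing diameter")
        time_s.append(t)
        right.append(r)
        left.append(l)
        ill.append(il)
        qual.append(q)
    if not time_s:
        raise TraceError(f"{path}: no data rows")
    if sample_rate is None:
        sample_rate = (
            (len(time_s) - 1) / (time_s[-1] - time_s[0]) if len(time_s) > 1 else 1.0
        )
    return PupilTrace(
        sample_rate_hz=sample_rate,
        time_s=np.array(time_s),
        right_mm=np.array(right),
        left_mm=np.array(left),
        illumination=np.array(ill, dtype=object),
        quality=np.array(qual, dtype=object),
    )
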