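"""SEC-SAXS series: intensity traces, buffer subtraction, rolling analysis.

A series is an ordered list of frames (profiles on one q grid) indexed by
acquisition order.  The standard workflow: plot an intensity trace to find
the elution peak, mark a buffer range, subtract the averaged buffer from
every frame, then step a window along the subtracted frames computing
Rg/I(0) (automatic Guinier) and molecular weight (volume of correlation,
which needs no concentration) per window.  Window results are assigned to
the window's central frame.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field

import numpy as np

from . import ops
from .core import ProfileError, ScatteringProfile, HistoryRecord
from .guinier import auto_guinier
from .molweight import vc_mw

__all__ = [
    "SECSeries",
    "make_series",
    "intensity_trace",
    "rolling_analysis",
    "extract",
    "save_series",
    "load_series",
    "export_series_csv",
    "SERIES_CSV_COLUMNS",
]

SERIES_FORMAT_VERSION = 1

# Exported per-frame columns, in order: the intensity traces, the frame
# index, the rolling structural parameters and the source filename.
SERIES_CSV_COLUMNS = [
    "total_intensity",
    "average_intensity",
    "intensity_at_q",
    "frame_number",
    "rg",
    "rg_uncertainty",
    "mw",
    "i0",
    "i0_uncertainty",
    "filename",
]


@dataclass
class SECSeries:
    profiles: list
    frame_numbers: list
    filenames: list = field(default_factory=list)
    buffer_ranges: list = field(default_factory=list)   # inclusive (a, b) pairs
    window: int | None = None
    subtracted: list | None = None
    results: list | None = None  # per-frame dicts or None

    def __len__(self) -> int:
        return len(self.profiles)

    @property
    def q(self) -> np.ndarray:
        return self.profiles[0].q


def make_series(profiles, filenames=None) -> SECSeries:
    """Build a series from >= 2 profiles sharing one q grid; frames are
    numbered 0..N-1 in input order."""
    profiles = list(profiles)
    if len(profiles) < 2:
        raise ValueError("a series needs at least 2 profiles")
    ops._check_grids(profiles)
    return SECSeries(
        profiles=profiles,
        frame_numbers=list(range(len(profiles))),
        filenames=list(filenames) if filenames else [],
    )


def intensity_trace(series: SECSeries, mode: str = "total", q_value: float | None = None):
    """Per-frame intensity: 'total' (sum over q), 'mean', or 'at_q' (the grid
    point nearest q_value; ties go to the lower index)."""
    if mode == "total":
        return np.array([p.intensity.sum() for p in series.profiles])
    if mode == "mean":
        return np.array([p.intensity.mean() for p in series.profiles])
    if mode == "at_q":
        if q_value is None:
            raise ValueError("mode 'at_q' requires q_value")
        q = series.q
        if q_value < q[0] or q_value > q[-1]:
            raise ValueError(f"q_value {q_value} outside grid range [{q[0]}, {q[-1]}]")
        idx = int(np.argmin(np.abs(q - q_value)))  # argmin ties -> lower index
        return np.array([p.intensity[idx] for p in series.profiles])
    raise ValueError(f"unknown trace mode {mode!r}")


def _validate_ranges(ranges, n: int) -> list:
    if not ranges:
        raise ValueError("at least one buffer range is required")
    norm = []
    for a, b in ranges:
        a, b = int(a), int(b)
        if not (0 <= a <= b < n):
            raise ValueError(f"range ({a}, {b}) outside frames [0, {n - 1}]")
        norm.append((a, b))
    norm.sort()
    for (a1, b1), (a2, b2) in zip(norm[:-1], norm[1:]):
        if a2 <= b1:
            raise ValueError(f"overlapping buffer ranges ({a1},{b1}) and ({a2},{b2})")
    return norm


def _range_frames(ranges) -> list:
    frames = []
    for a, b in ranges:
        frames.extend(range(a, b + 1))
    return frames


def rolling_analysis(
    series: SECSeries,
    buffer_ranges,
    window: int,
    molecule: str = "protein",
    qmax_cut: float | None = None,
) -> SECSeries:
    """Buffer-subtract every frame, then compute windowed Rg/I(0)/MW.

    All frames in `buffer_ranges` (inclusive, disjoint) are pooled into one
    averaged buffer which is subtracted from every frame.  A window of
    `window` frames steps along the subtracted series one frame at a time;
    each window is averaged, auto-Guinier fitted, and (when the fit is
    valid) given a volume-of-correlation MW.  The record lands on the
    window's central frame (start + window // 2); frames never at a window
    center carry no record.
    """
    n = len(series)
    window = int(window)
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > n:
        raise ValueError(f"window {window} exceeds series length {n}")
    ranges = _validate_ranges(buffer_ranges, n)
    buf_frames = _range_frames(ranges)
    buf_profiles = [series.profiles[f] for f in buf_frames]
    buffer = buf_profiles[0].copy(name="buffer") if len(buf_profiles) == 1 \
        else ops.average(buf_profiles)
    buffer.name = "buffer_average"

    series.subtracted = [ops.subtract(p, buffer) for p in series.profiles]
    series.buffer_ranges = ranges
    series.window = window

    results: list = [None] * n
    for start in range(0, n - window + 1):
        win = series.subtracted[start:start + window]
        avg = win[0] if window == 1 else ops.average(win)
        record = {"valid": False, "rg": None, "rg_err": None,
                  "i0": None, "i0_err": None, "mw": None}
        try:
            fit = auto_guinier(avg, store=False)
        except (ValueError, ProfileError):
            fit = None
        if fit is not None and fit.valid:
            record.update(valid=True, rg=fit.rg, rg_err=fit.rg_err,
                          i0=fit.i0, i0_err=fit.i0_err)
            try:
                record["mw"] = vc_mw(avg, fit, qmax_cut=qmax_cut,
                                     molecule=molecule, store=False).mw
            except (ValueError, ZeroDivisionError):
                pass
        results[start + window // 2] = record
    series.results = results
    return series


def extract(series: SECSeries, frame_range, mode: str = "each"):
    """Pull profiles for frames [a, b] inclusive: subtracted when available,
    raw otherwise.  mode='each' returns the list; mode='average' their mean
    (whose history lists every frame in the range)."""
    a, b = int(frame_range[0]), int(frame_range[1])
    n = len(series)
    if not (0 <= a <= b < n):
        raise ValueError(f"range ({a}, {b}) outside frames [0, {n - 1}]")
    source = series.subtracted if series.subtracted is not None else series.profiles
    selected = [source[f] for f in range(a, b + 1)]
    if mode == "each":
        return selected
    if mode == "average":
        return selected[0].copy() if len(selected) == 1 else ops.average(selected)
    raise ValueError(f"unknown extract mode {mode!r}")


def _profile_to_dict(p: ScatteringProfile) -> dict:
    return {
        "name": p.name,
        "q": p.q.tolist(),
        "intensity": p.intensity.tolist(),
        "sigma": p.sigma.tolist(),
        "analysis": p.analysis,
        "history": p.history.to_dict(),
    }


def _profile_from_dict(d: dict) -> ScatteringProfile:
    return ScatteringProfile(
        name=d["name"], q=np.asarray(d["q"]), intensity=np.asarray(d["intensity"]),
        sigma=np.asarray(d["sigma"]), analysis=dict(d.get("analysis", {})),
        history=HistoryRecord.from_dict(d.get("history", {})),
    )


def save_series(series: SECSeries, path) -> None:
    """One JSON document holding the whole series, lossless round trip."""
    from .core import _jsonify

    doc = {
        "format": "saxskit-series",
        "version": SERIES_FORMAT_VERSION,
        "frame_numbers": list(series.frame_numbers),
        "filenames": list(series.filenames),
        "buffer_ranges": [list(r) for r in series.buffer_ranges],
        "window": series.window,
        "profiles": [_profile_to_dict(p) for p in series.profiles],
        "subtracted": [_profile_to_dict(p) for p in series.subtracted]
        if series.subtracted is not None else None,
        "results": _jsonify(series.results),
    }
    with open(str(path), "w", encoding="utf-8") as fh:
        json.dump(doc, fh)


def load_series(path) -> SECSeries:
    with open(str(path), "r", encoding="utf-8") as fh:
        doc = json.load(fh)
    if doc.get("format") != "saxskit-series":
        raise ValueError("not a saxskit series file")
    if doc.get("version") != SERIES_FORMAT_VERSION:
        raise ValueError(f"unsupported series format version {doc.get('version')!r}")
    return SECSeries(
        profiles=[_profile_from_dict(d) for d in doc["profiles"]],
        frame_numbers=list(doc["frame_numbers"]),
        filenames=list(doc.get("filenames", [])),
        buffer_ranges=[tuple(r) for r in doc.get("buffer_ranges", [])],
        window=doc.get("window"),
        subtracted=[_profile_from_dict(d) for d in doc["subtracted"]]
        if doc.get("subtracted") is not None else None,
        results=doc.get("results"),
    )


def export_series_csv(series: SECSeries, path, q_value: float | None = None) -> None:
    """Per-frame CSV: intensity traces, frame number, rolling Rg/MW/I(0)
    with uncertainties, and the source filename (empty when unknown).

    `q_value` selects the q point for the intensity_at_q column; default is
    the middle of the grid.
    """
    if q_value is None:
        q_value = float(series.q[len(series.q) // 2])
    total = intensity_trace(series, "total")
    mean = intensity_trace(series, "mean")
    at_q = intensity_trace(series, "at_q", q_value)
    with open(str(path), "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(SERIES_CSV_COLUMNS)
        for f in range(len(series)):
            rec = series.results[f] if series.results else None
            fname = series.filenames[f] if f < len(series.filenames) else ""

            def cell(key):
                if rec is None or rec.get(key) is None:
                    return ""
                return repr(float(rec[key]))

            writer.writerow([
                repr(float(total[f])),
                repr(float(mean[f])),
                repr(float(at_q[f])),
                series.frame_numbers[f],
                cell("rg"), cell("rg_err"), cell("mw"),
                cell("i0"), cell("i0_err"),
                fname,
            ])
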