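"""Scattering-profile data model and text-based I/O.

A 1D scattering profile is the triple (q, I(q), sigma) produced by radially
averaging a detector image, where q = 4*pi*sin(theta)/lambda is the momentum
transfer in inverse Angstroms.  Profiles are written as plain three-column
``.dat`` files readable by any standard SAXS software; analysis results and
the full derivation history travel in a JSON footer on ``#``-prefixed lines,
which third-party readers treat as comments.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from typing import Any, Iterable, Sequence

import numpy as np

__all__ = [
    "ScatteringProfile",
    "HistoryRecord",
    "ProfileError",
    "read_dat",
    "write_dat",
    "export_analysis_csv",
]


class ProfileError(ValueError):
    """Raised for malformed profiles or profile files."""


@dataclass
class HistoryRecord:
    """Recursive record of how a profile was derived.

    A profile created directly from a file or an image carries a leaf record
    (possibly with operation/parameters describing the integration but no
    parents).  A profile derived from other profiles lists every parent as a
    ``(name, HistoryRecord)`` pair, so the full processing tree survives a
    save/load round trip.
    """

    operation: str = ""
    parameters: dict = field(default_factory=dict)
    parents: list = field(default_factory=list)  # list of (name, HistoryRecord)

    def depth(self) -> int:
        """Number of derivation generations (0 for a leaf)."""
        if not self.parents:
            return 0
        return 1 + max(rec.depth() for _, rec in self.parents)

    def to_dict(self) -> dict:
        return {
            "operation": self.operation,
            "parameters": _jsonify(self.parameters),
            "parents": [[name, rec.to_dict()] for name, rec in self.parents],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HistoryRecord":
        return cls(
            operation=d.get("operation", ""),
            parameters=dict(d.get("parameters", {})),
            parents=[
                (name, cls.from_dict(rec)) for name, rec in d.get("parents", [])
            ],
        )


@dataclass
class ScatteringProfile:
    """One-dimensional scattering profile I(q) with 1-sigma uncertainties.

    Invariants enforced at construction: equal array lengths, strictly
    increasing q, non-negative finite sigma, finite q and intensity.
    """

    name: str
    q: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray
    analysis: dict = field(default_factory=dict)
    history: HistoryRecord = field(default_factory=HistoryRecord)

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        n = len(self.q)
        if len(self.intensity) != n or len(self.sigma) != n:
            raise ProfileError(
                f"array length mismatch: q={n}, I={len(self.intensity)}, "
                f"sigma={len(self.sigma)}"
            )
        if n < 2:
            raise ProfileError("a profile needs at least 2 points")
        if not (
            np.all(np.isfinite(self.q))
            and np.all(np.isfinite(self.intensity))
            and np.all(np.isfinite(self.sigma))
        ):
            raise ProfileError("non-finite values in profile arrays")
        if np.any(np.diff(self.q) <= 0):
            bad = int(np.argmax(np.diff(self.q) <= 0))
            raise ProfileError(f"q must be strictly increasing (violated at index {bad + 1})")
        if np.any(self.sigma < 0):
            raise ProfileError("sigma must be non-negative")

    def __len__(self) -> int:
        return len(self.q)

    def copy(self, name: str | None = None) -> "ScatteringProfile":
        import copy as _copy

        return ScatteringProfile(
            name=name if name is not None else self.name,
            q=self.q.copy(),
            intensity=self.intensity.copy(),
            sigma=self.sigma.copy(),
            analysis=_copy.deepcopy(self.analysis),
            history=_copy.deepcopy(self.history),
        )


def _jsonify(obj: Any) -> Any:
    """Recursively convert numpy scalars/arrays to plain Python types."""
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def read_dat(path) -> ScatteringProfile:
    """Read a three-column (q, I, sigma) whitespace-separated ``.dat`` file.

    Lines starting with ``#`` are comments.  If the trailing comment block
    (the consecutive ``#`` lines after the last data row) concatenates to a
    JSON document with ``analysis``/``history`` keys, the stored analysis
    results and derivation history are restored; otherwise both are empty.

    Raises :class:`ProfileError` for malformed numeric rows (naming the line
    number), fewer than 2 data rows, or a non-increasing q grid.
    """
    path = str(path)
    rows: list[tuple[float, float, float]] = []
    trailing_comments: list[str] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                trailing_comments.append(line.lstrip("#").strip())
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ProfileError(
                    f"{path}:{lineno}: expected 3 columns, got {len(parts)}"
                )
            try:
                rows.append((float(parts[0]), float(parts[1]), float(parts[2])))
            except ValueError as exc:
                raise ProfileError(f"{path}:{lineno}: malformed numeric row: {line!r}") from exc
            trailing_comments = []  # only the block *after* the last data row counts
    if len(rows) < 2:
        raise ProfileError(f"{path}: fewer than 2 data rows")
    arr = np.array(rows, dtype=float)
    analysis: dict = {}
    history = HistoryRecord()
    if trailing_comments:
        try:
            doc = json.loads(" ".join(trailing_comments))
            if isinstance(doc, dict):
                analysis = dict(doc.get("analysis", {}))
                history = HistoryRecord.from_dict(doc.get("history", {}))
        except (json.JSONDecodeError, TypeError):
            warnings.warn(f"{path}: unreadable footer JSON; metadata ignored")
    import os

    name = os.path.splitext(os.path.basename(path))[0]
    return ScatteringProfile(
        name=name, q=arr[:, 0], intensity=arr[:, 1], sigma=arr[:, 2],
        analysis=analysis, history=history,
    )


def write_dat(profile: ScatteringProfile, path) -> None:
    """Write a profile as three-column text with a JSON metadata footer.

    Numbers are printed in scientific notation with 9 significant digits so
    that a read/write round trip preserves them to better than 1e-8 relative.
    """
    footer = json.dumps(
        {"analysis": _jsonify(profile.analysis), "history": profile.history.to_dict()},
        indent=2,
    )
    with open(str(path), "w", encoding="utf-8") as fh:
        for qi, ii, si in zip(profile.q, profile.intensity, profile.sigma):
            fh.write(f"{qi:.8e} {ii:.8e} {si:.8e}\n")
        for line in footer.splitlines():
            fh.write(f"# {line}\n")


# Column layout of the analysis summary CSV.  Cells are left empty when the
# corresponding analysis has not been run on a profile.
_CSV_COLUMNS = [
    "name",
    "rg",
    "rg_err",
    "i0",
    "i0_err",
    "qmin_rg",
    "qmax_rg",
    "r_squared",
    "mw_reference",
    "mw_absolute",
    "mw_porod",
    "mw_vc",
    "vp",
    "vc",
    "dmax",
]


def _fmt(value: Any) -> str:
    if value is None:
        return ""
    if isinstance(value, float) and not np.isfinite(value):
        return ""
    return repr(value) if isinstance(value, float) else str(value)


def analysis_row(profile: ScatteringProfile) -> dict:
    """Flatten a profile's stored analysis results into one summary row."""
    row: dict[str, Any] = {c: None for c in _CSV_COLUMNS}
    row["name"] = profile.name
    g = profile.analysis.get("guinier")
    if g:
        row["rg"] = g.get("rg")
        row["rg_err"] = g.get("rg_err")
        row["i0"] = g.get("i0")
        row["i0_err"] = g.get("i0_err")
        row["qmin_rg"] = g.get("qmin_rg")
        row["qmax_rg"] = g.get("qmax_rg")
        row["r_squared"] = g.get("r_squared")
    mw = profile.analysis.get("molweight", {})
    for method in ("reference", "absolute", "porod", "vc"):
        rec = mw.get(method)
        if rec:
            row[f"mw_{method}"] = rec.get("mw")
            inter = rec.get("intermediates", {})
            if method == "porod":
                row["vp"] = inter.get("vp_corrected", inter.get("vp"))
            if method == "vc":
                row["vc"] = inter.get("vc")
    b = profile.analysis.get("bift")
    if b:
        row["dmax"] = b.get("dmax")
    return row


def export_analysis_csv(profiles: Sequence[ScatteringProfile], path) -> None:
    """Write one analysis summary row per profile as RFC-4180 CSV."""
    if not profiles:
        raise ValueError("no profiles to export")
    with open(str(path), "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CSV_COLUMNS)
        for p in profiles:
            row = analysis_row(p)
            writer.writerow([_fmt(row[c]) for c in _CSV_COLUMNS])
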