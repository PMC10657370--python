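"""Embedded reliability data sets and plain-text sample I/O.

Two classical stress-rupture data sets ship with the package:

``kevlar49``
    Stress-rupture life (in hours, scaled) of 101 Kevlar 49/epoxy strands under
    constant sustained pressure at the 90% stress level, run until all failed
    (Andrews & Herzberg's collection).  The published table interleaves two
    print columns; the transcription here is de-interleaved against the
    canonical 90%-stress listing and is validated by checksum tests and by the
    maximized log-likelihood it yields under the aIW model.

``kevlar373``
    Life of fatigue fracture of 76 Kevlar 373/epoxy specimens at the 90%
    stress level (Glaser's data).

Values are stored sorted.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .params import Sample

__all__ = ["NamedDataset", "load", "available", "read_sample", "write_sample"]

_KEVLAR49 = (
    0.01, 0.01, 0.02, 0.02, 0.02, 0.03, 0.03, 0.04, 0.05, 0.06,
    0.07, 0.07, 0.08, 0.09, 0.09, 0.10, 0.10, 0.11, 0.11, 0.12,
    0.13, 0.18, 0.19, 0.20, 0.23, 0.24, 0.24, 0.29, 0.34, 0.35,
    0.36, 0.38, 0.40, 0.42, 0.43, 0.52, 0.54, 0.56, 0.60, 0.60,
    0.63, 0.65, 0.67, 0.68, 0.72, 0.72, 0.72, 0.73, 0.79, 0.79,
    0.80, 0.80, 0.83, 0.85, 0.90, 0.92, 0.95, 0.99, 1.00, 1.01,
    1.02, 1.03, 1.05, 1.10, 1.10, 1.11, 1.15, 1.18, 1.20, 1.29,
    1.31, 1.33, 1.34, 1.40, 1.43, 1.45, 1.50, 1.51, 1.52, 1.53,
    1.54, 1.54, 1.55, 1.58, 1.60, 1.63, 1.64, 1.80, 1.80, 1.81,
    2.02, 2.05, 2.14, 2.17, 2.33, 3.03, 3.03, 3.34, 4.20, 4.69,
    7.89,
)

_KEVLAR373 = (
    0.0251, 0.0886, 0.0891, 0.2501, 0.3113, 0.3451, 0.4763, 0.5650, 0.5671,
    0.6566, 0.6748, 0.6751, 0.6753, 0.7696, 0.8375, 0.8391, 0.8425, 0.8645,
    0.8851, 0.9113, 0.9120, 0.9836, 1.0483, 1.0596, 1.0773, 1.1733, 1.2570,
    1.2766, 1.2985, 1.3211, 1.3503, 1.3551, 1.4595, 1.4880, 1.5728, 1.5733,
    1.7083, 1.7263, 1.7460, 1.7630, 1.7746, 1.8275, 1.8375, 1.8503, 1.8808,
    1.8878, 1.8881, 1.9316, 1.9558, 2.0048, 2.0408, 2.0903, 2.1093, 2.1330,
    2.2100, 2.2460, 2.2878, 2.3203, 2.3470, 2.3513, 2.4951, 2.5260, 2.9911,
    3.0256, 3.2678, 3.4045, 3.4846, 3.7433, 3.7455, 3.9143, 4.8073, 5.4005,
    5.4435, 5.5295, 6.5541, 9.0960,
)

_SOURCES = {
    "kevlar49": "Andrews & Herzberg, Data: A Collection of Problems (1985); "
                "Kevlar 49/epoxy strand stress-rupture at 90% stress, n=101",
    "kevlar373": "Glaser (1983); Kevlar 373/epoxy fatigue fracture at 90% "
                 "stress, n=76",
}
_TABLES = {"kevlar49": _KEVLAR49, "kevlar373": _KEVLAR373}


@dataclass(frozen=True)
class NamedDataset:
    name: str
    sample: Sample
    source: str

    @property
    def n(self) -> int:
        return self.sample.n


def available() -> tuple[str, ...]:
    return tuple(sorted(_TABLES))


def load(name: str) -> NamedDataset:
    """Load one of the embedded data sets by name."""
    key = name.lower()
    if key not in _TABLES:
        raise KeyError(f"unknown dataset {name!r}; available: {available()}")
    return NamedDataset(name=key, sample=Sample(np.array(_TABLES[key])),
                        source=_SOURCES[key])


def read_sample(path, fmt: str | None = None, column: str | int = 0) -> Sample:
    """Read a sample from plain text (one value per line) or single-column CSV.

    ``fmt`` is inferred from the suffix when omitted.  Non-numeric or
    non-positive entries raise with the offending line number.
    """
    path = Path(path)
    if fmt is None:
        fmt = "csv" if path.suffix.lower() == ".csv" else "text"
    if fmt not in ("text", "csv"):
        raise ValueError(f"format must be 'text' or 'csv', got {fmt!r}")

    values: list[float] = []
    if fmt == "text":
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.strip()
                if not line or line.startswith("#"):
                    continue
                _append_value(values, line, path, lineno)
    else:
        with open(path, newline="") as fh:
            reader = csv.reader(fh)
            rows = list(reader)
        col = column
        start = 0
        if rows and isinstance(column, str):
            try:
                col = rows[0].index(column)
                start = 1
            except ValueError:
                raise ValueError(f"column {column!r} not found in CSV header")
        elif rows:
            # tolerate a non-numeric header row on numeric column index
            try:
                float(rows[0][int(col)])
            except (ValueError, IndexError):
                start = 1
        for lineno, row in enumerate(rows[start:], start=start + 1):
            if not row:
                continue
            _append_value(values, row[int(col)], path, lineno)
    if not values:
        raise ValueError(f"{path}: no values found")
    return Sample(values)


def _append_value(values: list[float], token: str, path: Path, lineno: int) -> None:
    try:
        v = float(token)
    except ValueError:
        raise ValueError(f"{path}:{lineno}: not a number: {token!r}") from None
    if not np.isfinite(v) or v <= 0:
        raise ValueError(f"{path}:{lineno}: values must be strictly positive, got {v}")
    values.append(v)


def write_sample(sample: Sample, path, header: str | None = None) -> None:
    """Write a sample as one value per line; optional '#'-prefixed header."""
    path = Path(path)
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        for v in sample.values:
            fh.write(f"{float(v)!r}\n")
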