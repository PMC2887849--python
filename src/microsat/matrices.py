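"""Labelled symmetric distance matrices and their plain-text format.

Format: first line is the label count; each following line is
``label v1 v2 ...`` with ``NA`` for undefined cells.  Labels containing
whitespace are double-quoted.
"""

from __future__ import annotations

import math
import shlex
from dataclasses import dataclass

import numpy as np

_SYMMETRY_TOL = 1e-12


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray  # square, symmetric, zero diagonal; NaN = undefined

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise ValueError("duplicate labels")
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} != ({n}, {n})")
        with np.errstate(invalid="ignore"):
            asym = np.nanmax(np.abs(self.values - self.values.T), initial=0.0)
        if asym > _SYMMETRY_TOL:
            raise ValueError(f"matrix asymmetric beyond tolerance ({asym:g})")
        if not np.all(np.isnan(self.values.T) == np.isnan(self.values)):
            raise ValueError("NA cells not symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("diagonal must be exactly zero")

    @property
    def n(self) -> int:
        return len(self.labels)

    def reorder(self, labels: list[str]) -> "DistanceMatrix":
        """Return a copy with rows/columns aligned to the given label order."""
        if set(labels) != set(self.labels):
            raise ValueError("label sets differ")
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)])

    def condensed(self) -> np.ndarray:
        """Upper-triangle (off-diagonal) values in row-major order."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]


def write_matrix(m: DistanceMatrix, sig_digits: int = 10) -> str:
    lines = [str(m.n)]
    for i, label in enumerate(m.labels):
        tok = f'"{label}"' if any(c.isspace() for c in label) or not label else label
        cells = [
            "NA" if math.isnan(v) else f"{v:.{sig_digits}g}" for v in m.values[i]
        ]
        lines.append(tok + " " + " ".join(cells))
    return "\n".join(lines) + "\n"


def read_matrix(text: str) -> DistanceMatrix:
    lines = [l for l in text.splitlines() if l.strip()]
    if not lines:
        raise ValueError("empty matrix file")
    try:
        n = int(lines[0].strip())
    except ValueError:
        raise ValueError(f"first line must be the label count, got {lines[0]!r}")
    if len(lines) - 1 != n:
        raise ValueError(f"expected {n} rows, found {len(lines) - 1}")
    labels, rows = [], []
    for line in lines[1:]:
        toks = shlex.split(line)
        if len(toks) != n + 1:
            raise ValueError(f"row {toks[0] if toks else '?'!r}: expected {n} values")
        labels.append(toks[0])
        rows.append([math.nan if t.upper() == "NA" else float(t) for t in toks[1:]])
    return DistanceMatrix(labels, np.array(rows))
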