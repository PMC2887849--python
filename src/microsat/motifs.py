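"""Canonical motif classes for short tandem repeats.

A repeat motif is identified up to cyclic rotation: ``CAG``, ``AGC`` and
``GCA`` describe the same tandem array read in the same strand at different
phases.  Each equivalence class is named by its lexicographically smallest
rotation.  Motifs that are whole-number repetitions of a shorter unit
(``ACAC``, ``AAA``) are degenerate — their arrays are arrays of the shorter
unit — and are rejected.  Reverse complements are *not* collapsed: the
scanned sequence is stranded.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

_ALPHABET = "ACGT"
_VALID_PERIODS = frozenset({2, 3, 4})


class DegenerateMotifError(ValueError):
    """Motif is a whole-number repetition of a shorter unit."""

    def __init__(self, motif: str, period: int):
        self.motif = motif
        self.period = period
        super().__init__(
            f"motif {motif!r} is degenerate: a repetition of its "
            f"period-{period} unit {motif[:period]!r}"
        )


@dataclass(frozen=True, order=True)
class MotifClass:
    """A primitive repeat motif named by its smallest cyclic rotation."""

    canonical: str

    @property
    def period(self) -> int:
        return len(self.canonical)

    def __post_init__(self) -> None:
        m = self.canonical
        if len(m) not in _VALID_PERIODS:
            raise ValueError(f"motif length must be 2-4, got {m!r}")
        if any(b not in _ALPHABET for b in m):
            raise ValueError(f"motif must be uppercase ACGT, got {m!r}")
        p = primitive_period(m)
        if p != len(m):
            raise DegenerateMotifError(m, p)
        if m != min(_rotations(m)):
            raise ValueError(f"{m!r} is not the canonical rotation")


def _rotations(m: str) -> list[str]:
    return [m[i:] + m[:i] for i in range(len(m))]


def primitive_period(s: str) -> int:
    """Smallest p such that s is a whole-number repetition of s[:p]."""
    n = len(s)
    for p in range(1, n + 1):
        if n % p == 0 and s == s[:p] * (n // p):
            return p
    return n  # unreachable


def canonical_motif(motif: str) -> MotifClass:
    """Map a raw motif string to its rotation class.

    Raises ``DegenerateMotifError`` for non-primitive motifs and
    ``ValueError`` for bad length or alphabet.
    """
    m = motif.upper()
    if len(m) not in _VALID_PERIODS:
        raise ValueError(f"motif length must be 2-4, got {motif!r}")
    if any(b not in _ALPHABET for b in m):
        raise ValueError(f"motif contains non-ACGT character: {motif!r}")
    p = primitive_period(m)
    if p != len(m):
        raise DegenerateMotifError(m, p)
    return MotifClass(min(_rotations(m)))


def enumerate_motif_classes(periods: set[int] | frozenset[int]) -> list[MotifClass]:
    """All primitive cyclic-rotation classes for the requested periods.

    Returns 6 classes for period 2, 20 for period 3 and 60 for period 4,
    sorted lexicographically by canonical string.
    """
    if not periods:
        raise ValueError("periods must be nonempty")
    bad = set(periods) - _VALID_PERIODS
    if bad:
        raise ValueError(f"unsupported periods {sorted(bad)}; allowed: 2, 3, 4")
    seen: set[str] = set()
    for p in sorted(periods):
        for combo in itertools.product(_ALPHABET, repeat=p):
            m = "".join(combo)
            if primitive_period(m) != p:
                continue
            seen.add(min(_rotations(m)))
    return [MotifClass(c) for c in sorted(seen)]
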