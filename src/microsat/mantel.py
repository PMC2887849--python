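"""Mantel permutation test of association between two distance matrices.

The observed statistic is the Pearson correlation over the n(n-1)/2
off-diagonal pairs; the null distribution is built by simultaneously
permuting the rows and columns of the second matrix.  Note on terminology:
significance here comes from label *permutations* — the standard Mantel
null — even where source descriptions of such analyses loosely say
"bootstrap replicates"; resampling pairs with replacement would break the
exchangeability the test relies on.

Matrices are aligned by label, never by row position.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .matrices import DistanceMatrix


@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int
    n_labels: int
    seed: int
    alternative: str
    n_pairs_used: int

    def to_dict(self) -> dict:
        return {
            "r": self.r,
            "p": self.p,
            "n_perm": self.n_perm,
            "n_labels": self.n_labels,
            "seed": self.seed,
            "alternative": self.alternative,
            "n_pairs_used": self.n_pairs_used,
        }


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = x - x.mean()
    y = y - y.mean()
    denom = np.sqrt((x @ x) * (y @ y))
    if denom == 0:
        raise ValueError("constant distances: Mantel r undefined")
    return float((x @ y) / denom)


def mantel(
    a: DistanceMatrix,
    b: DistanceMatrix,
    n_perm: int = 10_000,
    seed: int | None = None,
    alternative: str = "greater",
) -> MantelResult:
    """Mantel test between two label-aligned distance matrices.

    p = (1 + #{r_perm >= r_obs}) / (1 + n_perm) for ``greater``;
    the ``two-sided`` option compares |r_perm| with |r_obs|.
    Pairs undefined (NA) in either matrix are dropped with a warning.
    """
    if n_perm < 1:
        raise ValueError(f"n_perm must be >= 1, got {n_perm}")
    if alternative not in ("greater", "two-sided"):
        raise ValueError(f"alternative must be 'greater' or 'two-sided', got {alternative!r}")
    if set(a.labels) != set(b.labels):
        only_a = sorted(set(a.labels) - set(b.labels))
        only_b = sorted(set(b.labels) - set(a.labels))
        raise ValueError(
            f"label sets differ: only in first matrix {only_a}, only in second {only_b}"
        )
    if a.n < 4:
        raise ValueError(f"need >= 4 labels, got {a.n}")
    b = b.reorder(a.labels)

    n = a.n
    iu = np.triu_indices(n, k=1)
    xa, xb = a.values[iu], b.values[iu]
    mask = ~(np.isnan(xa) | np.isnan(xb))
    if not mask.all():
        warnings.warn(
            f"dropping {int((~mask).sum())} pair(s) with undefined distance",
            stacklevel=2,
        )
    r_obs = _pearson(xa[mask], xb[mask])

    if seed is None:
        seed = 0
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        bp = b.values[np.ix_(perm, perm)][iu]
        r_perm = _pearson(xa[mask], bp[mask])
        if alternative == "greater":
            hits += r_perm >= r_obs
        else:
            hits += abs(r_perm) >= abs(r_obs)
    p = (1 + hits) / (1 + n_perm)
    return MantelResult(
        r=r_obs,
        p=float(p),
        n_perm=n_perm,
        n_labels=n,
        seed=seed,
        alternative=alternative,
        n_pairs_used=int(mask.sum()),
    )
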