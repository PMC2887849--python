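"""Pairwise Fst between populations via the Weir-Cockerham theta estimator.

Variance components a (among populations), b (among individuals within
populations) and c (within individuals) are computed per allele per locus
from sample sizes, allele frequencies and observed heterozygote
proportions; theta combines them ratio-of-sums across alleles and loci.
Missing calls are dropped per locus; loci monomorphic across the pair
contribute nothing.  Negative estimates are retained.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from .genotypes import Call, GenotypeTable
from .matrices import DistanceMatrix


def _wc_components(calls_by_pop: Sequence[Sequence[Call]]) -> tuple[float, float]:
    """(sum_a, sum_abc) over alleles for one locus across r populations."""
    r = len(calls_by_pop)
    present = [[c for c in pop_calls if c is not None] for pop_calls in calls_by_pop]
    sizes = np.array([len(p) for p in present], dtype=float)
    if np.any(sizes == 0):
        return 0.0, 0.0
    alleles = sorted({a for pop in present for call in pop for a in call})
    if len(alleles) < 2:
        return 0.0, 0.0
    n_bar = sizes.sum() / r
    n_c = (r * n_bar - (sizes**2).sum() / (r * n_bar)) / (r - 1)
    sum_a = sum_abc = 0.0
    for allele in alleles:
        p_i = np.array(
            [sum(call.count(allele) for call in pop) / (2 * len(pop)) for pop in present]
        )
        h_i = np.array(
            [
                sum(1 for call in pop if (allele in call) and call[0] != call[1]) / len(pop)
                for pop in present
            ]
        )
        p_bar = (sizes * p_i).sum() / (r * n_bar)
        s2 = (sizes * (p_i - p_bar) ** 2).sum() / ((r - 1) * n_bar)
        h_bar = (sizes * h_i).sum() / (r * n_bar)
        a = (n_bar / n_c) * (
            s2 - (p_bar * (1 - p_bar) - ((r - 1) / r) * s2 - h_bar / 4) / (n_bar - 1)
        )
        b = (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar) - ((r - 1) / r) * s2 - ((2 * n_bar - 1) / (4 * n_bar)) * h_bar
        )
        c = h_bar / 2
        sum_a += a
        sum_abc += a + b + c
    return sum_a, sum_abc


def theta_pair(table: GenotypeTable, pop_a: str, pop_b: str) -> float:
    """Multi-locus Weir-Cockerham theta for one population pair.

    Returns NaN when no locus contributes (no shared polymorphic data).
    """
    sum_a = sum_abc = 0.0
    for locus in table.loci:
        calls_a = table.calls_at(locus, pop_a)
        calls_b = table.calls_at(locus, pop_b)
        la, labc = _wc_components([calls_a, calls_b])
        sum_a += la
        sum_abc += labc
    if sum_abc == 0.0:
        return math.nan
    return sum_a / sum_abc


def pairwise_fst(table: GenotypeTable) -> DistanceMatrix:
    """Symmetric matrix of pairwise theta over all population pairs."""
    pops = table.populations
    if len(pops) < 2:
        raise ValueError("need >= 2 populations")
    n = len(pops)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = theta_pair(table, pops[i], pops[j])
    return DistanceMatrix(list(pops), values)
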