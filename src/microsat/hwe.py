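"""Hardy-Weinberg chi-square QC and marker diagnostics.

Per locus x population: a chi-square goodness-of-fit test of observed
genotype counts against HWE expectations from the observed allele
frequencies (df = k(k-1)/2 for k observed alleles; no continuity
correction, no cell pooling).  Marker-level diagnostics: tie-aware Spearman
correlation of per-locus heterozygote deficit (H_e - H_o) with percent
missing — the classic null-allele signature — and one-way ANOVA of percent
missing across multiplex groups.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .genotypes import Call, GenotypeTable, LocusSummary

DEFAULT_ALPHA = 0.05


class HWEStatus(str, Enum):
    SIGNIFICANT = "significant"
    NON_SIGNIFICANT = "non_significant"
    MONOMORPHIC = "monomorphic"
    UNTESTABLE = "untestable"


@dataclass
class HWETestResult:
    locus: str
    population: str
    chi2: float | None
    df: int | None
    p: float | None
    status: HWEStatus
    n: int = 0
    low_expected_warning: bool = False


def genotype_counts(calls: Iterable[Call]) -> dict[tuple[int, int], int]:
    """Unordered genotype counts from calls, skipping missing."""
    counts: dict[tuple[int, int], int] = {}
    for call in calls:
        if call is None:
            continue
        counts[call] = counts.get(call, 0) + 1
    return counts


def hwe_chi2(
    counts: Mapping[tuple[int, int], int],
    alpha: float = DEFAULT_ALPHA,
    locus: str = "",
    population: str = "",
) -> HWETestResult:
    """Chi-square HWE test on unordered genotype counts for one locus.

    Expected counts are n*p_i^2 (homozygotes) and 2*n*p_i*p_j
    (heterozygotes) from observed allele frequencies, over all k(k+1)/2
    genotype cells.  A warning flag is set when any expected count < 1 or
    more than 20% of cells are < 5.
    """
    n = sum(counts.values())
    if n == 0:
        return HWETestResult(locus, population, None, None, None, HWEStatus.UNTESTABLE, 0)
    gene_copies: dict[int, int] = {}
    for (a, b), c in counts.items():
        if c < 0:
            raise ValueError(f"negative genotype count for {(a, b)}")
        gene_copies[a] = gene_copies.get(a, 0) + c
        gene_copies[b] = gene_copies.get(b, 0) + c
    alleles = sorted(gene_copies)
    k = len(alleles)
    if k == 1:
        return HWETestResult(locus, population, None, None, None, HWEStatus.MONOMORPHIC, n)
    freqs = {a: gene_copies[a] / (2 * n) for a in alleles}
    chi2 = 0.0
    expected = []
    for i, a in enumerate(alleles):
        for b in alleles[i:]:
            exp = n * (freqs[a] ** 2 if a == b else 2 * freqs[a] * freqs[b])
            obs = counts.get((a, b), 0) + (counts.get((b, a), 0) if a != b else 0)
            expected.append(exp)
            chi2 += (obs - exp) ** 2 / exp
    df = k * (k - 1) // 2
    p = float(stats.chi2.sf(chi2, df))
    warn = any(e < 1 for e in expected) or (
        sum(e < 5 for e in expected) > 0.2 * len(expected)
    )
    status = HWEStatus.SIGNIFICANT if p < alpha else HWEStatus.NON_SIGNIFICANT
    return HWETestResult(locus, population, chi2, df, p, status, n, warn)


@dataclass
class HWEStatusGrid:
    """Locus x population grid of HWE statuses; populations alphabetical."""

    loci: list[str]
    populations: list[str]  # sorted alphabetically
    results: dict[tuple[str, str], HWETestResult] = field(default_factory=dict)

    def status(self, locus: str, population: str) -> HWEStatus:
        return self.results[(locus, population)].status

    def to_tsv(self) -> str:
        lines = ["locus\t" + "\t".join(self.populations)]
        for locus in self.loci:
            row = [self.status(locus, p).value for p in self.populations]
            lines.append(locus + "\t" + "\t".join(row))
        return "\n".join(lines) + "\n"

    def to_text_grid(self) -> str:
        """Three-code character grid: '#' significant, '.' monomorphic,
        ' ' other (non-significant/untestable)."""
        codes = {
            HWEStatus.SIGNIFICANT: "#",
            HWEStatus.MONOMORPHIC: ".",
            HWEStatus.NON_SIGNIFICANT: " ",
            HWEStatus.UNTESTABLE: " ",
        }
        width = max(len(l) for l in self.loci)
        lines = []
        for locus in self.loci:
            cells = "".join(codes[self.status(locus, p)] for p in self.populations)
            lines.append(f"{locus:<{width}} |{cells}|")
        return "\n".join(lines) + "\n"

    def save_png(self, path: str) -> None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        from matplotlib.colors import ListedColormap

        level = {
            HWEStatus.SIGNIFICANT: 2,
            HWEStatus.MONOMORPHIC: 1,
            HWEStatus.NON_SIGNIFICANT: 0,
            HWEStatus.UNTESTABLE: 0,
        }
        grid = [
            [level[self.status(l, p)] for p in self.populations] for l in self.loci
        ]
        fig, ax = plt.subplots(
            figsize=(max(4, 0.2 * len(self.populations)), max(2, 0.3 * len(self.loci)))
        )
        cmap = ListedColormap(["white", "lightgrey", "dimgrey"])
        ax.imshow(grid, cmap=cmap, vmin=0, vmax=2, aspect="auto")
        ax.set_yticks(range(len(self.loci)), self.loci)
        ax.set_xticks(range(len(self.populations)), self.populations, rotation=90, fontsize=6)
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def hwe_grid(table: GenotypeTable, alpha: float = DEFAULT_ALPHA) -> HWEStatusGrid:
    """HWE test per locus per population; columns sorted alphabetically."""
    pops = sorted(table.populations)
    grid = HWEStatusGrid(loci=list(table.loci), populations=pops)
    for locus in table.loci:
        for pop in pops:
            counts = genotype_counts(table.calls_at(locus, pop))
            grid.results[(locus, pop)] = hwe_chi2(
                counts, alpha=alpha, locus=locus, population=pop
            )
    return grid


# ---------------------------------------------------------------------------
# Marker-level diagnostics


@dataclass
class CorrelationResult:
    r_s: float
    n: int
    p: float


def _midranks(x: Sequence[float]) -> np.ndarray:
    return stats.rankdata(np.asarray(x, dtype=float), method="average")


def deficit_vs_missingness(
    summaries: Sequence[LocusSummary],
    exact: bool = False,
) -> CorrelationResult:
    """Spearman correlation of (H_e - H_o) with percent missing across loci.

    Tie-aware: Pearson correlation of midranks.  p-value from the
    two-tailed t approximation with n-2 df, or an exact permutation
    enumeration when ``exact`` (only sensible for n <= 10).
    """
    usable = [s for s in summaries if s.has_data]
    if len(usable) < 3:
        raise ValueError(f"need >= 3 loci with data, got {len(usable)}")
    x = np.array([s.h_exp - s.h_obs for s in usable])
    y = np.array([s.percent_missing for s in usable])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: Spearman correlation undefined")
    rx, ry = _midranks(x), _midranks(y)
    r = float(np.corrcoef(rx, ry)[0, 1])
    n = len(usable)
    if exact:
        if n > 10:
            raise ValueError("exact permutation p only supported for n <= 10")
        count = 0
        total = 0
        for perm in itertools.permutations(ry):
            rp = float(np.corrcoef(rx, np.array(perm))[0, 1])
            count += abs(rp) >= abs(r) - 1e-12
            total += 1
        p = count / total
    elif abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * math.sqrt((n - 2) / (1 - r * r))
        p = float(2 * stats.t.sf(abs(t), n - 2))
    return CorrelationResult(r_s=r, n=n, p=p)


@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    group_means: dict[str, float]


def missingness_anova(groups: Mapping[str, Sequence[float]]) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA on per-locus percent missing.

    ``groups`` maps a multiplex label to its member loci's percent-missing
    values.  Zero within-group variance yields F = inf, p = 0.
    """
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    for g, vals in groups.items():
        if len(vals) == 0:
            raise ValueError(f"group {g!r} is empty")
    values = [np.asarray(v, dtype=float) for v in groups.values()]
    n = sum(len(v) for v in values)
    k = len(values)
    if n <= k:
        raise ValueError("need total n > number of groups")
    grand = np.concatenate(values).mean()
    ss_between = sum(len(v) * (v.mean() - grand) ** 2 for v in values)
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in values)
    df_b, df_w = k - 1, n - k
    means = {g: float(np.mean(v)) for g, v in groups.items()}
    if ss_within == 0:
        if ss_between == 0:
            return AnovaResult(0.0, df_b, df_w, 1.0, means)
        return AnovaResult(math.inf, df_b, df_w, 0.0, means)
    F = float((ss_between / df_b) / (ss_within / df_w))
    p = float(stats.f.sf(F, df_b, df_w))
    return AnovaResult(F, df_b, df_w, p, means)


def anova_from_summaries(summaries: Sequence[LocusSummary]) -> AnovaResult:
    """Group locus summaries by their multiplex label and run the ANOVA."""
    grouped: dict[str, list[float]] = {}
    for s in summaries:
        if s.group is None:
            raise ValueError(f"locus {s.locus!r} has no multiplex group label")
        grouped.setdefault(str(s.group), []).append(s.percent_missing)
    return missingness_anova(grouped)
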