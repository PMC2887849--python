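"""Seeded generators with ground-truth manifests.

Two generators:

* contigs with planted perfect repeats on a background that is rejected
  until it contains no spontaneous run at or above the mining threshold,
  so the truth table is exact;
* island-model multi-population genotype tables with a directly
  parameterized generative Fst (subpopulation allele frequencies drawn
  Dirichlet around ancestral frequencies with concentration
  p*(1-F)/F) and an overlaid per-locus null allele: null/null genotypes
  become missing, null/visible genotypes are recorded as visible
  homozygotes.

All randomness flows from one explicit seed per spec.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .genotypes import Call, GenotypeTable, Individual
from .mining import DEFAULT_MIN_REPEATS, SSRLocus, find_ssrs
from .motifs import canonical_motif

# ---------------------------------------------------------------------------
# Contig simulation


@dataclass
class PlantedRepeat:
    motif: str
    repeat_count: int
    position: int  # approximate left edge within the contig


@dataclass
class ContigSimSpec:
    n_contigs: int
    contig_length: int
    planted: list[list[PlantedRepeat]]  # one list per contig
    base_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    seed: int = 0
    min_repeats: int = DEFAULT_MIN_REPEATS  # threshold background must stay below

    def __post_init__(self) -> None:
        if self.n_contigs < 1 or self.contig_length < 1:
            raise ValueError("n_contigs and contig_length must be positive")
        if len(self.planted) != self.n_contigs:
            raise ValueError("planted must have one entry list per contig")
        comp = np.asarray(self.base_composition, dtype=float)
        if comp.shape != (4,) or np.any(comp < 0) or abs(comp.sum() - 1) > 1e-9:
            raise ValueError("base_composition must be 4 probabilities summing to 1")
        for repeats in self.planted:
            for r in repeats:
                canonical_motif(r.motif)  # validates alphabet/primitivity
                span = len(r.motif) * r.repeat_count
                if r.position < 0 or r.position + span > self.contig_length:
                    raise ValueError(
                        f"planted repeat ({r.motif} x{r.repeat_count}) at "
                        f"{r.position} does not fit in contig of length "
                        f"{self.contig_length}"
                    )


def _background(rng: np.random.Generator, length: int, comp, min_repeats: int) -> str:
    """Random sequence with no spontaneous SSR run at the threshold."""
    bases = np.array(list("ACGT"))
    for _ in range(1000):
        seq = "".join(rng.choice(bases, size=length, p=comp))
        if not find_ssrs(seq, min_repeats=min_repeats, flank_len=0):
            return seq
    raise RuntimeError("could not generate SSR-free background; lower contig_length")


def simulate_contigs(spec: ContigSimSpec) -> tuple[str, list[SSRLocus]]:
    """(FASTA text, truth table of loci a correct miner must report).

    Planted repeats below ``spec.min_repeats`` are written into the
    sequence but excluded from the truth table.
    """
    rng = np.random.default_rng(spec.seed)
    comp = np.asarray(spec.base_composition, dtype=float)
    records = []
    truth: list[SSRLocus] = []
    for c in range(spec.n_contigs):
        contig_id = f"contig_{c + 1}"
        seq = list(_background(rng, spec.contig_length, comp, spec.min_repeats))
        for r in sorted(spec.planted[c], key=lambda r: r.position):
            tract = r.motif.upper() * r.repeat_count
            seq[r.position : r.position + len(tract)] = tract
        seq_s = "".join(seq)
        # planting may merge with or truncate chance partial matches at the
        # edges, so recover exact truth by scanning the finished contig
        truth.extend(
            find_ssrs(seq_s, contig_id=contig_id, min_repeats=spec.min_repeats)
        )
        records.append(f">{contig_id}\n{seq_s}")
    return "\n".join(records) + "\n", truth


# ---------------------------------------------------------------------------
# Genotype simulation


@dataclass
class PopSimSpec:
    n_pops: int
    n_per_pop: int
    n_loci: int
    n_alleles: int = 5
    fst_target: float = 0.05
    null_rate: float | list[float] = 0.0  # scalar or per locus
    missing_rate_baseline: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_pops, self.n_per_pop, self.n_loci) < 1 or self.n_alleles < 2:
            raise ValueError("population/locus/allele counts out of range")
        if not (0 < self.fst_target < 1):
            raise ValueError(f"fst_target must be in (0,1), got {self.fst_target}")
        rates = self.null_rates
        if any(not (0 <= r < 1) for r in rates):
            raise ValueError("null_rate values must be in [0,1)")
        if not (0 <= self.missing_rate_baseline < 1):
            raise ValueError("missing_rate_baseline must be in [0,1)")

    @property
    def null_rates(self) -> list[float]:
        if isinstance(self.null_rate, (int, float)):
            return [float(self.null_rate)] * self.n_loci
        if len(self.null_rate) != self.n_loci:
            raise ValueError("per-locus null_rate must have n_loci entries")
        return [float(r) for r in self.null_rate]


@dataclass
class PopSimTruth:
    """Generative ground truth for one simulated table."""

    spec: PopSimSpec
    ancestral_freqs: np.ndarray  # (n_loci, n_alleles)
    pop_freqs: np.ndarray  # (n_pops, n_loci, n_alleles)
    allele_sizes: np.ndarray  # (n_loci, n_alleles) fragment sizes in bp

    def to_dict(self) -> dict:
        return {
            "spec": {
                **{
                    k: v
                    for k, v in dataclasses.asdict(self.spec).items()
                    if not isinstance(v, np.ndarray)
                },
            },
            "ancestral_freqs": self.ancestral_freqs.tolist(),
            "pop_freqs": self.pop_freqs.tolist(),
            "allele_sizes": self.allele_sizes.tolist(),
        }


def simulate_genotypes(spec: PopSimSpec) -> tuple[GenotypeTable, PopSimTruth]:
    """Island-model diploid genotypes with Balding-Nichols differentiation.

    Ancestral allele frequencies are flat-Dirichlet per locus;
    each population's frequencies are Dirichlet with concentration
    p * (1-F)/F; genotypes are drawn under within-population HWE.
    The null-allele overlay then hides gene copies: a copy is null with
    probability null_rate, null/null becomes missing, null/visible is
    recorded as a visible homozygote.  Baseline missingness is applied
    independently afterwards.
    """
    rng = np.random.default_rng(spec.seed)
    L, K, P = spec.n_loci, spec.n_alleles, spec.n_pops
    null_rates = spec.null_rates
    f = spec.fst_target
    scale = (1 - f) / f

    ancestral = rng.dirichlet(np.ones(K), size=L)  # (L, K)
    pop_freqs = np.empty((P, L, K))
    for p in range(P):
        for l in range(L):
            pop_freqs[p, l] = rng.dirichlet(ancestral[l] * scale)
    # distinct, 3-digit-safe fragment sizes: dinucleotide ladder per locus
    allele_sizes = np.array([[100 + 2 * k for k in range(K)] for _ in range(L)])

    individuals = []
    for p in range(P):
        pop_name = f"pop{p + 1:02d}"
        for i in range(spec.n_per_pop):
            calls: list[Call] = []
            for l in range(L):
                a1, a2 = rng.choice(K, size=2, p=pop_freqs[p, l])
                nu = null_rates[l]
                n1 = nu > 0 and rng.random() < nu
                n2 = nu > 0 and rng.random() < nu
                if n1 and n2:
                    calls.append(None)
                    continue
                if n1:
                    a1 = a2
                elif n2:
                    a2 = a1
                if spec.missing_rate_baseline > 0 and rng.random() < spec.missing_rate_baseline:
                    calls.append(None)
                    continue
                s1, s2 = int(allele_sizes[l, a1]), int(allele_sizes[l, a2])
                calls.append((s1, s2) if s1 <= s2 else (s2, s1))
            individuals.append(Individual(f"{pop_name}_ind{i + 1:03d}", pop_name, calls))

    table = GenotypeTable(
        loci=[f"locus{l + 1:02d}" for l in range(L)],
        individuals=individuals,
        title=f"simulated island-model genotypes (seed={spec.seed})",
    )
    truth = PopSimTruth(spec, ancestral, pop_freqs, allele_sizes)
    return table, truth
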