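"""Diploid microsatellite genotype tables: data model, GenePop I/O, summaries.

Alleles are identified by integer fragment size (bp).  A call is an
unordered pair of allele sizes or missing (``None``).  Pooled per-locus
summary statistics (allele count, observed and expected heterozygosity,
percent missing) mirror the columns of a genotyping-panel summary table.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

Call = tuple[int, int] | None


class GenepopFormatError(ValueError):
    """Malformed GenePop input; carries the 1-based offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class NoDataError(ValueError):
    """Requested scope contains no non-missing calls."""


@dataclass
class Individual:
    name: str
    population: str
    calls: list[Call]  # one entry per locus, aligned with GenotypeTable.loci


@dataclass
class GenotypeTable:
    """Multi-population diploid genotypes across named loci."""

    loci: list[str]
    individuals: list[Individual]
    title: str = "microsat genotype table"

    def __post_init__(self) -> None:
        for ind in self.individuals:
            if len(ind.calls) != len(self.loci):
                raise ValueError(
                    f"individual {ind.name!r} has {len(ind.calls)} calls "
                    f"for {len(self.loci)} loci"
                )
            for call in ind.calls:
                if call is not None and (call[0] <= 0 or call[1] <= 0):
                    raise ValueError(
                        f"individual {ind.name!r}: allele sizes must be positive, got {call}"
                    )

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for ind in self.individuals:
            seen.setdefault(ind.population, None)
        return list(seen)

    def population_members(self, population: str) -> list[Individual]:
        return [i for i in self.individuals if i.population == population]

    def locus_index(self, locus: str) -> int:
        try:
            return self.loci.index(locus)
        except ValueError:
            raise KeyError(f"unknown locus {locus!r}") from None

    def calls_at(self, locus: str, population: str | None = None) -> list[Call]:
        """Calls at a locus, optionally restricted to one population."""
        j = self.locus_index(locus)
        inds = self.individuals if population is None else self.population_members(population)
        if population is not None and not inds:
            raise KeyError(f"unknown population {population!r}")
        return [ind.calls[j] for ind in inds]


def allele_frequencies(
    table: GenotypeTable, locus: str, population: str | None = None
) -> dict[int, float]:
    """Allele frequencies over 2 x (non-missing individuals) gene copies.

    ``population=None`` pools all populations.  Raises ``NoDataError``
    when every call in scope is missing.
    """
    counts: dict[int, int] = {}
    total = 0
    for call in table.calls_at(locus, population):
        if call is None:
            continue
        for a in call:
            counts[a] = counts.get(a, 0) + 1
            total += 1
    if total == 0:
        scope = population if population is not None else "<pooled>"
        raise NoDataError(f"no non-missing calls at locus {locus!r} in {scope}")
    return {a: c / total for a, c in sorted(counts.items())}


@dataclass
class LocusSummary:
    """Pooled per-locus summary; fields are None when the locus has no data."""

    locus: str
    allele_count: int | None
    h_obs: float | None
    h_exp: float | None
    percent_missing: float
    group: str | None = None

    @property
    def has_data(self) -> bool:
        return self.allele_count is not None


def locus_summaries(
    table: GenotypeTable,
    groups: Mapping[str, str] | None = None,
    sample_size_correction: bool = False,
) -> list[LocusSummary]:
    """Per-locus pooled summaries across all populations.

    h_exp is the plain gene diversity 1 - sum(p^2); pass
    ``sample_size_correction=True`` for the 2n/(2n-1) small-sample factor.
    ``groups`` optionally attaches a label (e.g. a multiplex PCR number)
    per locus.
    """
    if not table.individuals:
        raise ValueError("empty genotype table")
    n_total = len(table.individuals)
    out = []
    for j, locus in enumerate(table.loci):
        calls = [ind.calls[j] for ind in table.individuals]
        present = [c for c in calls if c is not None]
        pct_missing = 100.0 * (n_total - len(present)) / n_total
        group = groups.get(locus) if groups else None
        if not present:
            out.append(LocusSummary(locus, None, None, None, pct_missing, group))
            continue
        freqs = allele_frequencies(table, locus)
        h_exp = 1.0 - sum(p * p for p in freqs.values())
        if sample_size_correction:
            n2 = 2 * len(present)
            h_exp *= n2 / (n2 - 1) if n2 > 1 else 1.0
        h_obs = sum(1 for a, b in present if a != b) / len(present)
        out.append(LocusSummary(locus, len(freqs), h_obs, h_exp, pct_missing, group))
    return out


def summaries_to_frame(summaries: Iterable[LocusSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "locus": s.locus,
                "group": s.group,
                "allele_count": s.allele_count,
                "H_o": s.h_obs,
                "H_e": s.h_exp,
                "percent_missing": s.percent_missing,
            }
            for s in summaries
        ]
    )


# ---------------------------------------------------------------------------
# GenePop I/O


def _parse_allele_pair(token: str, line_no: int) -> Call:
    if len(token) == 6:
        w = 3
    elif len(token) == 4:
        w = 2
    else:
        raise GenepopFormatError(
            f"genotype token {token!r} must be 4 or 6 digits", line_no
        )
    if not token.isdigit():
        raise GenepopFormatError(f"genotype token {token!r} is not numeric", line_no)
    a, b = int(token[:w]), int(token[w:])
    if a == 0 and b == 0:
        return None
    if a == 0 or b == 0:
        # a half-missing call carries no usable diploid genotype
        return None
    return (a, b) if a <= b else (b, a)


def read_genepop(text: str) -> GenotypeTable:
    """Parse GenePop text: title, locus names, Pop blocks of individuals.

    Locus names may be one per line or comma-separated on one line.
    ``000000``/``0000`` is missing.  The population label is the name of
    the first individual of each Pop block.
    """
    lines = text.splitlines()
    if not lines:
        raise GenepopFormatError("empty input")
    title = lines[0].strip()
    loci: list[str] = []
    individuals: list[Individual] = []
    i = 1
    # locus-name section runs until the first "Pop" line
    while i < len(lines):
        stripped = lines[i].strip()
        if stripped.lower() == "pop":
            break
        if stripped:
            if "," in stripped:
                loci.extend(t.strip() for t in stripped.split(",") if t.strip())
            else:
                loci.append(stripped)
        i += 1
    if i == len(lines):
        raise GenepopFormatError("no 'Pop' line found", len(lines))
    if not loci:
        raise GenepopFormatError("no locus names before first 'Pop'", i + 1)

    pop_label: str | None = None
    while i < len(lines):
        stripped = lines[i].strip()
        if stripped.lower() == "pop":
            pop_label = None
            i += 1
            continue
        if not stripped:
            i += 1
            continue
        if "," not in stripped:
            raise GenepopFormatError(
                f"expected 'name , genotypes', got {stripped!r}", i + 1
            )
        name, _, geno = stripped.partition(",")
        name = name.strip()
        tokens = geno.split()
        if len(tokens) != len(loci):
            raise GenepopFormatError(
                f"individual {name!r} has {len(tokens)} genotypes for "
                f"{len(loci)} loci",
                i + 1,
            )
        if pop_label is None:
            pop_label = name
        calls = [_parse_allele_pair(t, i + 1) for t in tokens]
        individuals.append(Individual(name=name, population=pop_label, calls=calls))
        i += 1
    if not individuals:
        raise GenepopFormatError("no individuals found")
    return GenotypeTable(loci=loci, individuals=individuals, title=title)


def write_genepop(table: GenotypeTable, digits: int = 3) -> str:
    """Serialize to GenePop text with fixed allele-code width (2 or 3)."""
    if digits not in (2, 3):
        raise ValueError(f"digits must be 2 or 3, got {digits}")
    limit = 10**digits - 1
    out = [table.title]
    out.extend(table.loci)
    for pop in table.populations:
        out.append("Pop")
        for ind in table.population_members(pop):
            tokens = []
            for call in ind.calls:
                if call is None:
                    tokens.append("0" * (2 * digits))
                    continue
                a, b = call
                if a > limit or b > limit:
                    raise ValueError(
                        f"allele size {max(a, b)} exceeds {digits}-digit GenePop width"
                    )
                tokens.append(f"{a:0{digits}d}{b:0{digits}d}")
            out.append(f"{ind.name} ,  " + " ".join(tokens))
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# Long-format TSV I/O (individual, population, locus, allele1, allele2)


def read_long_tsv(text: str) -> GenotypeTable:
    df = pd.read_csv(io.StringIO(text), sep="\t", dtype={"allele1": "Int64", "allele2": "Int64"})
    required = {"individual", "population", "locus", "allele1", "allele2"}
    if missing := required - set(df.columns):
        raise ValueError(f"long TSV missing columns: {sorted(missing)}")
    loci = list(dict.fromkeys(df["locus"]))
    idx = {l: j for j, l in enumerate(loci)}
    inds: dict[str, Individual] = {}
    for row in df.itertuples(index=False):
        ind = inds.get(row.individual)
        if ind is None:
            ind = Individual(row.individual, row.population, [None] * len(loci))
            inds[row.individual] = ind
        if pd.isna(row.allele1) or pd.isna(row.allele2):
            call: Call = None
        else:
            a, b = int(row.allele1), int(row.allele2)
            call = (a, b) if a <= b else (b, a)
        ind.calls[idx[row.locus]] = call
    return GenotypeTable(loci=loci, individuals=list(inds.values()))


def write_long_tsv(table: GenotypeTable) -> str:
    rows = []
    for ind in table.individuals:
        for locus, call in zip(table.loci, ind.calls):
            a, b = (call if call is not None else ("", ""))
            rows.append((ind.name, ind.population, locus, a, b))
    df = pd.DataFrame(rows, columns=["individual", "population", "locus", "allele1", "allele2"])
    return df.to_csv(sep="\t", index=False)
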