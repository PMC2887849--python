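from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from microsat.genotypes import GenotypeTable, Individual, LocusSummary

REPO_ROOT = Path(__file__).resolve().parent.parent
PANEL_TSV = REPO_ROOT / "data" / "panel_summary.tsv"


@pytest.fixture(scope="session")
def panel_summaries() -> list[LocusSummary]:
    """The published 10-locus genotyping-panel summary table."""
    df = pd.read_csv(PANEL_TSV, sep="\t")
    return [
        LocusSummary(
            locus=row.locus,
            allele_count=int(row.allele_count),
            h_obs=float(row.H_o),
            h_exp=float(row.H_e),
            percent_missing=float(row.percent_missing),
            group=str(row.group),
        )
        for row in df.itertuples(index=False)
    ]


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260905)


def make_table(calls_by_pop: dict[str, list[list]], loci: list[str]) -> GenotypeTable:
    """Build a GenotypeTable from {pop: [per-individual call lists]}."""
    individuals = []
    for pop, ind_calls in calls_by_pop.items():
        for i, calls in enumerate(ind_calls):
            norm = [
                None if c is None else (min(c), max(c))
                for c in calls
            ]
            individuals.append(Individual(f"{pop}_{i}", pop, norm))
    return GenotypeTable(loci=loci, individuals=individuals)


@pytest.fixture
def small_table() -> GenotypeTable:
    """2 pops x 3 individuals x 2 loci with one missing call."""
    return make_table(
        {
            "north": [
                [(100, 100), (140, 144)],
                [(100, 102), (140, 140)],
                [(102, 102), None],
            ],
            "south": [
                [(100, 102), (144, 144)],
                [(100, 100), (140, 144)],
                [(100, 102), (140, 140)],
            ],
        },
        loci=["locA", "locB"],
    )
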