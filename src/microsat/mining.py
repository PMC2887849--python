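"""Perfect tandem-repeat (SSR) mining from assembled contigs.

Scans each contig for maximal perfect runs of di-, tri- and tetra-nucleotide
motifs with at least ``min_repeats`` whole copies.  Only whole motif copies
count; a trailing partial copy is excluded from the locus.  Non-ACGT
characters break runs.  Coordinates are 0-based half-open internally; GFF3
output converts to 1-based inclusive.
"""

from __future__ import annotations

import csv
import gzip
import io
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

from .motifs import MotifClass, canonical_motif, primitive_period

_ACGT = frozenset("ACGT")

DEFAULT_MIN_REPEATS = 8
DEFAULT_FLANK_LEN = 200
DEFAULT_COMPOUND_GAP = 10


@dataclass(frozen=True)
class SSRLocus:
    """One maximal perfect repeat run on a contig.

    ``start``/``end`` are 0-based half-open; ``end - start`` equals
    ``repeat_count * len(motif_observed)``.  ``motif_observed`` is the motif
    as read at ``start``; ``motif_class`` is its rotation class.
    """

    contig_id: str
    motif_observed: str
    motif_class: MotifClass
    start: int
    end: int
    repeat_count: int
    compound: bool = False
    left_flank: str = ""
    right_flank: str = ""

    def __post_init__(self) -> None:
        if self.end - self.start != self.repeat_count * len(self.motif_observed):
            raise ValueError(
                f"span {self.end - self.start} != "
                f"{self.repeat_count} x {len(self.motif_observed)}"
            )


def find_ssrs(
    sequence: str,
    contig_id: str = "",
    min_repeats: int = DEFAULT_MIN_REPEATS,
    periods: Iterable[int] = (2, 3, 4),
    flank_len: int = DEFAULT_FLANK_LEN,
    compound_gap: int = DEFAULT_COMPOUND_GAP,
) -> list[SSRLocus]:
    """All maximal perfect-repeat loci with >= min_repeats copies.

    Per period p, the sequence is swept for maximal stretches satisfying
    seq[i] == seq[i+p]; each stretch yields at most one locus, aligned to
    its leftmost position, provided the motif read there is primitive
    (period-p exactly, so an (AC)n run is never re-reported as (ACAC)m).
    Loci whose repeat tracts lie within ``compound_gap`` bases of another
    reported locus are flagged compound.
    """
    if min_repeats < 2:
        raise ValueError(f"min_repeats must be >= 2, got {min_repeats}")
    periods = sorted(set(periods))
    if not periods or any(p not in (2, 3, 4) for p in periods):
        raise ValueError(f"periods must be a nonempty subset of {{2,3,4}}, got {periods}")
    seq = sequence.upper()
    n = len(seq)
    loci: list[SSRLocus] = []
    for p in periods:
        i = 0
        limit = n - p
        while i < limit:
            if seq[i] in _ACGT and seq[i] == seq[i + p]:
                # extend the periodic stretch
                j = i
                while j < limit and seq[j] in _ACGT and seq[j] == seq[j + p]:
                    j += 1
                # periodic segment is seq[i : j + p]
                copies = (j + p - i) // p
                motif = seq[i : i + p]
                if copies >= min_repeats and primitive_period(motif) == p:
                    start, end = i, i + copies * p
                    loci.append(
                        SSRLocus(
                            contig_id=contig_id,
                            motif_observed=motif,
                            motif_class=canonical_motif(motif),
                            start=start,
                            end=end,
                            repeat_count=copies,
                            left_flank=seq[max(0, start - flank_len) : start],
                            right_flank=seq[end : end + flank_len],
                        )
                    )
                i = j + 1
            else:
                i += 1
    loci.sort(key=lambda l: (l.start, l.end, l.motif_class.canonical))
    return _flag_compound(loci, compound_gap)


def _flag_compound(loci: list[SSRLocus], gap: int) -> list[SSRLocus]:
    if len(loci) < 2:
        return loci
    flag = [False] * len(loci)
    for a in range(len(loci)):
        for b in range(a + 1, len(loci)):
            if loci[b].start - loci[a].end <= gap:
                flag[a] = flag[b] = True
            else:
                break
    return [replace(l, compound=f) if f != l.compound else l for l, f in zip(loci, flag)]


def scan_fasta(
    path: str | Path,
    min_repeats: int = DEFAULT_MIN_REPEATS,
    periods: Iterable[int] = (2, 3, 4),
    flank_len: int = DEFAULT_FLANK_LEN,
    compound_gap: int = DEFAULT_COMPOUND_GAP,
) -> Iterator[SSRLocus]:
    """Mine every record of a (possibly gzipped) multi-FASTA file."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:  # type: ignore[operator]
        for rec in SeqIO.parse(fh, "fasta"):
            yield from find_ssrs(
                str(rec.seq),
                contig_id=rec.id,
                min_repeats=min_repeats,
                periods=periods,
                flank_len=flank_len,
                compound_gap=compound_gap,
            )


_TSV_COLUMNS = (
    "contig",
    "motif_class",
    "motif_observed",
    "start",
    "end",
    "repeat_count",
    "compound",
    "left_flank",
    "right_flank",
)


def write_ssr_report(loci: Iterable[SSRLocus], format: str = "tsv") -> str:
    """Render loci as TSV or GFF3 text."""
    if format == "tsv":
        return _to_tsv(loci)
    if format == "gff3":
        return _to_gff3(loci)
    raise ValueError(f"unknown report format {format!r}; expected 'tsv' or 'gff3'")


def _to_tsv(loci: Iterable[SSRLocus]) -> str:
    buf = io.StringIO()
    w = csv.writer(buf, delimiter="\t", lineterminator="\n")
    w.writerow(_TSV_COLUMNS)
    for l in loci:
        w.writerow(
            [
                l.contig_id,
                l.motif_class.canonical,
                l.motif_observed,
                l.start,
                l.end,
                l.repeat_count,
                str(l.compound).lower(),
                l.left_flank,
                l.right_flank,
            ]
        )
    return buf.getvalue()


def _to_gff3(loci: Iterable[SSRLocus]) -> str:
    lines = ["##gff-version 3"]
    for l in loci:
        attrs = (
            f"motif={l.motif_observed};motif_class={l.motif_class.canonical};"
            f"repeat_count={l.repeat_count};compound={str(l.compound).lower()}"
        )
        lines.append(
            "\t".join(
                [
                    l.contig_id,
                    "microsat",
                    "microsatellite",
                    str(l.start + 1),  # GFF3 is 1-based inclusive
                    str(l.end),
                    ".",
                    "+",
                    ".",
                    attrs,
                ]
            )
        )
    return "\n".join(lines) + "\n"


def read_ssr_report(text: str) -> list[SSRLocus]:
    """Parse the TSV report back into loci (round-trip of write_ssr_report)."""
    reader = csv.DictReader(io.StringIO(text), delimiter="\t")
    loci = []
    for row in reader:
        loci.append(
            SSRLocus(
                contig_id=row["contig"],
                motif_observed=row["motif_observed"],
                motif_class=MotifClass(row["motif_class"]),
                start=int(row["start"]),
                end=int(row["end"]),
                repeat_count=int(row["repeat_count"]),
                compound=row["compound"] == "true",
                left_flank=row["left_flank"],
                right_flank=row["right_flank"],
            )
        )
    return loci
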