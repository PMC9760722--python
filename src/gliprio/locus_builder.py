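"""Locus window construction and interval-overlap queries.

A gene's locus is the span from the start of its first exon to the end of its
last exon, pooled across every transcript, extended by a flank (500 kb by
default) on both sides and clamped to chromosome bounds. A DNA-methylation
site's locus is the same flank on either side of the probe position.

Coordinates are 1-based and fully inclusive in memory; BED-like annotation on
disk is 0-based half-open and converted at the I/O boundary. The flank
boundary itself is inclusive: a position exactly ``flank`` bases away is
inside the window.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from gliprio.errors import (
    InconsistentAnnotationError,
    InvalidPositionError,
)

#: "500 kb" means exactly 500,000 bp.
DEFAULT_FLANK = 500_000

GENE_BED_COLUMNS = ["chrom", "exon_start", "exon_end", "gene_id", "transcript_id"]


@dataclass(frozen=True)
class GenomicInterval:
    """A 1-based, inclusive genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1:
            raise InvalidPositionError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise InvalidPositionError(
                f"end ({self.end}) precedes start ({self.start})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


@dataclass(frozen=True)
class GeneLocus:
    """A gene's exon span and its flanked window."""

    gene_id: str
    exon_span: GenomicInterval
    window: GenomicInterval

    @property
    def chrom(self) -> str:
        return self.window.chrom


@dataclass(frozen=True)
class SiteLocus:
    """A DNAm site position and its flanked window."""

    cpg_id: str
    chrom: str
    pos: int
    window: GenomicInterval


def gene_window(
    gene_id: str,
    exons: Sequence[GenomicInterval],
    flank: int = DEFAULT_FLANK,
    chrom_len: int | None = None,
) -> GeneLocus:
    """Build a gene locus from its exons: [min start - flank, max end + flank].

    All exons must lie on one chromosome; transcripts are expected to be
    pooled by the caller (every exon of every transcript in one list).
    """
    if not exons:
        raise InconsistentAnnotationError(f"gene {gene_id!r} has no exons")
    chroms = {e.chrom for e in exons}
    if len(chroms) != 1:
        raise InconsistentAnnotationError(
            f"gene {gene_id!r} has exons on multiple chromosomes: {sorted(chroms)}"
        )
    chrom = chroms.pop()
    span = GenomicInterval(chrom, min(e.start for e in exons), max(e.end for e in exons))
    lo = max(1, span.start - flank)
    hi = span.end + flank
    if chrom_len is not None:
        hi = min(hi, chrom_len)
    return GeneLocus(gene_id, span, GenomicInterval(chrom, lo, hi))


def site_window(
    cpg_id: str,
    chrom: str,
    pos: int,
    flank: int = DEFAULT_FLANK,
    chrom_len: int | None = None,
) -> SiteLocus:
    """Build a DNAm-site locus: [pos - flank, pos + flank], clamped."""
    if pos < 1 or (chrom_len is not None and pos > chrom_len):
        raise InvalidPositionError(
            f"site {cpg_id!r} position {pos} outside [1, {chrom_len}] on {chrom}"
        )
    lo = max(1, pos - flank)
    hi = pos + flank
    if chrom_len is not None:
        hi = min(hi, chrom_len)
    return SiteLocus(cpg_id, chrom, pos, GenomicInterval(chrom, lo, hi))


class LocusIndex:
    """Point-overlap queries against a set of locus windows.

    Backed by one interval tree per chromosome; ``query`` is equivalent to a
    linear scan over all windows.
    """

    def __init__(self, loci: Iterable[GeneLocus | SiteLocus] = ()):
        self._trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
        self._n = 0
        for locus in loci:
            self.add(locus)

    def add(self, locus: GeneLocus | SiteLocus) -> None:
        w = locus.window
        # interval tree is half-open; +1 keeps the inclusive end queryable
        self._trees[w.chrom].addi(w.start, w.end + 1, locus)
        self._n += 1

    def __len__(self) -> int:
        return self._n

    def query(self, chrom: str, pos: int) -> list:
        """Return every locus whose window contains (chrom, pos)."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = [iv.data for iv in tree.at(pos)]
        hits.sort(key=_locus_key)
        return hits


def _locus_key(locus) -> tuple:
    name = getattr(locus, "gene_id", None) or getattr(locus, "cpg_id", "")
    return (locus.window.chrom, locus.window.start, locus.window.end, name)


def read_gene_bed(path: str | Path) -> pd.DataFrame:
    """Read BED-like exon annotation (0-based half-open) into 1-based columns.

    Returns a frame with chrom, start, end (1-based inclusive), gene_id,
    transcript_id.
    """
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=GENE_BED_COLUMNS)
    out = pd.DataFrame(
        {
            "chrom": df["chrom"].astype(str),
            "start": df["exon_start"].astype(int) + 1,
            "end": df["exon_end"].astype(int),
            "gene_id": df["gene_id"].astype(str),
            "transcript_id": df["transcript_id"].astype(str),
        }
    )
    return out


def write_gene_bed(annotation: pd.DataFrame, path: str | Path) -> None:
    """Write 1-based exon annotation back to BED-like (0-based half-open) TSV."""
    out = pd.DataFrame(
        {
            "chrom": annotation["chrom"],
            "exon_start": annotation["start"].astype(int) - 1,
            "exon_end": annotation["end"].astype(int),
            "gene_id": annotation["gene_id"],
            "transcript_id": annotation.get(
                "transcript_id", pd.Series(["t1"] * len(annotation))
            ),
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def gene_windows_from_annotation(
    annotation: pd.DataFrame,
    flank: int = DEFAULT_FLANK,
    chrom_lengths: Mapping[str, int] | None = None,
) -> dict[str, GeneLocus]:
    """Pool exons by gene_id (regardless of transcript) and build windows."""
    loci: dict[str, GeneLocus] = {}
    for gene_id, grp in annotation.groupby("gene_id", sort=True):
        exons = [
            GenomicInterval(r.chrom, int(r.start), int(r.end))
            for r in grp.itertuples()
        ]
        chrom = exons[0].chrom
        clen = chrom_lengths.get(chrom) if chrom_lengths else None
        loci[str(gene_id)] = gene_window(str(gene_id), exons, flank=flank, chrom_len=clen)
    return loci


def windows_to_bed(loci: Iterable[GeneLocus], path: str | Path) -> None:
    """Export gene windows as a 0-based half-open BED file."""
    rows = [
        (l.window.chrom, l.window.start - 1, l.window.end, l.gene_id)
        for l in sorted(loci, key=_locus_key)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)
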