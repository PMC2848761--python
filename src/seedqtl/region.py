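"""QTL-region demarcation from marker segregation.

A near-isogenic line (NIL) pair differs only in an introgressed chromosomal
segment.  Markers inside the introgression segregate in the NIL-derived
population; markers outside do not.  The QTL region is demarcated as the
interval between the closest *non*-segregating markers flanking the
segregating block on either side — the outer bound of where the introgression
can lie.

All coordinates are 1-based and inclusive on both ends (GFF3 convention).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import pandas as pd

logger = logging.getLogger(__name__)

#: Genotype call alphabet: parent-1 homozygote, parent-2 homozygote,
#: heterozygote.  Anything else (empty, '-', 'NA', '.') is treated as missing.
CALL_ALPHABET = frozenset({"A", "B", "H"})
MISSING_CALLS = frozenset({"", "-", ".", "NA", "nan", "None"})


@dataclass(frozen=True)
class Marker:
    """A mapped marker with its segregation status.

    ``segregating`` implies ``polymorphic``: a marker can only show multiple
    genotype classes in the population if the parents carry different alleles.
    """

    name: str
    chromosome: str
    position: int  # bp, 1-based
    polymorphic: bool
    segregating: bool

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"marker {self.name}: position must be >= 1")
        if self.segregating and not self.polymorphic:
            raise ValueError(
                f"marker {self.name}: segregating marker must be polymorphic"
            )


@dataclass(frozen=True)
class Region:
    """A genomic interval, 1-based, inclusive on both ends."""

    chromosome: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"region start {self.start} > end {self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def span_bp(self) -> int:
        """Distance between the border coordinates (end - start)."""
        return self.end - self.start

    def contains(self, chromosome: str, position: int) -> bool:
        return chromosome == self.chromosome and self.start <= position <= self.end


def call_segregation(calls) -> bool:
    """Decide whether one marker's genotype calls show segregation.

    A marker segregates iff at least two distinct non-missing genotype
    classes (A/B/H) are observed among the lines.  Heterozygous calls count
    as a class of their own.

    Parameters
    ----------
    calls : iterable of str
        One marker's row of a genotype-call matrix.

    Raises
    ------
    ValueError
        If every call is missing, or an unknown call symbol occurs.
    """
    observed = set()
    for c in calls:
        c = str(c).strip()
        if c in MISSING_CALLS:
            continue
        if c not in CALL_ALPHABET:
            raise ValueError(f"unknown genotype call {c!r}")
        observed.add(c)
    if not observed:
        raise ValueError("all genotype calls missing; segregation undefined")
    return len(observed) >= 2


def demarcate_region(markers, chrom_length: int | None = None) -> Region:
    """Demarcate the QTL interval from a marker panel on one chromosome.

    The region runs from the nearest non-segregating marker left of the
    leftmost segregating marker to the nearest non-segregating marker right
    of the rightmost segregating marker.  If a side has no non-segregating
    flank, the chromosome end (position 1, or ``chrom_length``) is used and
    a warning is issued.

    Parameters
    ----------
    markers : iterable of Marker
        Markers on a single chromosome, in any order.
    chrom_length : int, optional
        Chromosome length in bp, used as the right bound when no right
        flanking marker exists.

    Raises
    ------
    ValueError
        If no marker segregates, or markers span multiple chromosomes.
    """
    markers = sorted(markers, key=lambda m: m.position)
    if not markers:
        raise ValueError("no markers supplied")
    chroms = {m.chromosome for m in markers}
    seg_chroms = {m.chromosome for m in markers if m.segregating}
    if not seg_chroms:
        raise ValueError("no segregating marker; cannot demarcate a region")
    if len(seg_chroms) > 1:
        raise ValueError(
            f"segregating markers on multiple chromosomes: {sorted(seg_chroms)}; "
            "demarcate one chromosome per call"
        )
    if len(chroms) > 1:
        raise ValueError(f"markers span multiple chromosomes: {sorted(chroms)}")
    chrom = markers[0].chromosome

    seg_pos = [m.position for m in markers if m.segregating]
    left_seg, right_seg = seg_pos[0], seg_pos[-1]

    left_flanks = [
        m.position for m in markers if not m.segregating and m.position < left_seg
    ]
    right_flanks = [
        m.position for m in markers if not m.segregating and m.position > right_seg
    ]

    if left_flanks:
        start = max(left_flanks)
    else:
        start = 1
        warnings.warn(
            f"no non-segregating marker left of {left_seg} on {chrom}; "
            "using chromosome start",
            stacklevel=2,
        )
    if right_flanks:
        end = min(right_flanks)
    else:
        end = chrom_length if chrom_length is not None else right_seg
        warnings.warn(
            f"no non-segregating marker right of {right_seg} on {chrom}; "
            f"using chromosome end {end}",
            stacklevel=2,
        )
    return Region(chromosome=chrom, start=start, end=end)


def markers_from_frame(df: pd.DataFrame) -> list[Marker]:
    """Build Marker objects from a marker table.

    Expects columns ``name, chromosome, position, polymorphic, segregating``.
    If ``segregating`` is absent but per-line genotype-call columns
    (``call_*``) are present, segregation is derived with
    :func:`call_segregation`.
    """
    df = df.copy()
    if "segregating" not in df.columns:
        call_cols = [c for c in df.columns if c.startswith("call_")]
        if not call_cols:
            raise ValueError(
                "marker table needs a 'segregating' column or call_* columns"
            )
        df["segregating"] = [
            call_segregation(row) for row in df[call_cols].to_numpy()
        ]
    if "polymorphic" not in df.columns:
        # a segregating marker is necessarily polymorphic; default the rest
        df["polymorphic"] = df["segregating"]
    return [
        Marker(
            name=str(r.name_),
            chromosome=str(r.chromosome),
            position=int(r.position),
            polymorphic=bool(r.polymorphic),
            segregating=bool(r.segregating),
        )
        for r in df.rename(columns={"name": "name_"}).itertuples(index=False)
    ]


def genes_in_region(annotation: pd.DataFrame, region: Region) -> pd.DataFrame:
    """Genes overlapping the region by at least 1 bp, sorted by start.

    ``annotation`` must have columns ``gene_id, chromosome, start, end``
    (1-based inclusive).  Overlap is strand-agnostic.
    """
    sel = annotation[
        (annotation["chromosome"] == region.chromosome)
        & (annotation["end"] >= region.start)
        & (annotation["start"] <= region.end)
    ]
    return sel.sort_values("start").reset_index(drop=True)
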