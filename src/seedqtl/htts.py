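"""Read-count differential accumulation from high-throughput transcriptome
sequencing (HTTS).

Eight libraries (LoPro and HiPro at four seed-fill stages) of uniquely mapped
short reads are reduced to a gene × library count table by overlap with each
gene's longest splice variant, scaled so every library total equals the
experiment-wide mean total ("treatment-sum" normalization), and screened for
genes whose normalized counts differ between genotypes by at least two-fold
with a two-tailed exact binomial test: under the null the C1 + C2 reads for a
gene split Binomial(n, 1/2) between the two treatments.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.special import logsumexp

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.001
DEFAULT_FOLD = 2.0
MISMATCH_QUALITY_SUM_MAX = 6
UNIQUE_MAPQ = 99


@dataclass(frozen=True)
class ReadAlignment:
    """A uniquely-or-ambiguously placed read with its mismatch base qualities.

    ``mismatch_quals`` holds the Phred scores of the mismatched bases; an
    empty tuple means a perfect alignment.
    """

    read_id: str
    chromosome: str
    start: int  # 1-based leftmost position
    length: int
    mapq: int
    mismatch_quals: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"read {self.read_id}: start must be >= 1")
        if self.mapq < 0:
            raise ValueError(f"read {self.read_id}: mapping quality must be >= 0")

    @property
    def end(self) -> int:
        return self.start + self.length - 1


@dataclass
class GeneCountTable:
    """Gene × library raw counts with library metadata and normalization.

    ``counts``: integer DataFrame, genes as rows, libraries as columns.
    ``design``: DataFrame indexed by library with ``genotype`` and ``stage``.
    ``factors``/``normalized`` are filled by :func:`normalize_counts`.
    """

    counts: pd.DataFrame
    design: pd.DataFrame
    factors: pd.Series | None = field(default=None)
    normalized: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        missing = set(self.counts.columns) - set(self.design.index)
        if missing:
            raise ValueError(f"libraries missing from design: {sorted(missing)}")


def filter_alignments(records: Iterable[ReadAlignment]) -> list[ReadAlignment]:
    """Apply the read-retention rule.

    A mapping is kept iff it has mapping quality 99 (unique, high
    confidence), or no mismatches, or the summed Phred quality of the
    mismatched bases is at most 6 (mismatches confined to unreliable base
    calls).
    """
    return [
        r
        for r in records
        if r.mapq == UNIQUE_MAPQ
        or not r.mismatch_quals
        or sum(r.mismatch_quals) <= MISMATCH_QUALITY_SUM_MAX
    ]


def count_reads(
    records_by_library: Mapping[str, Iterable[ReadAlignment]],
    annotation,
    design: pd.DataFrame,
) -> GeneCountTable:
    """Count reads per gene per library against longest splice variants.

    A read increments a gene when any part of it overlaps (≥ 1 bp) the
    genomic span of the gene's longest splice variant; a read overlapping
    several genes increments each of them, but each gene at most once per
    read.  Reads on chromosomes absent from the annotation are logged and
    counted toward no gene.

    ``annotation`` is a :class:`seedqtl.io.GeneModels`.
    """
    genes = annotation.genes
    trees: dict[str, IntervalTree] = {}
    for row in genes.itertuples():
        trees.setdefault(row.chromosome, IntervalTree()).addi(
            row.lv_start, row.lv_end + 1, row.gene_id
        )
    libraries = list(records_by_library)
    gene_ids = genes["gene_id"].tolist()
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    mat = np.zeros((len(gene_ids), len(libraries)), dtype=np.int64)
    n_off = 0
    for j, lib in enumerate(libraries):
        for rec in records_by_library[lib]:
            tree = trees.get(rec.chromosome)
            if tree is None:
                n_off += 1
                continue
            for hit in tree.overlap(rec.start, rec.end + 1):
                mat[gene_pos[hit.data], j] += 1
    if n_off:
        logger.warning("%d reads on chromosomes absent from the annotation", n_off)
    counts = pd.DataFrame(mat, index=pd.Index(gene_ids, name="gene"), columns=libraries)
    return GeneCountTable(counts=counts, design=design)


def normalize_counts(table: GeneCountTable) -> GeneCountTable:
    """Treatment-sum normalization: equalize library totals.

    factor(lib) = (mean of all library totals) / (lib's total);
    normalized(g, lib) = count(g, lib) × factor(lib).  Afterwards every
    library's total equals the pre-normalization mean total.
    """
    sums = table.counts.sum(axis=0)
    if len(sums) < 2:
        raise ValueError("need >= 2 libraries")
    if (sums <= 0).any():
        bad = sums.index[sums <= 0].tolist()
        raise ValueError(f"libraries with zero total counts: {bad}")
    factors = sums.mean() / sums
    normalized = table.counts * factors
    return GeneCountTable(
        counts=table.counts,
        design=table.design,
        factors=factors,
        normalized=normalized,
    )


def binomial_p(c_small: int, c_large: int) -> float:
    """Two-tailed exact binomial p for a count pair under a fair 1/2 split.

    p_one = P(X ≤ c_small) for X ~ Binomial(c_small + c_large, 1/2), computed
    by exact log-space summation of the pmf; p_two = min(1, 2 · p_one).
    The pair is significant at level α iff p_one ≤ α/2, i.e. p_two ≤ α.
    """
    c_small, c_large = int(c_small), int(c_large)
    if c_small < 0 or c_large < 0:
        raise ValueError("counts must be non-negative")
    if c_small > c_large:
        raise ValueError("c_small must not exceed c_large")
    n = c_small + c_large
    if n == 0:
        raise ValueError("both counts zero; the binomial test is undefined")
    k = np.arange(c_small + 1)
    log_terms = (
        math.lgamma(n + 1)
        - np.array([math.lgamma(v + 1) for v in k])
        - np.array([math.lgamma(n - v + 1) for v in k])
        - n * math.log(2.0)
    )
    p_one = float(np.exp(logsumexp(log_terms)))
    return min(1.0, 2.0 * p_one)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def de_screen(
    table: GeneCountTable,
    comparisons: Iterable[str] | None = None,
    fold_min: float = DEFAULT_FOLD,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Screen genes for differential accumulation between genotypes.

    For each stage, the LoPro library is compared against the HiPro library
    of the same stage; for "overall", per-gene normalized counts are summed
    over the four stages within each genotype.  Normalized values are rounded
    half-up to integers before the binomial test.  A gene passes a comparison
    when the two-tailed binomial p ≤ ``alpha`` and the fold change
    (max/min of the normalized pair, ∞ when the smaller is 0) is at least
    ``fold_min``.  Genes with zero counts in both members of a comparison are
    not testable and are omitted from that comparison.

    Returns one row per (gene, comparison) with raw and normalized counts,
    fold, p and the ``significant`` flag.
    """
    if table.normalized is None:
        raise ValueError("normalize the table first (normalize_counts)")
    design = table.design
    stages = sorted(design["stage"].unique())
    if comparisons is None:
        comparisons = ["overall"] + [f"stage{k}" for k in stages]

    def libs(genotype: str, stage) -> list[str]:
        sel = design.index[
            (design["genotype"] == genotype) & (design["stage"] == stage)
        ].tolist()
        if not sel:
            raise ValueError(f"no library for genotype={genotype}, stage={stage}")
        return sel

    rows = []
    norm = table.normalized
    raw = table.counts
    for comp in comparisons:
        if comp == "overall":
            lo_cols = [c for s in stages for c in libs("LoPro", s)]
            hi_cols = [c for s in stages for c in libs("HiPro", s)]
        else:
            stage = int(comp.removeprefix("stage"))
            lo_cols = libs("LoPro", stage)
            hi_cols = libs("HiPro", stage)
        norm_a = norm[lo_cols].sum(axis=1)
        norm_b = norm[hi_cols].sum(axis=1)
        raw_a = raw[lo_cols].sum(axis=1)
        raw_b = raw[hi_cols].sum(axis=1)
        for gene in norm.index:
            na, nb = float(norm_a[gene]), float(norm_b[gene])
            ra, rb = _round_half_up(na), _round_half_up(nb)
            if ra + rb == 0:
                continue
            p = binomial_p(min(ra, rb), max(ra, rb))
            lo, hi = min(na, nb), max(na, nb)
            fold = math.inf if lo == 0 else hi / lo
            rows.append(
                {
                    "gene": gene,
                    "comparison": comp,
                    "count_A": int(raw_a[gene]),
                    "count_B": int(raw_b[gene]),
                    "norm_A": na,
                    "norm_B": nb,
                    "fold": fold,
                    "p_two_tailed": p,
                    "significant": (p <= alpha) and (fold >= fold_min),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "gene",
            "comparison",
            "count_A",
            "count_B",
            "norm_A",
            "norm_B",
            "fold",
            "p_two_tailed",
            "significant",
        ],
    )


def expression_evidence(table: GeneCountTable) -> set[str]:
    """Genes with at least one uniquely mapped read across all libraries."""
    totals = table.counts.sum(axis=1)
    return set(totals.index[totals >= 1])
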