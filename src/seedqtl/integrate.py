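"""Cross-platform candidate integration, GO enrichment, and qRT-PCR folds.

Differential-accumulation evidence from the expression array and from read
counting lives on different feature systems (probesets vs gene models).  The
two are merged by genome coordinates: features overlapping the demarcated QTL
region are clustered single-linkage by ≥ 1 bp interval overlap, and each
cluster becomes one candidate gene carrying the union of platform evidence
and a majority direction.  Flat GO-slim enrichment uses Fisher's exact test
with a Bonferroni correction over the total number of GO categories, and
qRT-PCR validation folds use the comparative-CT (ΔΔCT) method against an
actin reference.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class CandidateGene:
    """A cluster of mutually overlapping DE features on one chromosome."""

    chromosome: str
    start: int
    end: int
    members: tuple[str, ...]
    platforms: frozenset[str]
    direction: str  # "LoPro", "HiPro", or "mixed"

    @property
    def evidence(self) -> str:
        if self.platforms >= {"microarray", "htts"}:
            return "both"
        return next(iter(self.platforms))


def normalize_coordinates(coords: pd.DataFrame) -> pd.DataFrame:
    """Orient feature coordinates so start ≤ end.

    Published probeset alignments may list start > stop for minus-orientation
    matches; downstream interval logic assumes oriented intervals.
    Expects columns ``feature, chromosome, start, end`` (``platform`` and
    ``strand`` pass through).
    """
    coords = coords.copy()
    lo = coords[["start", "end"]].min(axis=1)
    hi = coords[["start", "end"]].max(axis=1)
    coords["start"], coords["end"] = lo, hi
    return coords


def candidate_table(
    de_microarray: pd.DataFrame,
    de_htts: pd.DataFrame,
    coords: pd.DataFrame,
    region,
) -> list[CandidateGene]:
    """Integrate DE features from both platforms into region candidates.

    ``de_microarray`` and ``de_htts`` need columns ``feature`` and
    ``direction`` (which genotype showed higher accumulation).  ``coords``
    maps every feature to ``chromosome, start, end``; features overlapping
    ``region`` by ≥ 1 bp are clustered single-linkage (strand-agnostic) and
    each cluster reported once with the union of platform evidence.

    Raises ``ValueError`` listing the ids of DE features absent from
    ``coords``.
    """
    frames = []
    for df, platform in ((de_microarray, "microarray"), (de_htts, "htts")):
        if df is None or len(df) == 0:
            continue
        d = df[["feature", "direction"]].copy()
        d["platform"] = platform
        frames.append(d)
    if not frames:
        return []
    feats = pd.concat(frames, ignore_index=True)

    cmap = normalize_coordinates(coords).set_index("feature")
    missing = [f for f in feats["feature"] if f not in cmap.index]
    if missing:
        raise ValueError(f"DE features without coordinates: {sorted(set(missing))}")

    feats = feats.join(cmap[["chromosome", "start", "end"]], on="feature")
    in_region = feats[
        (feats["chromosome"] == region.chromosome)
        & (feats["end"] >= region.start)
        & (feats["start"] <= region.end)
    ].sort_values(["start", "end", "feature"])

    candidates: list[CandidateGene] = []
    cluster: list = []
    cluster_end = -1

    def flush() -> None:
        if not cluster:
            return
        members = tuple(sorted({r.feature for r in cluster}))
        platforms = frozenset(r.platform for r in cluster)
        votes = Counter(r.direction for r in cluster)
        top = votes.most_common()
        if len(top) > 1 and top[0][1] == top[1][1]:
            direction = "mixed"
        else:
            direction = top[0][0]
        candidates.append(
            CandidateGene(
                chromosome=region.chromosome,
                start=min(r.start for r in cluster),
                end=max(r.end for r in cluster),
                members=members,
                platforms=platforms,
                direction=direction,
            )
        )

    for row in in_region.itertuples(index=False):
        if cluster and row.start <= cluster_end:
            cluster.append(row)
            cluster_end = max(cluster_end, row.end)
        else:
            flush()
            cluster = [row]
            cluster_end = row.end
    flush()
    return candidates


def candidates_to_frame(candidates: list[CandidateGene]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chromosome": [c.chromosome for c in candidates],
            "start": [c.start for c in candidates],
            "end": [c.end for c in candidates],
            "members": [";".join(c.members) for c in candidates],
            "direction": [c.direction for c in candidates],
            "evidence": [c.evidence for c in candidates],
        }
    )


def fisher_enrichment(
    de_genes,
    universe_genes,
    category_map: pd.DataFrame,
    n_categories_total: int,
    alpha: float = 0.05,
    report_all: bool = False,
) -> pd.DataFrame:
    """Flat GO-category enrichment of DE genes against the expressed universe.

    Per category with ≥ 1 universe gene, a 2×2 table (DE in / non-DE in /
    DE out / non-DE out) is tested with Fisher's exact two-tail rule (sum of
    hypergeometric probabilities ≤ the observed table's); the p-value is
    Bonferroni-multiplied by ``n_categories_total`` (the total number of GO
    categories on the platform, which may exceed the number tested here).
    Only over-represented categories with adjusted p < ``alpha`` are
    reported unless ``report_all``.

    ``category_map`` needs columns ``category`` and ``gene``.
    """
    de = set(de_genes)
    universe = set(universe_genes)
    if not de <= universe:
        raise ValueError("de_genes must be a subset of universe_genes")
    cats = (
        category_map[category_map["gene"].isin(universe)]
        .groupby("category")["gene"]
        .apply(set)
    )
    if n_categories_total < len(cats):
        raise ValueError(
            "n_categories_total smaller than the number of tested categories"
        )
    rows = []
    n_de = len(de)
    n_u = len(universe)
    for cat, genes in cats.items():
        a = len(de & genes)
        b = len(genes) - a  # non-DE in category
        c = n_de - a  # DE outside
        d = n_u - n_de - b  # non-DE outside
        p = float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
        adjusted = min(1.0, p * n_categories_total)
        over = a * d > b * c  # odds ratio > 1
        rows.append(
            {
                "category": cat,
                "de_in": a,
                "nonde_in": b,
                "de_out": c,
                "nonde_out": d,
                "p": p,
                "p_adjusted": adjusted,
                "over_represented": over,
                "reported": over and adjusted < alpha,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "category",
            "de_in",
            "nonde_in",
            "de_out",
            "nonde_out",
            "p",
            "p_adjusted",
            "over_represented",
            "reported",
        ],
    )
    if report_all:
        return out
    return out[out["reported"]].reset_index(drop=True)


def comparative_ct(
    records: pd.DataFrame, group_a: str, group_b: str
) -> tuple[float, float]:
    """Comparative-CT (ΔΔCT) fold change of group_a relative to group_b.

    ``records`` needs columns ``genotype, target_ct, reference_ct``.
    ΔCT = target CT − reference CT per sample; ΔΔCT = mean ΔCT(group_a) −
    mean ΔCT(group_b); fold = 2^(−ΔΔCT).  Returns ``(fold, sd)`` where sd is
    the standard deviation of per-replicate folds of group_a against the
    group_b mean (0 when group_a has a single replicate).

    Raises ``ValueError`` when a group is empty or a reference CT is missing.
    """
    if records["reference_ct"].isna().any():
        raise ValueError("missing reference CT value")
    d = records.copy()
    d["dct"] = d["target_ct"] - d["reference_ct"]
    da = d.loc[d["genotype"] == group_a, "dct"]
    db = d.loc[d["genotype"] == group_b, "dct"]
    if len(da) == 0 or len(db) == 0:
        raise ValueError(f"need >= 1 record for each of {group_a!r} and {group_b!r}")
    ddct = da.mean() - db.mean()
    fold = float(2.0 ** (-ddct))
    rep_folds = 2.0 ** (-(da - db.mean()))
    sd = float(np.std(rep_folds, ddof=1)) if len(rep_folds) > 1 else 0.0
    return fold, sd
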