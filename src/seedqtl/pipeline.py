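"""Top-level pipeline driver: demarcate → microarray DE → SFP → read-count DE
→ candidate integration → GO enrichment.

Inputs, thresholds and the seed live in a flat :class:`PipelineConfig`
(loadable from a YAML key-value file).  Every stage writes a TSV/BED/JSON
artifact into the output directory plus a run log recording the package
version, the seed, and every threshold actually applied; given identical
inputs and seed the outputs are byte-identical.  Environment variables are
never consulted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import io as sio
from . import htts, integrate, microarray, region as qregion, sfp as sfpmod

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and thresholds for a full pipeline run."""

    markers: str
    intensities: str
    array_design: str
    counts: str
    library_design: str
    annotation: str
    feature_coords: str
    go_map: str
    outdir: str
    seed: int = 0
    chromosome: str | None = None  # restrict markers to this chromosome
    chrom_length: int | None = None
    microarray_fold: float = 1.5
    microarray_fdr: float = 0.05
    htts_fold: float = 2.0
    htts_alpha: float = 0.001
    sfp_permutations: int = 200
    sfp_fdr: float = 0.05
    enrichment_alpha: float = 0.05

    def __post_init__(self) -> None:
        for name in (
            "microarray_fold", "microarray_fdr", "htts_fold", "htts_alpha",
            "sfp_fdr", "enrichment_alpha",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def input_paths(self) -> dict[str, Path]:
        return {
            k: Path(getattr(self, k))
            for k in (
                "markers", "intensities", "array_design", "counts",
                "library_design", "annotation", "feature_coords", "go_map",
            )
        }


def load_config(path) -> PipelineConfig:
    """Load a flat YAML key-value pipeline configuration."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return PipelineConfig(**data)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis and write all artifacts.

    Returns a report dict (also written as ``run_log.json``).  All inputs
    are checked up front so a missing path aborts before any output is
    written.
    """
    missing = [str(p) for p in config.input_paths().values() if not p.exists()]
    if missing:
        raise FileNotFoundError(f"missing input files: {missing}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:  # re-tag with the failing stage
            raise StageError(f"stage {name!r} failed: {exc}") from exc

    # --- region demarcation
    def _demarcate():
        mdf = sio.read_markers(config.markers)
        if config.chromosome is not None:
            mdf = mdf[mdf["chromosome"] == config.chromosome]
        markers = qregion.markers_from_frame(mdf)
        reg = qregion.demarcate_region(markers, chrom_length=config.chrom_length)
        sio.write_region_bed(reg, outdir / "region.bed")
        return reg

    reg = stage("demarcate", _demarcate)

    # --- microarray condensation + contrasts + ANOVA
    def _microarray():
        raw = sio.read_intensities(config.intensities, config.array_design)
        norm = microarray.quantile_normalize(raw)
        expr = microarray.median_polish_condense(norm)
        de = microarray.genotype_contrast(
            expr, fold_min=config.microarray_fold, fdr=config.microarray_fdr
        )
        anova = microarray.two_way_anova(expr, fdr=config.microarray_fdr)
        de.to_csv(outdir / "genotype_contrast.tsv", sep="\t", index=False)
        anova.to_csv(outdir / "anova.tsv", sep="\t", index=False)
        return norm, expr, de, anova

    norm, expr, ma_de, anova = stage("microarray-de", _microarray)

    # --- SFP detection
    def _sfp():
        aff = sfpmod.compute_affinity(norm, expr)
        calls = sfpmod.sfp_test(
            aff,
            n_permutations=config.sfp_permutations,
            fdr=config.sfp_fdr,
            seed=config.seed,
        )
        calls.to_csv(outdir / "sfp_calls.tsv", sep="\t", index=False)
        sfpmod.sfp_probeset_summary(calls).to_csv(
            outdir / "sfp_probesets.tsv", sep="\t", index=False
        )
        return calls

    sfp_calls = stage("sfp", _sfp)

    # --- read-count DE
    def _htts():
        table = sio.read_counts(config.counts, config.library_design)
        table = htts.normalize_counts(table)
        de = htts.de_screen(table, fold_min=config.htts_fold, alpha=config.htts_alpha)
        de.to_csv(outdir / "htts_de.tsv", sep="\t", index=False)
        return table, de

    count_table, htts_de = stage("htts-de", _htts)

    # --- candidate integration
    def _integrate():
        coords = sio.read_coordinate_map(config.feature_coords)
        ma_sig = ma_de[ma_de["significant"]]
        de_ma = pd.DataFrame(
            {
                "feature": ma_sig["probeset"],
                "direction": [
                    "LoPro" if r > 1 else "HiPro" for r in ma_sig["ratio"]
                ],
            }
        )
        ht_sig = htts_de[htts_de["significant"]]
        de_ht = (
            pd.DataFrame(
                {
                    "feature": ht_sig["gene"],
                    "direction": [
                        "LoPro" if a > b else "HiPro"
                        for a, b in zip(ht_sig["norm_A"], ht_sig["norm_B"])
                    ],
                }
            )
            .drop_duplicates(subset="feature")
            .reset_index(drop=True)
        )
        cands = integrate.candidate_table(de_ma, de_ht, coords, reg)
        integrate.candidates_to_frame(cands).to_csv(
            outdir / "candidates.tsv", sep="\t", index=False
        )
        return cands

    candidates = stage("integrate", _integrate)

    # --- GO enrichment of read-count DE genes vs the expressed universe
    def _enrich():
        go = sio.read_go_map(config.go_map)
        universe = htts.expression_evidence(count_table)
        de_genes = set(htts_de.loc[htts_de["significant"], "gene"]) & universe
        n_total = go["category"].nunique()
        enr = integrate.fisher_enrichment(
            de_genes, universe, go, n_categories_total=n_total,
            alpha=config.enrichment_alpha, report_all=True,
        )
        enr.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
        return enr

    enrichment = stage("enrich", _enrich)

    report = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": {
            "microarray_fold": config.microarray_fold,
            "microarray_fdr": config.microarray_fdr,
            "htts_fold": config.htts_fold,
            "htts_alpha": config.htts_alpha,
            "sfp_permutations": config.sfp_permutations,
            "sfp_fdr": config.sfp_fdr,
            "enrichment_alpha": config.enrichment_alpha,
        },
        "region": {
            "chromosome": reg.chromosome,
            "start": reg.start,
            "end": reg.end,
            "span_bp": reg.span_bp,
        },
        "n_microarray_significant": int(ma_de["significant"].sum()),
        "n_anova_significant": int(anova["significant"].sum()),
        "n_sfp_probes": int(sfp_calls["significant"].sum()),
        "n_htts_de_genes": int(
            htts_de.loc[htts_de["significant"], "gene"].nunique()
        ),
        "n_candidates": len(candidates),
        "n_enriched_categories": int(enrichment["reported"].sum()),
    }
    sio.write_json(report, outdir / "run_log.json")
    logger.info("pipeline complete: %s", report)
    return report
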