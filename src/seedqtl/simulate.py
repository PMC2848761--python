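"""Synthetic NIL seed-fill experiments with known ground truth.

Generates the complete input set the pipeline consumes — gene models, a
marker panel with a contiguous segregating block, probe-level microarray
intensities with an additive log2 structure (probeset expression + probe
affinity + noise) and injected single-feature polymorphisms, and eight
read-count libraries (two genotypes × four seed-fill stages) with unequal
depths and fold-change differential expression concentrated in the
introgressed segment — together with truth tables listing every injected
effect, so each downstream stage can be checked for recovery.

Defaults mirror the study design being emulated: 3 biological replicates,
4 stages, 11 probes per probeset, ~200k uniquely mapped reads per library,
a two-genotype NIL contrast with differential accumulation confined to the
introgression.  All randomness flows from ``SimulationConfig.seed`` through
named per-stage substreams, so an identical config reproduces the experiment
byte-for-byte.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as sio
from .htts import GeneCountTable, ReadAlignment
from .io import GeneModels
from .microarray import ProbeIntensityMatrix
from .region import Region

GENOTYPES = ("LoPro", "HiPro")
#: substream labels so each simulation stage has an independent, named RNG
_STREAMS = {"annotation": 1, "markers": 2, "microarray": 3, "counts": 4,
            "alignments": 5, "go": 6, "qpcr": 7}


def _rng(config: "SimulationConfig", stage: str) -> np.random.Generator:
    return np.random.default_rng([config.seed, _STREAMS[stage]])


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a synthetic NIL seed-fill experiment.

    ``introgression_interval`` is (chromosome, start bp, end bp), 1-based
    inclusive; ``sfp_shift`` is the log2 affinity shift applied to the HiPro
    arrays of each affected probe; ``de_fold`` is the linear expression fold
    between genotypes for differential genes; ``count_dispersion`` is the
    negative-binomial dispersion (0 degenerates to Poisson);
    ``intensity_sigma`` is the log2-scale noise s.d. on the arrays.
    """

    seed: int = 0
    n_chromosomes: int = 2
    chromosome_length_bp: int = 10_000_000
    n_genes: int = 2000
    n_markers: int = 20
    introgression_interval: tuple[str, int, int] = ("chr1", 3_000_000, 5_000_000)
    n_probesets: int = 500
    probes_per_probeset: int = 11
    n_replicates: int = 3
    n_stages: int = 4
    de_fraction_in_region: float = 0.3
    de_fold: float = 4.0
    sfp_fraction: float = 0.04
    sfp_shift: float = 2.0
    library_depth_range: tuple[int, int] = (150_000, 250_000)
    count_dispersion: float = 0.05
    intensity_sigma: float = 0.2
    stage_factors: tuple[float, ...] = (1.0, 1.5, 2.5, 4.0)
    silent_gene_fraction: float = 0.14
    n_go_categories: int = 30

    def __post_init__(self) -> None:
        for name in (
            "n_chromosomes", "chromosome_length_bp", "n_genes", "n_markers",
            "n_probesets", "probes_per_probeset", "n_replicates", "n_stages",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("de_fraction_in_region", "sfp_fraction", "silent_gene_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.de_fold < 1.0:
            raise ValueError("de_fold must be >= 1")
        chrom, start, end = self.introgression_interval
        if not (1 <= start <= end <= self.chromosome_length_bp):
            raise ValueError("introgression interval outside chromosome bounds")
        if len(self.stage_factors) != self.n_stages:
            raise ValueError("stage_factors must have n_stages entries")
        if self.library_depth_range[0] > self.library_depth_range[1]:
            raise ValueError("library_depth_range must be (min, max)")

    @property
    def chromosomes(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    @property
    def region(self) -> Region:
        chrom, start, end = self.introgression_interval
        return Region(chromosome=chrom, start=start, end=end)


@dataclass
class SimulatedExperiment:
    """A full synthetic experiment with its truth tables."""

    config: SimulationConfig
    annotation: GeneModels
    markers: pd.DataFrame
    probe_intensities: ProbeIntensityMatrix
    probeset_coords: pd.DataFrame  # feature coordinate map (both platforms)
    truth_sfps: pd.DataFrame  # probeset, probe, shift (log2, applied to HiPro)
    counts: GeneCountTable
    truth_de: pd.DataFrame  # gene, direction, fold
    go_map: pd.DataFrame


# ---------------------------------------------------------------------------
# Annotation and markers


def simulate_annotation_and_markers(
    config: SimulationConfig,
) -> tuple[GeneModels, pd.DataFrame]:
    """Generate non-overlapping gene models and a marker panel.

    Genes are laid out in equal slots along each chromosome, each occupying a
    random non-degenerate sub-interval of its slot, with two splice variants
    (the full span, designated longest, and a shorter internal one).  Markers
    on the introgressed chromosome are evenly spaced; those inside the
    introgression are flagged segregating, all others non-segregating, and a
    6-line genotype-call matrix consistent with the flags is attached.
    """
    chrom, istart, iend = config.introgression_interval
    rng_a = _rng(config, "annotation")

    per_chrom = config.n_genes // config.n_chromosomes
    extra = config.n_genes - per_chrom * config.n_chromosomes
    g_rows, t_rows = [], []
    gi = 0
    for ci, c in enumerate(config.chromosomes):
        n_here = per_chrom + (1 if ci < extra else 0)
        slot = config.chromosome_length_bp // max(n_here, 1)
        for k in range(n_here):
            gi += 1
            slot_start = k * slot + 1
            length = int(rng_a.integers(max(2, slot // 10), max(3, slot // 2)))
            offset = int(rng_a.integers(0, max(1, slot - length)))
            start = slot_start + offset
            end = min(start + length - 1, config.chromosome_length_bp)
            strand = "+" if rng_a.random() < 0.5 else "-"
            gene_id = f"gene{gi:05d}"
            g_rows.append(
                {
                    "gene_id": gene_id,
                    "chromosome": c,
                    "start": start,
                    "end": end,
                    "strand": strand,
                    "lv_id": f"{gene_id}.1",
                    "lv_start": start,
                    "lv_end": end,
                }
            )
            t_rows.append(
                {
                    "transcript_id": f"{gene_id}.1",
                    "gene_id": gene_id,
                    "chromosome": c,
                    "start": start,
                    "end": end,
                    "strand": strand,
                }
            )
            if end - start >= 4:
                t_rows.append(
                    {
                        "transcript_id": f"{gene_id}.2",
                        "gene_id": gene_id,
                        "chromosome": c,
                        "start": start + 1,
                        "end": end - 1,
                        "strand": strand,
                    }
                )
    annotation = GeneModels(
        genes=pd.DataFrame(g_rows), transcripts=pd.DataFrame(t_rows)
    )

    rng_m = _rng(config, "markers")
    positions = np.linspace(
        1, config.chromosome_length_bp, config.n_markers, dtype=int
    )
    seg_flags = (positions >= istart) & (positions <= iend)
    if seg_flags.all() or positions[~seg_flags].size == 0 or (
        istart <= positions[0] and iend >= positions[-1]
    ):
        raise ValueError(
            "introgression interval covers the whole marker panel; "
            "no flanking non-segregating marker possible"
        )
    if not seg_flags.any():
        # guarantee a segregating block exists: force the marker closest to
        # the interval centre inside it
        raise ValueError(
            "no marker falls inside the introgression interval; "
            "increase n_markers or widen the interval"
        )
    n_lines = 6
    m_rows = []
    for i, (pos, seg) in enumerate(zip(positions, seg_flags)):
        calls = ["A"] * n_lines
        if seg:
            # at least two classes among the lines
            n_b = int(rng_m.integers(1, n_lines))
            idx = rng_m.choice(n_lines, size=n_b, replace=False)
            for j in idx:
                calls[j] = "B" if rng_m.random() < 0.7 else "H"
        row = {
            "name": f"mk{i + 1:03d}",
            "chromosome": chrom,
            "position": int(pos),
            "polymorphic": bool(seg),
            "segregating": bool(seg),
        }
        row.update({f"call_line{j + 1}": calls[j] for j in range(n_lines)})
        m_rows.append(row)
    markers = pd.DataFrame(m_rows)
    return annotation, markers


def _choose_de_genes(
    config: SimulationConfig, annotation: GeneModels, region: Region,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Pick the truth set of differential genes inside the region."""
    genes = annotation.genes
    in_region = genes[
        (genes["chromosome"] == region.chromosome)
        & (genes["end"] >= region.start)
        & (genes["start"] <= region.end)
    ]["gene_id"].tolist()
    n_de = int(round(config.de_fraction_in_region * len(in_region)))
    chosen = sorted(rng.choice(in_region, size=n_de, replace=False)) if n_de else []
    directions = rng.choice(["LoPro", "HiPro"], size=len(chosen), p=[0.8, 0.2])
    return pd.DataFrame(
        {"gene": chosen, "direction": directions, "fold": config.de_fold}
    )


# ---------------------------------------------------------------------------
# Microarray


def simulate_microarray(
    config: SimulationConfig,
    annotation: GeneModels,
    region: Region,
    truth_de: pd.DataFrame | None = None,
):
    """Simulate probe-level intensities under the additive log2 model.

    log2 intensity of probe j of probeset i on array a is
    I(i, genotype, stage) + A(i, j) + δ(i, j)·[genotype = HiPro] + ε with
    ε ~ Normal(0, ``intensity_sigma``); δ is nonzero only for injected SFPs
    (one probe per affected probeset, |δ| = ``sfp_shift``, random sign).
    Probesets are mapped onto distinct genes; probesets on truth-DE genes
    carry the genotype fold change in I.

    Returns ``(ProbeIntensityMatrix, probeset coordinate map, truth SFP
    table, truth DE table)``.
    """
    rng = _rng(config, "microarray")
    genes = annotation.genes
    if truth_de is None:
        truth_de = _choose_de_genes(config, annotation, region, rng)
    de_dir = dict(zip(truth_de["gene"], truth_de["direction"]))

    n_ps = min(config.n_probesets, len(genes))
    # map probesets onto distinct genes; guarantee every truth-DE gene gets one
    de_gene_ids = [g for g in de_dir if g in set(genes["gene_id"])]
    others = [g for g in genes["gene_id"] if g not in de_dir]
    n_other = max(0, n_ps - len(de_gene_ids))
    chosen = de_gene_ids + sorted(rng.choice(others, size=n_other, replace=False))
    chosen = sorted(chosen)[:n_ps]
    gidx = genes.set_index("gene_id")

    coords = []
    for k, g in enumerate(chosen):
        row = gidx.loc[g]
        coords.append(
            {
                "feature": f"ps{k + 1:05d}",
                "gene": g,
                "chromosome": row["chromosome"],
                "start": int(row["start"]),
                "end": int(row["end"]),
                "strand": row["strand"],
                "platform": "microarray",
            }
        )
    coords = pd.DataFrame(coords)

    n_probes = config.probes_per_probeset
    stages = range(1, config.n_stages + 1)
    arrays, design_rows = [], []
    for geno in GENOTYPES:
        for s in stages:
            for r in range(1, config.n_replicates + 1):
                a = f"{geno}_s{s}_r{r}"
                arrays.append(a)
                design_rows.append(
                    {"array": a, "genotype": geno, "stage": s, "replicate": r}
                )
    design = pd.DataFrame(design_rows).set_index("array")

    base = rng.uniform(6.0, 12.0, size=n_ps)  # log2 probeset expression
    affinity = rng.normal(0.0, 0.8, size=(n_ps, n_probes))
    stage_log = np.log2(np.asarray(config.stage_factors))

    n_sfp = int(config.sfp_fraction * n_ps)
    if config.sfp_fraction > 0 and n_sfp < 1:
        warnings.warn(
            "sfp_fraction too small for this probeset count; no SFP injected",
            stacklevel=2,
        )
    sfp_ps = rng.choice(n_ps, size=n_sfp, replace=False) if n_sfp else np.array([], int)
    sfp_probe = rng.integers(0, n_probes, size=n_sfp)
    sfp_sign = rng.choice([-1.0, 1.0], size=n_sfp)
    truth_sfps = pd.DataFrame(
        {
            "probeset": [coords["feature"].iloc[i] for i in sfp_ps],
            "probe": sfp_probe + 1,
            "shift": sfp_sign * config.sfp_shift,
        }
    )

    delta = np.zeros((n_ps, n_probes))
    delta[sfp_ps, sfp_probe] = sfp_sign * config.sfp_shift

    log_fold = np.log2(config.de_fold)
    values = np.empty((n_ps * n_probes, len(arrays)))
    index = pd.MultiIndex.from_product(
        [coords["feature"], range(1, n_probes + 1)], names=["probeset", "probe"]
    )
    geno_de = np.zeros((n_ps, 2))  # extra log2 expression per genotype column
    for k, g in enumerate(chosen):
        if g in de_dir:
            col = 0 if de_dir[g] == "LoPro" else 1
            geno_de[k, col] = log_fold
    for a_i, a in enumerate(arrays):
        geno = design.loc[a, "genotype"]
        s = int(design.loc[a, "stage"])
        gcol = 0 if geno == "LoPro" else 1
        expr = base + stage_log[s - 1] + geno_de[:, gcol]
        probe_log2 = expr[:, None] + affinity
        if geno == "HiPro":
            probe_log2 = probe_log2 + delta
        if config.intensity_sigma > 0:
            probe_log2 = probe_log2 + rng.normal(
                0.0, config.intensity_sigma, size=probe_log2.shape
            )
        values[:, a_i] = np.power(2.0, probe_log2).ravel()
    matrix = ProbeIntensityMatrix(
        values=pd.DataFrame(values, index=index, columns=arrays), design=design
    )
    return matrix, coords, truth_sfps, truth_de


# ---------------------------------------------------------------------------
# Read counts


def library_design(config: SimulationConfig) -> pd.DataFrame:
    """The eight-library design: A1–A4 = LoPro stages, B1–B4 = HiPro stages."""
    rows = []
    for geno, prefix in zip(GENOTYPES, ("A", "B")):
        for s in range(1, config.n_stages + 1):
            rows.append({"library": f"{prefix}{s}", "genotype": geno, "stage": s})
    return pd.DataFrame(rows).set_index("library")


def simulate_htts(
    config: SimulationConfig,
    annotation: GeneModels,
    region: Region,
    truth_de: pd.DataFrame | None = None,
) -> tuple[GeneCountTable, pd.DataFrame]:
    """Simulate the gene × library count table.

    Per-gene abundance weights are log-normal, multiplied by shared stage
    factors and, for truth-DE genes, by ``de_fold`` in the favoured genotype;
    library depths are drawn uniformly from ``library_depth_range``.  Counts
    are negative binomial via a Gamma–Poisson mixture (Poisson when
    ``count_dispersion`` is 0).  A ``silent_gene_fraction`` of genes has zero
    expected count everywhere.
    """
    rng = _rng(config, "counts")
    if truth_de is None:
        truth_de = _choose_de_genes(config, annotation, region, rng)
    de_dir = dict(zip(truth_de["gene"], truth_de["direction"]))
    genes = annotation.genes["gene_id"].tolist()
    n_genes = len(genes)

    weights = rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)
    silent = rng.random(n_genes) < config.silent_gene_fraction
    # truth-DE genes must be expressed to be recoverable
    de_mask = np.array([g in de_dir for g in genes])
    silent &= ~de_mask
    weights[silent] = 0.0

    design = library_design(config)
    depth = rng.uniform(*config.library_depth_range, size=len(design))
    design = design.assign(depth=depth)
    stage_f = np.asarray(config.stage_factors)

    fold_term = np.ones((n_genes, 2))  # columns LoPro, HiPro
    for i, g in enumerate(genes):
        if g in de_dir:
            col = 0 if de_dir[g] == "LoPro" else 1
            fold_term[i, col] = config.de_fold

    base_total = float((weights * stage_f.mean()).sum())
    mat = np.zeros((n_genes, len(design)), dtype=np.int64)
    for j, lib in enumerate(design.index):
        geno = design.loc[lib, "genotype"]
        s = int(design.loc[lib, "stage"])
        gcol = 0 if geno == "LoPro" else 1
        mu = weights * stage_f[s - 1] * fold_term[:, gcol]
        mu = mu * (depth[j] / base_total)
        if config.count_dispersion > 0:
            shape = 1.0 / config.count_dispersion
            lam = np.where(
                mu > 0, rng.gamma(shape, 1.0, size=n_genes) * mu / shape, 0.0
            )
        else:
            lam = mu
        mat[:, j] = rng.poisson(lam)
    counts = pd.DataFrame(
        mat, index=pd.Index(genes, name="gene"), columns=list(design.index)
    )
    return GeneCountTable(counts=counts, design=design), truth_de


def simulate_alignments(
    config: SimulationConfig,
    annotation: GeneModels,
    counts: GeneCountTable,
    read_length: int = 36,
    junk_per_library: int = 0,
) -> dict[str, list[ReadAlignment]]:
    """Emit alignment records that reproduce the count table exactly.

    Each counted read is placed fully inside its gene's longest-variant span
    with mapping quality 99 and no mismatches, so filtering plus counting
    recovers ``counts.counts``.  ``junk_per_library`` adds reads that fail
    every retention rule (low mapq, one high-quality mismatch), placed in
    intergenic space when possible, to exercise the filter.
    """
    rng = _rng(config, "alignments")
    genes = annotation.genes.set_index("gene_id")
    out: dict[str, list[ReadAlignment]] = {}
    for lib in counts.counts.columns:
        recs: list[ReadAlignment] = []
        col = counts.counts[lib]
        for gene, n in col[col > 0].items():
            row = genes.loc[gene]
            lo = int(row["lv_start"])
            hi = max(lo, int(row["lv_end"]) - read_length + 1)
            starts = rng.integers(lo, hi + 1, size=int(n))
            for k, st in enumerate(starts):
                recs.append(
                    ReadAlignment(
                        read_id=f"{lib}_{gene}_{k}",
                        chromosome=row["chromosome"],
                        start=int(st),
                        length=read_length,
                        mapq=99,
                        mismatch_quals=(),
                    )
                )
        for k in range(junk_per_library):
            recs.append(
                ReadAlignment(
                    read_id=f"{lib}_junk_{k}",
                    chromosome=config.chromosomes[0],
                    start=int(rng.integers(1, config.chromosome_length_bp)),
                    length=read_length,
                    mapq=0,
                    mismatch_quals=(30,),
                )
            )
        out[lib] = recs
    return out


# ---------------------------------------------------------------------------
# GO map, qPCR, full experiment


def simulate_go_map(config: SimulationConfig, annotation: GeneModels) -> pd.DataFrame:
    """Assign each gene 1–3 GO-slim categories uniformly at random."""
    rng = _rng(config, "go")
    rows = []
    cats = [f"GO:{i + 1:07d}" for i in range(config.n_go_categories)]
    for g in annotation.genes["gene_id"]:
        k = int(rng.integers(1, 4))
        for c in rng.choice(cats, size=k, replace=False):
            rows.append({"category": c, "gene": g})
    return pd.DataFrame(rows)


def simulate_qpcr(
    config: SimulationConfig,
    fold: float,
    n_replicates: int | None = None,
    noise_sd: float = 0.1,
) -> pd.DataFrame:
    """Simulate a comparative-CT table for one target with a known LoPro/HiPro fold.

    The reference (actin) CT is constant; the target CT in LoPro is lower
    than in HiPro by log2(fold), plus Normal noise, so the ΔΔCT method
    should recover ``fold``.
    """
    rng = _rng(config, "qpcr")
    n = n_replicates or config.n_replicates
    rows = []
    for geno in GENOTYPES:
        shift = -np.log2(fold) if geno == "LoPro" else 0.0
        for r in range(1, n + 1):
            rows.append(
                {
                    "genotype": geno,
                    "stage": 3,
                    "replicate": r,
                    "target_ct": 24.0 + shift + rng.normal(0.0, noise_sd),
                    "reference_ct": 20.0 + rng.normal(0.0, noise_sd),
                }
            )
    return pd.DataFrame(rows)


def simulate_experiment(config: SimulationConfig) -> SimulatedExperiment:
    """Generate a complete coordinated experiment.

    One truth-DE gene set drives both platforms, so cross-platform
    integration can be checked against a single truth table.
    """
    annotation, markers = simulate_annotation_and_markers(config)
    region = config.region
    rng = _rng(config, "counts")
    truth_de = _choose_de_genes(config, annotation, region, rng)
    intensities, coords, truth_sfps, _ = simulate_microarray(
        config, annotation, region, truth_de=truth_de
    )
    counts, _ = simulate_htts(config, annotation, region, truth_de=truth_de)
    gene_coords = annotation.genes.rename(columns={"gene_id": "feature"})[
        ["feature", "chromosome", "start", "end", "strand"]
    ].assign(platform="htts")
    coords_all = pd.concat(
        [coords[["feature", "chromosome", "start", "end", "strand", "platform"]],
         gene_coords],
        ignore_index=True,
    )
    go_map = simulate_go_map(config, annotation)
    return SimulatedExperiment(
        config=config,
        annotation=annotation,
        markers=markers,
        probe_intensities=intensities,
        probeset_coords=coords_all,
        truth_sfps=truth_sfps,
        counts=counts,
        truth_de=truth_de,
        go_map=go_map,
    )


def write_experiment(exp: SimulatedExperiment, outdir) -> dict[str, Path]:
    """Write every component of a simulated experiment to ``outdir``.

    Emits GFF3 gene models, the marker TSV, long-format probe intensities
    with the array design, the count matrix with the library design, the
    feature coordinate map, the GO map, and JSON truth tables.  Returns the
    path of each artifact.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "annotation": outdir / "annotation.gff3",
        "markers": outdir / "markers.tsv",
        "intensities": outdir / "intensities.tsv",
        "array_design": outdir / "array_design.tsv",
        "counts": outdir / "counts.tsv",
        "library_design": outdir / "library_design.tsv",
        "coords": outdir / "feature_coords.tsv",
        "go_map": outdir / "go_map.tsv",
        "truth": outdir / "truth.json",
    }
    sio.write_gff3(exp.annotation, paths["annotation"])
    sio.write_markers(exp.markers, paths["markers"])
    sio.write_intensities(
        exp.probe_intensities, paths["intensities"], paths["array_design"]
    )
    sio.write_counts(exp.counts, paths["counts"], paths["library_design"])
    exp.probeset_coords.to_csv(paths["coords"], sep="\t", index=False)
    exp.go_map.to_csv(paths["go_map"], sep="\t", index=False)
    sio.write_json(
        {
            "seed": exp.config.seed,
            "region": list(exp.config.introgression_interval),
            "truth_de": exp.truth_de.to_dict(orient="records"),
            "truth_sfps": exp.truth_sfps.to_dict(orient="records"),
        },
        paths["truth"],
    )
    return paths
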