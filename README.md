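# seedqtl

Candidate-gene nomination for a soybean seed-protein QTL from near-isogenic
line (NIL) transcriptome contrasts.

A pair of NILs — **LoPro** (recurrent *G. max* allele, low seed protein) and
**HiPro** (introgressed *G. soja* allele, high seed protein) — differ only in
a small introgressed segment of chromosome 20.  Any transcript-level
difference between the lines during seed fill must therefore trace back to
that segment.  This package implements the full computational arm of such a
study:

1. **Region demarcation** — the QTL interval is the span between the closest
   non-segregating SSR markers flanking the block of segregating markers
   (`seedqtl.region`).
2. **Expression-array differential accumulation** — quantile normalization,
   median-polish condensation of probe-level intensities (global linear
   median rescaled to 10,000), pooled t-tests with Benjamini–Hochberg FDR,
   a 1.5-fold ratio screen, and a balanced two-way genotype × stage ANOVA
   (`seedqtl.microarray`).
3. **Single-feature polymorphism (SFP) detection** — probe affinities
   estimated as log2(probe) − log2(probeset expression), screened with a
   moderated difference statistic and a genotype-label permutation FDR
   (`seedqtl.sfp`).
4. **Read-count differential accumulation** — mapping-quality/mismatch read
   retention, counting against each gene's longest splice variant,
   treatment-sum library normalization, and a two-tailed exact binomial test
   with a 2-fold screen (`seedqtl.htts`).
5. **Integration and validation** — coordinate-overlap clustering of DE
   features from both platforms into region candidates, Fisher/Bonferroni GO
   enrichment, and comparative-CT (ΔΔCT) qRT-PCR folds
   (`seedqtl.integrate`).
6. **Synthetic experiments with ground truth** — a seeded generator that
   produces every input the pipeline consumes (gene models, markers, probe
   intensities with injected DE and SFPs, read counts, alignments, GO map)
   plus truth tables, so each stage's recovery can be verified
   (`seedqtl.simulate`).
7. **I/O and a thin CLI** — validated readers/writers for GFF3, marker/count
   /intensity TSVs, BED, a minimal SAM subset, and a `seedqtl` command with
   one subcommand per stage (`seedqtl.io`, `seedqtl.cli`,
   `seedqtl.pipeline`).

Small published reference tables (border markers, the 13-probeset genotype
contrast, the 21-row read-count screen, per-library totals) ship with the
package in `seedqtl.datasets` so the screening rules can be audited without
external data.

## Quick start

```python
from seedqtl import SimulationConfig, simulate_experiment
from seedqtl.region import demarcate_region, markers_from_frame
from seedqtl.microarray import quantile_normalize, median_polish_condense, genotype_contrast

config = SimulationConfig(seed=1, n_genes=200, n_probesets=60, n_markers=12,
                          library_depth_range=(20_000, 30_000))
experiment = simulate_experiment(config)

region = demarcate_region(markers_from_frame(experiment.markers),
                          chrom_length=config.chromosome_length_bp)
print(region)            # Region(chromosome='chr1', start=2727273, end=5454545)

expr = median_polish_condense(quantile_normalize(experiment.probe_intensities))
contrast = genotype_contrast(expr)
print(int(contrast["significant"].sum()), "significant probesets")
```

The same flow from the shell:

```sh
seedqtl simulate --outdir /tmp/exp --seed 1
seedqtl demarcate --markers /tmp/exp/markers.tsv
seedqtl htts-de --counts /tmp/exp/counts.tsv --design /tmp/exp/library_design.tsv \
    --out /tmp/exp/htts_de.tsv
```

or end-to-end via `seedqtl run-all --config pipeline.yaml` (see
`seedqtl.pipeline.PipelineConfig` for the keys).

## Examples

`examples/` contains one short narrative script per capability:

| script | shows |
|---|---|
| `01_simulate_and_demarcate.py` | generator + marker-based region demarcation |
| `02_microarray_de.py` | condensation, genotype contrast, ANOVA |
| `03_sfp_detection.py` | affinity estimation and SFP calling vs truth |
| `04_htts_de.py` | count normalization and the exact binomial screen |
| `05_integrate_and_validate.py` | candidate integration, enrichment, ΔΔCT |
| `06_published_tables.py` | screens re-applied to the embedded published tables |

Each runs in a few seconds: `python examples/01_simulate_and_demarcate.py`.

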