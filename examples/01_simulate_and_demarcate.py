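"""Generate a synthetic NIL experiment and demarcate the QTL region.

The generator injects a contiguous introgression on chr1; the segregating
markers inside it, bracketed by the closest non-segregating markers, define
the region every later stage works within.
"""

from seedqtl import SimulationConfig, simulate_experiment
from seedqtl.region import demarcate_region, genes_in_region, markers_from_frame

config = SimulationConfig(seed=1, n_genes=200, n_probesets=60, n_markers=12,
                          library_depth_range=(20_000, 30_000))
experiment = simulate_experiment(config)

print(f"genes: {len(experiment.annotation)}  markers: {len(experiment.markers)}")
print(f"injected introgression: {config.introgression_interval}")

markers = markers_from_frame(experiment.markers)
region = demarcate_region(markers, chrom_length=config.chromosome_length_bp)
print(f"demarcated region: {region.chromosome}:{region.start}-{region.end} "
      f"({region.span_bp / 1e6:.2f} Mbp)")

region_genes = genes_in_region(experiment.annotation.genes, region)
print(f"{len(region_genes)} gene models overlap the region; "
      f"{len(experiment.truth_de)} carry an injected expression difference")
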