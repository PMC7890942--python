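"""Scan deletion sites for selection signatures with ΔAF and RFD.

ΔAF = |f_focal - mean(f_ref)| and RFD = (f_focal - mean(f_ref))/f_pooled
are computed over all eligible deletions (<=100 kb, pooled frequency
>=0.01); each statistic is thresholded at its empirical top 5% and a site
is significant only when it is in both tails. Significant sites within
100 kb are merged into candidate selection regions.
"""

import numpy as np

from svsweep import (
    SimulationConfig,
    allele_frequencies,
    build_regions,
    scan_deletions,
    simulate_truth,
)
from svsweep.annotate import attach_genes, count_distinct_genes
from svsweep.simulate import simulate_genes

config = SimulationConfig(
    seed=3,
    n_sites={"DEL": 3000},
    genome=tuple((f"chr{i + 1}", 20_000_000) for i in range(6)),
    populations=(("MS", 50), ("DU", 50), ("TB", 50)),
    n_selected_sites=30, selected_focal_af=0.9, selected_ref_af=0.1,
)
truth = simulate_truth(config)
records = allele_frequencies(truth.genotypes, truth.popmap)
results = scan_deletions(records, truth.popmap)
regions = attach_genes(build_regions(results), simulate_genes(config, n_genes=150))

sig = [r for r in results if r.significant]
planted = {sv.site_id for sv, sel in zip(truth.svs, truth.selected) if sel}
recovered = sum(1 for r in sig if r.site_id in planted)
print(f"scanned {len(results)} deletion sites; "
      f"{sum(r.pass_daf for r in results)} in the ΔAF tail, "
      f"{sum(r.pass_rfd for r in results)} in the RFD tail, "
      f"{len(sig)} significant in both")
print(f"planted selected sites recovered: {recovered}/{len(planted)}")
print(f"selection regions: {len(regions)}; "
      f"distinct genes covered: {count_distinct_genes({r: r.genes for r in regions})}")
print(f"max ΔAF = {max(r.delta_af for r in results):.3f}, "
      f"max RFD = {max(r.rfd for r in results):.3f}")
print("\nThe intersection rule keeps the significant fraction below 5% while")
print("deletions planted at ΔAF=0.8 stand far outside both null tails.")
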