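"""Classify SVs relative to gene models.

Each SV gets one class by fixed precedence: exonic if it touches any exon,
else intronic inside a gene span, else upstream/downstream when within 1 kb
of a gene (strand-aware), else intergenic.
"""

from svsweep import SimulationConfig, merge_callsets, simulate_callsets, simulate_truth
from svsweep.annotate import class_distribution

config = SimulationConfig(seed=19, n_sites={"DEL": 400, "INS": 40, "DUP": 20})
truth = simulate_truth(config)
consensus = merge_callsets(simulate_callsets(truth))

from svsweep.simulate import simulate_genes

genes = simulate_genes(config, n_genes=200)
table = class_distribution(consensus, genes)
print(f"{len(consensus)} consensus SVs vs {len(genes)} simulated genes:")
print(table.to_string(index=False))
print("\nWith ~200 genes of 5-50 kb on a 75 Mb genome most SVs fall in")
print("intergenic space; the exonic/intronic split follows exon density.")
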