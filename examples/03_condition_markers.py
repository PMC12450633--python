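"""Condition marker genes: disease-upregulated ∩ pathway gene sets.

The disease-vs-normal contrast inside the disease-skewed subtype is
filtered for upregulated genes, then intersected with the union of two
GO-style pathway gene sets (fatty acid metabolic process, small-molecule
catabolic process). The intersection is the marker set.
"""

from hepacre.markers import intersect_with_pathways, upregulated_in_condition
from hepacre.synthetic import (
    SyntheticConfig,
    generate_condition_deg_table,
    generate_pathways,
)

config = SyntheticConfig(seed=42)
degs = generate_condition_deg_table(config)
pathways = generate_pathways(config)

upregulated = upregulated_in_condition(degs, "HTN_vs_normal")
markers, venn = intersect_with_pathways(upregulated, pathways)

print(f"{len(upregulated)} upregulated genes in the disease contrast")
print(f"{len(markers)} markers: {', '.join(sorted(markers))}")
print("Venn regions:", {k: v for k, v in venn.items() if v})
# The markers are the genes both differentially expressed under disease and
# annotated to the disease-relevant metabolic pathways.
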