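"""Generate a atlas-shaped synthetic single-cell dataset and inspect it.

Six imbalanced cell types (one rare, one transcriptionally dominant),
negative-binomial counts with dropout, and disjoint planted marker genes.
"""

from shapcell import generate_dataset, muscle_atlas_config

config = muscle_atlas_config(scale=0.12, seed=7)
matrix, truth = generate_dataset(config)

print(f"cells x genes: {matrix.n_cells} x {matrix.n_genes}")
print(f"type counts:   {matrix.class_counts()}")
print(f"dominant type: {truth.dominant_type} (markers get twice the fold change)")
for t, markers in truth.marker_map.items():
    print(f"  {t}: markers {markers[:3]} ... ({len(markers)} total)")

# The counts above are the ground truth every downstream stage is tested
# against: the marker map says which genes each type over-expresses, and the
# dominant type is the one the importance ranking should place first.
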