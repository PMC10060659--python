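"""Generate a synthetic grazing x phosphorus soil community and inspect it.

The generator plants two reciprocal dominant species that together hold ~50%
of relative abundance and carry genes in every functional category, plus 188
noise species.  Treatments shift abundance from the sensitive dominant (A) to
its complement (R) while per-category functional totals stay conserved.
"""

from redunet import SyntheticDesign, aggregate, generate, top_features

design = SyntheticDesign(seed=1)
table, catalog, metadata, truth = generate(design)

print(f"samples: {len(table.samples)}   genes: {len(table.features)}")
print(f"functional classes: {catalog.frame['func_class'].value_counts().to_dict()}")

species = aggregate(table, catalog, by="species")
top12, coverage = top_features(species, 12)
print(f"top-12 species cover {coverage:.1%} of total abundance "
      "(the study community reports >95%)")

rel = species.data.div(species.data.sum(axis=1), axis=0)
share = rel.groupby(metadata["treatment"]).mean()
print("\nmean share of the two dominants per treatment:")
print(share[[truth.species_a, truth.species_r]].round(3))
print("\nPlanted reciprocal shifts (delta):", truth.delta)
print("Under G+P+ the A share drops by ~0.10 and the R share rises by ~0.10; "
      "their sum stays ~0.50 in every treatment.")
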