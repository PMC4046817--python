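#!/usr/bin/env python
"""Classify the called regions by genomic context (intergenic-overlap vs
intragenic, by number of ORFs touched) and signed distance from each peak
center to the nearest transcription start site."""

from common import RESULTS, analysis_config, get_dataset

from chiptile import annotate, pipeline

files = get_dataset()
results = pipeline.run_pipeline(analysis_config(files))
genome = results["genome"]

annos = annotate.annotate_regions(results["regions"], genome)
table = annotate.annotation_table(annos)
table.to_csv(RESULTS / "regions_annotated.tsv", sep="\t", index=False)

counts = annotate.category_counts(annos)
two_way = annotate.two_way_split(counts)
n = len(annos)
print(f"location categories for {n} regions:")
for cat, c in counts.items():
    print(f"  {cat:32} {c}")
print(
    f"two-way split: {two_way['overlaps_intergenic']}/{n} overlap intergenic sequence, "
    f"{two_way['intragenic_only']}/{n} are exclusively intragenic"
)
print("signed peak-center -> nearest-TSS distances (negative = upstream of gene):")
print(table[["start", "end", "closest_gene_id", "tss_distance"]].to_string(index=False))
print(f"table written to {RESULTS / 'regions_annotated.tsv'}")
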