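#!/usr/bin/env python
"""Simulate the study-condition dataset: a 200 kb circular genome with 60
ORFs, eight planted Lrp-box words of graded affinity (two of them blocked
by non-permissive chromatin), and tiling arrays for three ChIP replicates
plus a mock at 25 bp probe spacing with technical duplicates."""

import pandas as pd

from common import CONFIG, DATASET, get_dataset

files = get_dataset()
truth = pd.read_csv(files["truth"], sep="\t")

print(f"dataset written to {DATASET}")
print(
    f"genome: {CONFIG.genome_length:,} bp circular, {CONFIG.n_genes} ORFs, "
    f"probes every {CONFIG.probe_step} bp (x2 duplicates), noise sd {CONFIG.noise_sd}"
)
print(f"planted sites ({len(truth)}; occupancy = P/(K_D+P) at P = {CONFIG.protein_conc:g} M):")
print(
    truth.assign(realized_kd_nm=(truth["realized_kd"] * 1e9).round(1))[
        ["position", "strand", "word", "realized_kd_nm", "permissive", "occupancy"]
    ].round({"occupancy": 3}).to_string(index=False)
)
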