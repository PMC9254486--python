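"""Linking R-loop occupancy to nascent transcription.

Transcripts are binned into expression quartiles; R-loop peaks link to
transcripts by strand-matched overlap.  The generator plants 4:1 odds of
R-loop formation in the top quartile, so about 4/7 = 57% of R-loop genes
should come from Q4, and no expression shift for sample-specific R-loop
genes, so the median expression difference should sit near zero.
"""

import rloopscape as rl

ds = rl.generate_dataset(
    rl.SimulationConfig(seed=11, samples=("S2", "embryo_2_3h"))
)
links = {
    s: rl.link_rloops_to_genes(ds.tracks.rloops[s], ds.tracks.transcripts)
    for s in ds.config.samples
}
expr = {s: rl.assign_quartiles(ds.tracks.expression[s]) for s in ds.config.samples}

occ = rl.quartile_occupancy(links["S2"], expr["S2"])
print("S2 quartile occupancy of R-loop genes (expected 25% each if uncoupled):")
print(occ.round(4).to_string(index=False))
print("planted 4:1 top-quartile odds -> expected Q4 share 4/7 = 0.571\n")

means = rl.peaks_per_gene_by_quartile(links["S2"], expr["S2"])
print("mean R-loop peaks per positive gene by quartile:")
print(means.round(3).to_string())

res = rl.specificity_vs_expression(
    links["S2"], links["embryo_2_3h"],
    ds.tracks.expression["S2"], ds.tracks.expression["embryo_2_3h"],
    name_a="S2", name_b="embryo_2_3h",
)
print(f"\n{res.n_genes} genes with sample-specific R-loops; "
      f"median FPKM difference {res.median_delta:+.3f} "
      f"(sign-test p = {res.sign_test_p:.3f})")
print("-> specificity is not driven by expression differences in this dataset")
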