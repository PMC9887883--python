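"""Simulate a small-RNA library and classify its reads.

Builds a 60-gene annotation with planted WAGO/CSR-1 target classes,
simulates an input library of 10,000 reads, and classifies every read
into {22G, piRNA, miRNA, other, unassigned}.  The class percentages
mirror the mixture the generator was configured with (80% 22G-class).
"""

from srnakit import SampleSpec, SimConfig, build_truth, classify_frame, quantify, simulate_library

config = SimConfig(n_mrna=60, n_pirna=8, n_mirna=4, n_wago=10, n_csr1=15, n_both=3)
genes, truth = build_truth(config, seed=7)
frame, sidecar = simulate_library(genes, truth, SampleSpec("demo_input", depth=10_000))

labeled = classify_frame(frame, genes)
print("read-class breakdown (counts):")
print(labeled["label"].value_counts().to_string())
print()

ct = quantify(frame, genes, class_filter="22G", sample_id="demo_input")
top = ct.rpm.sort_values(ascending=False).head(5)
print("top 5 genes by 22G-RNA RPM (reads per million, total =", ct.total, "reads):")
print(top.round(1).to_string())
print()
print("Each RPM value is the gene's unique 22-nt antisense read count")
print("scaled by 1e6 / total mapped reads in the sample.")
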