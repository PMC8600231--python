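"""Differential-expression filtering and upregulated-TF selection.

A gene is differentially expressed when |log2 fold change| >= 1 with
BH-adjusted p < 0.01 at month 2 or month 3 versus month 1 (Welch test on
log2(FPKM+1) replicates).  Upregulated TFs are the input to the network
stages.
"""

from xylemtrn import (
    ddct,
    differential_genes,
    generate_reference_dataset,
    select_upregulated_tfs,
)

ds = generate_reference_dataset(seed=1)
de = differential_genes(ds.expression, alpha=0.01, lfc_threshold=1.0)

n_deg = int(de["deg"].sum())
print(f"DEGs: {n_deg} of {len(de)} genes")
for tag in ("2v1", "3v1"):
    up = int((de[f"direction_{tag}"] == "up").sum())
    down = int((de[f"direction_{tag}"] == "down").sum())
    print(f"  month {tag[0]} vs 1: {up} up, {down} down")

tfs = select_upregulated_tfs(de, ds.catalog)
print(f"upregulated TFs (master switches included): {len(tfs)}")
# 124 = 8 WND + 116 TFs whose promoters the scanning stage will analyze.

# qPCR sanity check of one transcript: 2^-ddCt relative expression
rel = ddct(ct_target_sample=20, ct_ref_sample=18,
           ct_target_calibrator=22, ct_ref_calibrator=18)
print(f"2^-ddCt example: {rel:.1f}x the calibrator level")
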