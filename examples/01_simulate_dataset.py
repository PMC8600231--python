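"""Generate the study-composition synthetic dataset and inspect its truth.

Builds a catalog of 479 genes (8 WND master switches, 126 TFs, 98 cell wall
genes, 47 PCD genes, 200 background), 2-kb promoters with planted
cis-elements, and three-stage expression/proteome matrices with planted
trajectories and concordance labels.
"""

from collections import Counter

from xylemtrn import generate_reference_dataset

ds = generate_reference_dataset(seed=1)

print(f"catalog: {len(ds.catalog)} genes")
roles = Counter(e.role for e in ds.catalog)
print("  roles:", dict(roles))
print(f"promoters: {len(ds.promoters)} x {ds.window} bp")
print(f"expression: {ds.expression.shape[0]} genes x {ds.expression.shape[1]} samples")
print(f"proteome: {ds.proteome.shape[0]} proteins")

elements = Counter(el.motif_name for el in ds.truth.planted_elements)
print("planted elements:", dict(elements))
trajectories = Counter(ds.truth.planted_trajectory.values())
print("planted trajectories:", dict(trajectories))
concordance = Counter(ds.truth.planted_concordance.values())
print("planted concordance:", dict(concordance))
# The planted composition is what the downstream stages must recover:
# 124 rising TFs (8 WND + 116 scanned), a 9/14/93 SNBE/SMRE partition,
# and 121 consistent / 72 discordant proteins.
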