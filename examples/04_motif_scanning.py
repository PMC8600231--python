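"""Degenerate cis-element scanning of promoter windows.

Parses degenerate consensus notation (e.g. the 7-bp SMRE
"ACC(A/T)A(A/C)(T/C)"), scans both strands of each 2-kb promoter, and
partitions the scanned TFs by SNBE/SMRE presence.
"""

from xylemtrn import (
    element_profiles,
    expand_variants,
    parse_consensus,
    scan,
    scan_promoters,
    generate_reference_dataset,
)

smre = parse_consensus("ACC(A/T)A(A/C)(T/C)", name="SMRE")
print(f"SMRE: {len(smre)} bp, {smre.variant_count} variants:")
print("  " + " ".join(expand_variants(smre)))

# a minus-strand match is reported in promoter-forward coordinates
hits = scan("GGATTAGGTCC", smre)
for h in hits:
    print(f"hit at [{h.start}, {h.end}) strand {h.strand}: {h.matched_seq}")

ds = generate_reference_dataset(seed=1)
all_hits = scan_promoters(ds.promoters, ds.motifs)
scanned_tfs = [e.gene_id for e in ds.catalog.with_role("TF")
               if ds.truth.planted_trajectory[e.gene_id] != "flat"]
profiles, partition = element_profiles(
    [h for h in all_hits if h.gene_id in set(scanned_tfs)],
    list(ds.motifs), scanned_tfs,
)
print(f"scanned {len(scanned_tfs)} upregulated TF promoters:")
print(f"  SNBE only: {partition['snbe_only']}, SMRE only: {partition['smre_only']}, "
      f"both: {partition['both']}, neither: {partition['neither']}")
# TFs with only SNBE sit directly under the WND master switches (layer 2);
# TFs with SMRE (alone or with SNBE) are MYB targets (layer 3).
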