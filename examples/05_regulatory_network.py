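"""Four-layer transcriptional regulatory network from element profiles.

Layer 1: WND master switches (by role).  Layer 2: SNBE-only TFs.  Layer 3:
TFs with SMRE (alone or with SNBE).  Layer 4: cell wall and PCD effector
genes.  Edges run strictly downward, each mediated by a cis-element present
in the target's promoter.
"""

from xylemtrn import (
    assign_layers,
    build_edges,
    differential_genes,
    element_profiles,
    export_network,
    generate_reference_dataset,
    scan_promoters,
    select_upregulated_tfs,
    summarize,
)

ds = generate_reference_dataset(seed=1)
de = differential_genes(ds.expression)
upregulated = select_upregulated_tfs(de, ds.catalog)

hits = scan_promoters(ds.promoters, ds.motifs)
candidates = {e.gene_id for e in ds.catalog
              if e.role in ("TF", "CW_secondary", "CW_primary", "PCD")}
profiles, _ = element_profiles(
    [h for h in hits if h.gene_id in candidates], list(ds.motifs), sorted(candidates)
)

nodes, unplaced = assign_layers(profiles, ds.catalog, upregulated)
edges = build_edges(nodes, profiles)
report = summarize(nodes, edges, unplaced)

print("nodes per layer:", report["per_layer"])
print("edges per element:", report["edges_per_element"])
print(f"unplaced TFs (no SNBE/SMRE): {report['n_unplaced']}")

written = export_network(nodes, edges, "scratch_trn.edges.tsv", fmt="edgelist")
print("wrote:", ", ".join(str(p) for p in written))
# Every edge is acyclic by construction (source layer < target layer) and
# soundly mediated: its element occurs in the target promoter.
tgtg_edges = [e for e in edges if e.element == "TGTG"]
print(f"NAC072/NAC045-class -> PCD edges via TGTG: {len(tgtg_edges)}")
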