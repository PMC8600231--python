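"""Proteome differential filter and transcript-protein concordance.

Differential proteins pass fold change >= 2 or <= 0.5 with BH-adjusted
p < 0.05.  Each protein's per-comparison direction is compared with its
transcript's: agreement at every jointly significant comparison means
'consistent'; any disagreement means 'discordant' — the candidate list for
post-translational regulation.
"""

from xylemtrn import (
    concordance,
    differential_genes,
    differential_proteins,
    generate_reference_dataset,
    ptm_candidates,
)

ds = generate_reference_dataset(seed=1)
de = differential_genes(ds.expression)
prot_de = differential_proteins(ds.proteome, fc_threshold=2.0, alpha=0.05)

print(f"differential proteins: {int(prot_de['dp'].sum())} of {len(prot_de)}")

table, summary = concordance(de, prot_de, ds.protein_gene_map)
print(f"concordance: {summary['consistent']} consistent, "
      f"{summary['discordant']} discordant, {summary['untestable']} untestable")

candidates = ptm_candidates(table)
print(f"PTM candidates (discordant proteins): {len(candidates)}, e.g. {candidates[:3]}")
# A discordant protein rises while its transcript falls (or vice versa),
# pointing to regulation beyond transcript abundance.
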