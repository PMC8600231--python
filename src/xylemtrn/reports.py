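"""Consistency arithmetic over the study's published summary counts.

The genome-scale results of the underlying three-stage poplar xylem study
(12,916 DEGs, 445 differential proteins, the Fig-4 network membership)
derive from deposited raw sequencing/proteomics data and are not
recomputable at desk scale.  What *is* recomputable is the study's internal
arithmetic: group totals from the printed per-cluster sizes, the scanned-TF
total from the printed element partition and independently from the
upregulated-TF and master-switch counts, and the network input totals.
:func:`consistency_report` performs that arithmetic from the shipped
printed-counts table (or any user-supplied one with the same schema).
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

from .errors import ValidationError
from .motifs import default_motifs

DEFAULT_PROMOTER_WINDOW = 2000


def load_reported_counts(path: str | Path | None = None) -> dict:
    """The published summary-count table (shipped copy by default)."""
    if path is None:
        source = resources.files("xylemtrn.data") / "reported_counts.json"
        return json.loads(source.read_text())
    return json.loads(Path(path).read_text())


def group_total(counts: dict, group: str) -> int:
    """Total genes in a trajectory group, summed from printed cluster sizes.

    Groups whose per-cluster sizes were not printed fall back to the printed
    group total.
    """
    sizes = counts["cluster_sizes"]
    members = [c for c, g in counts["cluster_groups"].items() if g == group]
    if members:
        missing = [c for c in members if c not in sizes]
        if missing:
            raise ValidationError(f"cluster sizes missing for clusters {missing}")
        return sum(sizes[c] for c in members)
    if group in counts.get("group_totals", {}):
        return counts["group_totals"][group]
    raise ValidationError(f"no printed information for group {group!r}")


def consistency_report(counts: dict | None = None) -> dict:
    """Recompute the study's internal arithmetic from printed inputs.

    Returns the derived quantities with, where two independent derivations
    exist, both routes reported side by side.
    """
    if counts is None:
        counts = load_reported_counts()
    partition = counts["element_partition"]
    motifs = default_motifs()
    return {
        "group_I_total": group_total(counts, "I"),
        "group_III_total": group_total(counts, "III"),
        "group_II_total": group_total(counts, "II"),
        "group_IV_total": group_total(counts, "IV"),
        "scanned_tfs_from_partition": sum(partition.values()),
        "scanned_tfs_from_upregulated": counts["upregulated_tfs"]
        - counts["wnd_master_switches"],
        "trn_input_tfs": counts["trn_tfs_known_function"]
        + counts["trn_tfs_unknown_function"],
        "trn_input_total": counts["trn_tfs_known_function"]
        + counts["trn_tfs_unknown_function"]
        + counts["cw_genes"]
        + counts["pcd_genes"],
        "cw_genes_from_split": counts["cw_secondary"] + counts["cw_primary"],
        "smre_length": len(motifs["SMRE"]),
        "smre_variant_count": motifs["SMRE"].variant_count,
        "tgtg_variant_count": motifs["TGTG"].variant_count,
        "default_promoter_window": DEFAULT_PROMOTER_WINDOW,
    }
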