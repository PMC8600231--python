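{
  "comment": "Summary counts reported for the three-stage (1/2/3-month) poplar xylem development study that this package's pipeline re-implements. Used by xylemtrn.reports.consistency_report to recompute the study's internal arithmetic (group totals from cluster sizes, scanned-TF totals, network input totals) from these printed inputs.",
  "cluster_sizes": {"1": 1045, "2": 846, "3": 1049, "7": 1763, "8": 2505, "9": 2199},
  "cluster_groups": {"1": "I", "2": "I", "3": "I", "7": "III", "8": "III", "9": "III"},
  "group_totals": {"II": 417, "IV": 251},
  "degs_total": 12916,
  "deg_up_2v1": 2494,
  "deg_down_2v1": 4844,
  "deg_up_3v1": 3450,
  "deg_down_3v1": 7126,
  "upregulated_tfs": 124,
  "wnd_master_switches": 8,
  "element_partition": {"snbe_only": 9, "smre_only": 14, "both": 93},
  "trn_tfs_known_function": 10,
  "trn_tfs_unknown_function": 50,
  "cw_genes": 98,
  "cw_secondary": 90,
  "cw_primary": 8,
  "pcd_genes": 47,
  "pcd_with_tgtg": 40,
  "cw_without_snbe": 14,
  "cw_with_both": 84,
  "proteins_detected": 3657,
  "proteins_differential": 445,
  "proteins_consistent": 121,
  "proteins_discordant": 72
}
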