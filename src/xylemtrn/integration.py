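"""Proteome differential filter and transcript-protein concordance.

Differential proteins pass a raw fold-change filter (ratio of stage means
>= 2 or <= 0.5) with BH-adjusted p < 0.05 at one or both of the
month-2-vs-1 / month-3-vs-1 comparisons; the significance test and BH
machinery are the same as for transcripts (Welch on log2(x+1) replicates).

Concordance compares per-comparison direction calls between a protein and
its transcript: *consistent* if the signs agree at every comparison where
both are significant (and at least one such comparison exists), *discordant*
if they disagree at one or more jointly significant comparisons, otherwise
*untestable*.  Discordant proteins are the pipeline's candidate list for
post-translational regulation.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .expression import COMPARISONS, stage_columns

logger = logging.getLogger(__name__)

_TAGS = ("2v1", "3v1")


def differential_proteins(
    matrix: pd.DataFrame,
    fc_threshold: float = 2.0,
    alpha: float = 0.05,
    pseudocount: float = 0.0,
) -> pd.DataFrame:
    """Differential-protein table with raw fold changes of stage means.

    ``fc_*`` is mean(contrast)/mean(reference) on the raw abundance scale
    (with the configurable pseudocount, default 0).  A zero reference mean
    without pseudocount yields an infinite fold change, which passes the
    magnitude criterion and is logged.  ``dp`` is the overall flag.
    """
    if fc_threshold <= 1:
        raise ValidationError(f"fc_threshold must exceed 1, got {fc_threshold}")
    if (matrix.to_numpy() < 0).any():
        raise ValidationError("protein abundances must be nonnegative")
    stages = stage_columns(matrix)
    lower = 1.0 / fc_threshold
    out = pd.DataFrame(index=matrix.index)
    for (ref, con), tag in zip(COMPARISONS, _TAGS):
        for s in (ref, con):
            if s not in stages:
                raise ValidationError(f"stage {s!r} not present in matrix")
            if len(stages[s]) < 2:
                raise ValidationError(f"stage {s!r} needs at least 2 replicates")
        a = matrix[stages[ref]].to_numpy()
        b = matrix[stages[con]].to_numpy()
        mean_a = a.mean(axis=1) + pseudocount
        mean_b = b.mean(axis=1) + pseudocount
        with np.errstate(divide="ignore", invalid="ignore"):
            fc = np.where(mean_a > 0, mean_b / mean_a, np.inf)
        n_inf = int(np.isinf(fc).sum())
        if n_inf:
            logger.warning(
                "%d protein(s) with zero reference mean in %s: fold change set to "
                "infinity (passes the magnitude criterion)", n_inf, tag,
            )
        tt = stats.ttest_ind(
            np.log2(b + 1.0), np.log2(a + 1.0), axis=1, equal_var=False
        )
        p = np.where(np.isnan(tt.pvalue), 1.0, tt.pvalue)
        padj = multipletests(p, method="fdr_bh")[1]
        sig = padj < alpha
        direction = np.where(
            sig & (fc >= fc_threshold), "up",
            np.where(sig & (fc <= lower), "down", "ns"),
        )
        out[f"fc_{tag}"] = fc
        out[f"p_{tag}"] = p
        out[f"padj_{tag}"] = padj
        out[f"direction_{tag}"] = direction
    out["dp"] = (out["direction_2v1"] != "ns") | (out["direction_3v1"] != "ns")
    return out


def concordance(
    transcript_de: pd.DataFrame,
    protein_de: pd.DataFrame,
    mapping: Mapping[str, str],
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Per-protein concordance labels plus a summary count.

    *mapping* resolves protein_id -> gene_id (each protein to at most one
    gene).  Returns (table, summary); the table is indexed by protein_id
    with the mapped gene, the per-comparison transcript/protein direction
    pairs, and the label; the summary counts consistent / discordant /
    untestable proteins and partitions all proteins in *protein_de*.
    """
    rows = []
    for protein_id in protein_de.index:
        gene_id = mapping.get(protein_id)
        row = {"protein_id": protein_id, "gene_id": gene_id or ""}
        if gene_id is None or gene_id not in transcript_de.index:
            logger.warning("protein %s has no mapped transcript; untestable", protein_id)
            row.update({f"t_dir_{t}": "na" for t in _TAGS})
            row.update({f"p_dir_{t}": protein_de.at[protein_id, f"direction_{t}"] for t in _TAGS})
            row["label"] = "untestable"
            rows.append(row)
            continue
        joint_signs: list[tuple[str, str]] = []
        for tag in _TAGS:
            t_dir = transcript_de.at[gene_id, f"direction_{tag}"]
            p_dir = protein_de.at[protein_id, f"direction_{tag}"]
            row[f"t_dir_{tag}"] = t_dir
            row[f"p_dir_{tag}"] = p_dir
            if t_dir != "ns" and p_dir != "ns":
                joint_signs.append((t_dir, p_dir))
        if not joint_signs:
            row["label"] = "untestable"
        elif all(t == p for t, p in joint_signs):
            row["label"] = "consistent"
        else:
            row["label"] = "discordant"
        rows.append(row)
    table = pd.DataFrame(rows).set_index("protein_id")
    summary = {
        label: int((table["label"] == label).sum())
        for label in ("consistent", "discordant", "untestable")
    }
    return table, summary


def ptm_candidates(concordance_table: pd.DataFrame) -> list[str]:
    """Discordant proteins, the candidate targets for PTM follow-up."""
    return sorted(concordance_table.index[concordance_table["label"] == "discordant"])
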