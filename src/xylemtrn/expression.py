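"""Differential expression, trajectory grouping, soft clustering, qPCR utility.

Expression matrices are pandas DataFrames indexed by gene id with replicate
columns named ``M1_r1 ... M3_r3`` (month, replicate), on an FPKM-like
nonnegative scale.  All fold changes are computed on log2(x + pseudocount).

Differential genes pass |log2FC| >= 1 with Benjamini-Hochberg adjusted
p < 0.01 in at least one of the month-2-vs-1 / month-3-vs-1 comparisons.
The per-gene test is a Welch two-sample t-test on log2(x+1) replicate
values — the upstream study does not name its RNA-seq caller, so this
self-contained test stands in for it; results on real count data will
differ from a count-model caller.
"""

from __future__ import annotations

import math
import re
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .catalog import GeneCatalog
from .clustering import FuzzyCMeansResult, fuzzy_cmeans
from .errors import ValidationError

COMPARISONS = (("M1", "M2"), ("M1", "M3"))  # (reference, contrast)
GROUPS = ("I", "II", "III", "IV", "flat")

_COL_RE = re.compile(r"^(M\d+)_r(\d+)$")


def stage_columns(matrix: pd.DataFrame) -> dict[str, list[str]]:
    """Map stage name ('M1', ...) to its replicate columns, in column order."""
    stages: dict[str, list[str]] = {}
    for col in matrix.columns:
        m = _COL_RE.match(str(col))
        if not m:
            raise ValidationError(f"column {col!r} does not follow the M<stage>_r<rep> naming")
        stages.setdefault(m.group(1), []).append(col)
    return stages


def read_matrix(path: str | Path) -> pd.DataFrame:
    matrix = pd.read_csv(path, sep="\t", index_col=0)
    stage_columns(matrix)  # validates column naming
    return matrix


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t")


def _check_nonnegative(matrix: pd.DataFrame) -> None:
    if (matrix.to_numpy() < 0).any():
        raise ValidationError("expression values must be nonnegative")


def log2_fold_change(
    matrix: pd.DataFrame,
    comparison: tuple[str, str] = ("M1", "M2"),
    pseudocount: float = 1.0,
) -> pd.Series:
    """Per-gene log2 fold change of stage b over stage a.

    log2FC = mean over b replicates of log2(x + pseudocount) minus the same
    mean over a replicates; exactly antisymmetric under swapping a and b.
    """
    _check_nonnegative(matrix)
    stages = stage_columns(matrix)
    a, b = comparison
    for s in (a, b):
        if s not in stages:
            raise ValidationError(f"stage {s!r} not present in matrix")
    la = np.log2(matrix[stages[a]].to_numpy() + pseudocount).mean(axis=1)
    lb = np.log2(matrix[stages[b]].to_numpy() + pseudocount).mean(axis=1)
    return pd.Series(lb - la, index=matrix.index, name=f"log2fc_{b}v{a}")


def differential_genes(
    matrix: pd.DataFrame,
    alpha: float = 0.01,
    lfc_threshold: float = 1.0,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Differential-expression table over the M2-vs-M1 and M3-vs-M1 comparisons.

    Returns a DataFrame indexed by gene id with, per comparison ``2v1``/``3v1``:
    ``log2fc_*``, raw ``p_*``, BH-adjusted ``padj_*`` (adjusted within the
    comparison across all genes), ``direction_*`` in {up, down, ns}; plus the
    overall ``deg`` flag (significant in at least one comparison).
    """
    _check_nonnegative(matrix)
    stages = stage_columns(matrix)
    out = pd.DataFrame(index=matrix.index)
    for (ref, con), tag in zip(COMPARISONS, ("2v1", "3v1")):
        for s in (ref, con):
            if s not in stages:
                raise ValidationError(f"stage {s!r} not present in matrix")
            if len(stages[s]) < 2:
                raise ValidationError(
                    f"stage {s!r} has {len(stages[s])} replicate(s); the significance "
                    f"test needs at least 2 — a fold-change-only screen must be run "
                    f"explicitly via log2_fold_change"
                )
        la = np.log2(matrix[stages[ref]].to_numpy() + pseudocount)
        lb = np.log2(matrix[stages[con]].to_numpy() + pseudocount)
        lfc = lb.mean(axis=1) - la.mean(axis=1)
        # Welch (unequal-variance) t-test per gene on log2 replicate values
        tt = stats.ttest_ind(lb, la, axis=1, equal_var=False)
        p = np.where(np.isnan(tt.pvalue), 1.0, tt.pvalue)
        padj = multipletests(p, method="fdr_bh")[1]
        sig = padj < alpha
        direction = np.where(
            sig & (lfc >= lfc_threshold), "up",
            np.where(sig & (lfc <= -lfc_threshold), "down", "ns"),
        )
        out[f"log2fc_{tag}"] = lfc
        out[f"p_{tag}"] = p
        out[f"padj_{tag}"] = padj
        out[f"direction_{tag}"] = direction
    out["deg"] = (out["direction_2v1"] != "ns") | (out["direction_3v1"] != "ns")
    return out


def stage_means_log2(matrix: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """Per-gene mean of log2(x + pseudocount) per stage, stages in M-number order."""
    _check_nonnegative(matrix)
    stages = stage_columns(matrix)
    order = sorted(stages, key=lambda s: int(s[1:]))
    data = {
        s: np.log2(matrix[stages[s]].to_numpy() + pseudocount).mean(axis=1) for s in order
    }
    return pd.DataFrame(data, index=matrix.index)


def classify_trajectory(stage_means: Sequence[float], epsilon: float = 0.25) -> str:
    """Three-stage trajectory group from log2-scale stage means.

    With d1 = m2 - m1 and d2 = m3 - m2, steps within the dead zone
    (|d| <= epsilon) count as flat.  Rising overall -> I, down-then-up -> II,
    falling overall -> III, up-then-down -> IV, both flat -> 'flat'.
    """
    if len(stage_means) != 3:
        raise ValidationError(f"expected exactly 3 stage means, got {len(stage_means)}")
    if not all(math.isfinite(m) for m in stage_means):
        raise ValidationError("stage means must be finite")
    m1, m2, m3 = stage_means
    s1 = 0 if abs(m2 - m1) <= epsilon else (1 if m2 > m1 else -1)
    s2 = 0 if abs(m3 - m2) <= epsilon else (1 if m3 > m2 else -1)
    if s1 == 0 and s2 == 0:
        return "flat"
    if s1 >= 0 and s2 >= 0:
        return "I"
    if s1 <= 0 and s2 <= 0:
        return "III"
    return "II" if s1 < 0 else "IV"


def classify_trajectories(
    matrix: pd.DataFrame, epsilon: float = 0.25, pseudocount: float = 1.0
) -> pd.Series:
    """Vectorized :func:`classify_trajectory` over a matrix (stage means of log2)."""
    means = stage_means_log2(matrix, pseudocount=pseudocount)
    if means.shape[1] != 3:
        raise ValidationError(f"trajectory grouping needs 3 stages, found {means.shape[1]}")
    return pd.Series(
        [classify_trajectory(row, epsilon=epsilon) for row in means.to_numpy()],
        index=matrix.index,
        name="group",
    )


def standardize_profiles(
    matrix: pd.DataFrame, pseudocount: float = 1.0
) -> tuple[pd.DataFrame, list]:
    """Z-score per-gene stage-mean log2 profiles; constant profiles are dropped.

    Returns (standardized profiles, ids of dropped constant genes).
    """
    means = stage_means_log2(matrix, pseudocount=pseudocount)
    arr = means.to_numpy()
    sd = arr.std(axis=1, ddof=0)
    constant = sd == 0
    kept = arr[~constant]
    kept = (kept - kept.mean(axis=1, keepdims=True)) / sd[~constant][:, None]
    dropped = list(means.index[constant])
    return pd.DataFrame(kept, index=means.index[~constant], columns=means.columns), dropped


def soft_cluster(
    profiles: pd.DataFrame,
    c: int = 12,
    m: float = 2.0,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> tuple[pd.DataFrame, FuzzyCMeansResult]:
    """Fuzzy c-means on standardized profiles.

    Returns (table, fit): *table* is indexed by gene id with ``cluster_id``
    (1-based argmax label, ties to the lowest index) and one ``mem_<k>``
    column per cluster; *fit* carries centers and the objective trace.
    Profiles must be standardized beforehand (see :func:`standardize_profiles`);
    constant profiles are rejected.
    """
    X = profiles.to_numpy(dtype=float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValidationError("profiles must be a nonempty 2-D table")
    if (X.std(axis=1, ddof=0) == 0).any():
        raise ValidationError(
            "constant profiles present; exclude them (standardize_profiles) before clustering"
        )
    fit = fuzzy_cmeans(X, c=c, m=m, seed=seed, tol=tol, max_iter=max_iter)
    table = pd.DataFrame(
        fit.memberships,
        index=profiles.index,
        columns=[f"mem_{k + 1}" for k in range(c)],
    )
    table.insert(0, "cluster_id", fit.hard_labels + 1)
    return table, fit


def cluster_groups(
    fit: FuzzyCMeansResult, epsilon: float = 0.25
) -> dict[int, str]:
    """Trajectory group of each cluster, from its center shape (1-based ids)."""
    return {
        k + 1: classify_trajectory(center, epsilon=epsilon)
        for k, center in enumerate(fit.centers)
    }


def select_upregulated_tfs(de: pd.DataFrame, catalog: GeneCatalog) -> set[str]:
    """TF genes (master switches included) significantly up in either comparison."""
    tf_ids = catalog.tf_ids()
    up = (de["direction_2v1"] == "up") | (de["direction_3v1"] == "up")
    return {g for g in de.index[up] if g in tf_ids}


def ddct(
    ct_target_sample: float,
    ct_ref_sample: float,
    ct_target_calibrator: float,
    ct_ref_calibrator: float,
) -> float:
    """Relative qPCR expression by the 2^-ddCt method.

    ddCt = (Ct_target - Ct_reference) in the sample minus the same difference
    in the calibrator; returns 2**(-ddCt).
    """
    cts = (ct_target_sample, ct_ref_sample, ct_target_calibrator, ct_ref_calibrator)
    for ct in cts:
        if not math.isfinite(ct) or ct <= 0:
            raise ValidationError(f"Ct values must be finite and positive, got {ct!r}")
    ddct_value = (ct_target_sample - ct_ref_sample) - (
        ct_target_calibrator - ct_ref_calibrator
    )
    return 2.0**-ddct_value
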