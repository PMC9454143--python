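"""TPM normalization, family aggregation, differential expression, clustering.

Counts are normalized to transcripts per million (TPM): count / library
total x 1e6, so each library column sums to 1e6 when the rows cover every
counted species.  Differential expression between tissues uses the group
mean TPM with a pseudocount of 1 for the fold change and a two-sided Welch
t-test on log2(TPM+1) for the P value; a feature is significant when
|fold change| >= 2 and P < 0.05 (raw P, no multiple-testing correction —
the screening criterion, not a calibrated error rate).  Expression-profile
groups come from average-linkage hierarchical clustering of row-z-scored
log2(TPM+1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

FC_THRESHOLD = 2.0
P_THRESHOLD = 0.05
PSEUDOCOUNT = 1.0


@dataclass(frozen=True)
class DEResult:
    id: str
    log2_fc: float
    p_value: float
    significant: bool


def tpm_normalize(counts: pd.DataFrame, library_totals: Mapping[str, float] | None = None) -> pd.DataFrame:
    """Normalize a (feature x library) count table to TPM.

    ``library_totals`` defaults to the column sums; a zero total raises,
    naming the library.
    """
    if library_totals is None:
        library_totals = counts.sum(axis=0).to_dict()
    for lib in counts.columns:
        if library_totals.get(lib, 0) <= 0:
            raise ValueError(f"library {lib} has zero mapped-read total")
    totals = pd.Series({lib: float(library_totals[lib]) for lib in counts.columns})
    return counts.div(totals, axis=1) * 1e6


def family_aggregate(matrix: pd.DataFrame, family_map: Mapping[str, str]) -> pd.DataFrame:
    """Sum member rows into family rows; total mass is conserved."""
    families = pd.Series({rid: family_map.get(rid, rid) for rid in matrix.index})
    out = matrix.groupby(families).sum()
    out.index.name = "family"
    return out


def differential_expression(
    matrix: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    fc_threshold: float = FC_THRESHOLD,
    p_threshold: float = P_THRESHOLD,
) -> list[DEResult]:
    """Welch t-test of group A vs group B per feature on TPM values.

    Fold change is (mean_A + 1) / (mean_B + 1); the test is two-sided on
    log2(TPM+1).  Requires >= 2 replicates per group.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 replicates")
    a = matrix[list(group_a)].to_numpy(dtype=float)
    b = matrix[list(group_b)].to_numpy(dtype=float)
    fc = (a.mean(axis=1) + PSEUDOCOUNT) / (b.mean(axis=1) + PSEUDOCOUNT)
    log2_fc = np.log2(fc)
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.ttest_ind(np.log2(a + 1), np.log2(b + 1), axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)
    results = []
    for rid, lfc, pv in zip(matrix.index, log2_fc, p):
        sig = abs(lfc) >= np.log2(fc_threshold) and pv < p_threshold
        results.append(DEResult(str(rid), float(lfc), float(pv), bool(sig)))
    return results


def cluster_expression_groups(matrix: pd.DataFrame, k: int) -> pd.Series:
    """Cut an average-linkage (Euclidean) tree of z-scored log2 profiles.

    Rows with zero variance z-score to 0.  Returns a Series of integer
    group labels (1..k) indexed like ``matrix``; deterministic.
    """
    if not 1 <= k <= len(matrix):
        raise ValueError("k must be between 1 and the number of rows")
    logm = np.log2(matrix.to_numpy(dtype=float) + 1)
    mu = logm.mean(axis=1, keepdims=True)
    sd = logm.std(axis=1, keepdims=True)
    z = np.where(sd > 0, (logm - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    link = hierarchy.linkage(z, method="average", metric="euclidean")
    labels = hierarchy.fcluster(link, t=k, criterion="maxclust")
    return pd.Series(labels, index=matrix.index, name="group")
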