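"""Turn raw matrices (PSI, TPM, single-cell counts) into molecular signatures.

A signature is the difference between a case condition and a reference:
deltaPSI for exon inclusion, log2 fold-change for expression. The rules here
mirror the conventions of perturbation-network pipelines: expression is
log2(x+1)-transformed before any averaging or subtraction, replicate
averaging happens on the transformed scale for expression and on raw PSI for
splicing, and a signature entry exists only where both sides were observed.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse

from .io import FeatureMatrix, PerturbCellData, ValidationError

logger = logging.getLogger("sfactivity")


def log_transform(matrix: FeatureMatrix) -> FeatureMatrix:
    """log2(value + 1), elementwise; missing propagates.

    Accepts non-negative matrices (TPM or CPM scale) and returns kind
    ``log_expr``.
    """
    arr = matrix.values
    if (arr < 0).any():
        raise ValidationError("log_transform requires non-negative values")
    out = pd.DataFrame(
        np.log2(arr + 1.0), index=matrix.data.index, columns=matrix.data.columns
    )
    return FeatureMatrix(out, "log_expr", {"transform": "log2(x+1)"})


def pseudobulk(cells: PerturbCellData) -> FeatureMatrix:
    """Aggregate single-cell counts into per-perturbation log2(CPM+1) profiles.

    Counts of all cells sharing a perturbation label are summed, scaled to
    counts per million over all genes in the matrix, and log-transformed.
    Returns genes x labels, kind ``log_expr``.
    """
    counts = cells.counts
    if scipy.sparse.issparse(counts):
        counts = np.asarray(counts.todense())
    counts = np.asarray(counts, dtype=float)
    labels = cells.labels
    cell_labels = np.array([cells.cell_to_perturbation[c] for c in cells.cell_ids])
    cols = {}
    for lab in labels:
        summed = counts[cell_labels == lab].sum(axis=0)
        total = summed.sum()
        if total == 0:
            raise ValidationError(f"perturbation {lab!r} has zero total counts")
        cols[lab] = np.log2(summed / total * 1e6 + 1.0)
    out = pd.DataFrame(cols, index=cells.gene_ids)
    return FeatureMatrix(
        out, "log_expr", {"aggregation": "pseudobulk sum -> CPM -> log2(x+1)"}
    )


def _aggregate(df: pd.DataFrame, stat: str) -> pd.Series:
    if stat == "median":
        return df.median(axis=1, skipna=True)
    if stat == "mean":
        return df.mean(axis=1, skipna=True)
    raise ValueError(f"unknown reference statistic {stat!r}")


def subtract_reference(
    matrix: FeatureMatrix,
    case_samples: Sequence[str] | Mapping[str, Sequence[str]],
    reference_samples: Sequence[str],
    ref_stat: str = "median",
    per_sample: bool = True,
) -> FeatureMatrix:
    """Case-minus-reference signatures.

    With ``per_sample=True`` each case sample yields one signature column
    (sample value minus the reference aggregate). With ``per_sample=False``
    case replicates are averaged first, producing one column per case
    condition; ``case_samples`` may then be a mapping of condition name to
    replicate sample ids (a flat list is treated as a single condition named
    ``"case"``). The reference aggregate is the ``ref_stat`` (median or
    mean) of the reference samples per feature. A signature entry is missing
    whenever either side has no observed value.
    """
    reference_samples = list(reference_samples)
    if not reference_samples:
        raise ValidationError("reference sample set is empty")
    if isinstance(case_samples, Mapping):
        case_groups = {k: list(v) for k, v in case_samples.items()}
    else:
        case_list = list(case_samples)
        case_groups = (
            {s: [s] for s in case_list} if per_sample else {"case": case_list}
        )
    all_case = [s for group in case_groups.values() for s in group]
    overlap = set(all_case) & set(reference_samples)
    if overlap:
        raise ValidationError(f"case and reference samples overlap: {sorted(overlap)}")
    for s in [*all_case, *reference_samples]:
        if s not in matrix.data.columns:
            raise ValidationError(f"sample {s!r} not in matrix")
    ref = _aggregate(matrix.data[reference_samples], ref_stat)
    cols = {}
    if per_sample:
        for cond, group in case_groups.items():
            for s in group:
                cols[s if cond == s else f"{cond}:{s}"] = matrix.data[s] - ref
    else:
        for cond, group in case_groups.items():
            cols[cond] = matrix.data[group].mean(axis=1, skipna=True) - ref
    out = pd.DataFrame(cols, index=matrix.data.index)
    return FeatureMatrix(
        out,
        "signature",
        {
            "reference": reference_samples,
            "ref_stat": ref_stat,
            "per_sample": per_sample,
            "source_kind": matrix.kind,
        },
    )


def median_center(matrix: FeatureMatrix) -> FeatureMatrix:
    """Subtract each feature's median across samples (observed entries only)."""
    if matrix.data.shape[1] < 2:
        raise ValidationError("median centering needs at least 2 samples")
    med = matrix.data.median(axis=1, skipna=True)
    out = matrix.data.sub(med, axis=0)
    return FeatureMatrix(
        out, "signature", {"reference": "within-matrix median", "ref_stat": "median"}
    )


def average_replicates(
    matrix: FeatureMatrix, groups: Mapping[str, str]
) -> FeatureMatrix:
    """Average replicate columns: ``groups`` maps sample id -> condition.

    Every sample must be assigned; missing values are ignored in the mean.
    Output columns follow first appearance order of the conditions.
    """
    unassigned = [s for s in matrix.data.columns if s not in groups]
    if unassigned:
        raise ValidationError(f"samples not assigned to a group: {unassigned[:5]}")
    order: list[str] = []
    members: dict[str, list[str]] = {}
    for s in matrix.data.columns:
        g = groups[s]
        if g not in members:
            members[g] = []
            order.append(g)
        members[g].append(s)
    cols = {g: matrix.data[members[g]].mean(axis=1, skipna=True) for g in order}
    out = pd.DataFrame(cols, index=matrix.data.index)[order]
    return FeatureMatrix(out, matrix.kind, {"aggregation": "replicate mean"})
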