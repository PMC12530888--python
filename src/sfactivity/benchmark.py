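"""Leave-one-out benchmark: do inferred activities recover the perturbed SF?

For each perturbation dataset, regulons are inferred from all *other*
datasets, activities are computed on the held-out dataset's signatures, and
ROC AUCs quantify how well the activity of the truly perturbed splicing
factor stands out — per signature across candidate SFs ("across_sf") and
per SF across signatures ("across_perturbations").

Score convention: the regulons in scope are knockdown-derived (mor is the
sign of the knockdown response), so a held-out knockdown signature of the
same factor recapitulates its regulon and attains the top *positive* NES;
equivalently, the factor's activity (-NES under the knockdown-derived sign
convention) drops the most. The default ranking score is therefore +NES for
silencing screens; ``perturbation="activation"`` flips it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import FeatureMatrix, ValidationError
from .activity import DEFAULT_MIN_TARGETS, activity_matrix
from .regulons import NetworkSet, infer_regulons

logger = logging.getLogger("sfactivity")


@dataclass
class BenchmarkResult:
    """Per-unit ROC AUCs along one axis plus the median."""

    axis: str
    aucs: pd.Series  # indexed by signature (across_sf) or SF (across_perturbations)
    median: float
    n_excluded: int


def rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """ROC AUC via the rank/U statistic; ties earn half credit.

    AUC = (sum of positive ranks - n+ (n+ + 1)/2) / (n+ n-).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    r = rankdata(scores, method="average")
    u = r[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def leave_one_out(
    datasets: Mapping[str, tuple[FeatureMatrix, Mapping[str, str]]],
    threshold: float,
    min_targets: int = DEFAULT_MIN_TARGETS,
    integration: str = "mean",
) -> dict[str, FeatureMatrix]:
    """Per held-out dataset: activities computed with all-other networks.

    ``datasets`` maps dataset name to (perturbation signatures, condition
    -> perturbed SF map). For each dataset d, one network per remaining
    dataset is inferred at ``threshold`` and d's signatures are scored
    against their combination.
    """
    if len(datasets) < 2:
        raise ValidationError("leave-one-out needs >= 2 datasets")
    inferred = {
        name: infer_regulons(sigs, cond_map, threshold)
        for name, (sigs, cond_map) in datasets.items()
    }
    out = {}
    for held_out in datasets:
        networks = {n: regs for n, regs in inferred.items() if n != held_out and regs}
        if not networks:
            raise ValidationError(
                f"no usable network remains after holding out {held_out!r}"
            )
        sigs, _ = datasets[held_out]
        out[held_out] = activity_matrix(
            sigs, NetworkSet(networks), min_targets=min_targets,
            integration=integration,
        )
    return out


def recovery_auc(
    activities: FeatureMatrix,
    truth: Mapping[str, str],
    axis: str = "across_sf",
    perturbation: str = "knockdown",
) -> BenchmarkResult:
    """ROC AUCs for recovering the perturbed SF from activities.

    ``truth`` maps each signature (column) to the SF perturbed in it.
    ``across_sf``: one AUC per signature, ranking candidate SFs (those with
    observed activity); ``across_perturbations``: one AUC per SF, ranking
    signatures. Units lacking either a positive or a negative are excluded
    and counted. See the module docstring for the score sign convention.
    """
    missing = [c for c in activities.data.columns if c not in truth]
    if missing:
        raise ValidationError(f"signatures without a truth label: {missing[:5]}")
    if axis not in {"across_sf", "across_perturbations"}:
        raise ValidationError(f"unknown axis {axis!r}")
    if perturbation not in {"knockdown", "activation"}:
        raise ValidationError(f"unknown perturbation type {perturbation!r}")
    sign = 1.0 if perturbation == "knockdown" else -1.0
    scores = sign * activities.data
    aucs = {}
    n_excluded = 0
    if axis == "across_sf":
        for cond in scores.columns:
            col = scores[cond].dropna()
            labels = col.index == truth[cond]
            auc = rank_auc(col.to_numpy(), labels)
            if np.isnan(auc):
                n_excluded += 1
            else:
                aucs[cond] = auc
    else:
        for sf in scores.index:
            row = scores.loc[sf].dropna()
            labels = np.array([truth[c] == sf for c in row.index])
            auc = rank_auc(row.to_numpy(), labels)
            if np.isnan(auc):
                n_excluded += 1
            else:
                aucs[sf] = auc
    series = pd.Series(aucs, dtype=float)
    median = float(series.median()) if len(series) else float("nan")
    return BenchmarkResult(axis, series, median, n_excluded)


def run_benchmark(
    datasets: Mapping[str, tuple[FeatureMatrix, Mapping[str, str]]],
    threshold: float,
    min_targets: int = DEFAULT_MIN_TARGETS,
    perturbation: str = "knockdown",
) -> pd.DataFrame:
    """Leave-one-out + AUC along both axes; one row per (dataset, axis)."""
    activities = leave_one_out(datasets, threshold, min_targets)
    rows = []
    for name, acts in activities.items():
        _, truth = datasets[name]
        for axis in ("across_sf", "across_perturbations"):
            res = recovery_auc(acts, truth, axis, perturbation)
            rows.append(
                {
                    "dataset": name,
                    "axis": axis,
                    "median_auc": res.median,
                    "n_units": len(res.aucs),
                    "n_excluded": res.n_excluded,
                }
            )
    return pd.DataFrame(rows)
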