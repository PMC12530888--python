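"""Rank-based enrichment engine for splicing-factor activity (aREA-style NES).

Given a molecular signature (deltaPSI or log2FC per feature) and a regulon,
the engine rank-transforms the signature into standard-normal quantile
scores and computes a normalized enrichment score (NES) combining a
directional component (weighted by mode of regulation, mor) and a magnitude
component (active only for |mor| < 1). The analytic standardization
D / sqrt(sum w'^2) makes the NES approximately standard normal under a null
of exchangeable signatures, so values are comparable across regulons of
different sizes.

Multiple networks are integrated at the activity level: each network that
contains a regulator with enough observed targets contributes one NES, and
the integrated activity is their unweighted mean.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .io import FeatureMatrix, ValidationError
from .regulons import NetworkSet, Regulon

logger = logging.getLogger("sfactivity")

#: Minimum observed regulon targets for a NES to be reported.
DEFAULT_MIN_TARGETS = 25

ONCOGENIC = "oncogenic-like"
TUMOR_SUPPRESSOR = "tumor-suppressor-like"
NON_DRIVER = "non-driver-like"
PROGRAM_CLASSES = (ONCOGENIC, TUMOR_SUPPRESSOR, NON_DRIVER)


# ---------------------------------------------------------------------------
# Quantile transform
# ---------------------------------------------------------------------------


@dataclass
class QuantileScores:
    """Standard-normal quantile scores of one signature column.

    ``q2`` is the directional score (increasing with signature rank),
    ``q1`` the magnitude score (large for extreme values of either sign).
    Both are aligned to ``features``; only observed features appear.
    """

    features: pd.Index
    q2: np.ndarray
    q1: np.ndarray


def quantile_transform(signature: pd.Series) -> QuantileScores:
    """Rank-transform one signature column into normal quantile scores.

    With n observed features and average-tie ranks r:
    t2 = r/(n+1) and q2 = Phi^-1(t2); t1 = 2*|t2 - 0.5| rescaled by
    t1 <- t1 + (1 - max(t1))/2, q1 = Phi^-1(t1).
    """
    obs = signature.dropna()
    if len(obs) < 2:
        raise ValidationError("quantile transform needs >= 2 observed features")
    q2, q1 = _quantile_scores(obs.to_numpy()[:, None])
    return QuantileScores(obs.index, q2[:, 0], q1[:, 0])


def _quantile_scores(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized column-wise quantile scores for a fully observed array."""
    n = values.shape[0]
    r = rankdata(values, axis=0, method="average")
    t2 = r / (n + 1.0)
    t1 = 2.0 * np.abs(t2 - 0.5)
    t1 = t1 + (1.0 - t1.max(axis=0, keepdims=True)) / 2.0
    return norm.ppf(t2), norm.ppf(t1)


# ---------------------------------------------------------------------------
# NES
# ---------------------------------------------------------------------------


def _nes_from_scores(
    q2: np.ndarray, q1: np.ndarray, mor: np.ndarray, likelihood: np.ndarray
) -> float:
    """NES given target-aligned scores (1-d arrays over observed targets)."""
    lmax = likelihood.max()
    if lmax == 0:
        raise ValidationError("all regulon likelihoods are zero")
    w = likelihood / lmax
    d = w.sum()
    sum1 = float((w * mor * q2).sum() / d)
    sum2 = float((w * (1.0 - np.abs(mor)) * q1).sum() / d)
    es = abs(sum1) + max(sum2, 0.0)
    sign = 1.0 if sum1 >= 0 else -1.0
    return sign * es * d / np.sqrt((w**2).sum())


def nes(
    signature: pd.Series, regulon: Regulon, min_targets: int = DEFAULT_MIN_TARGETS
) -> float:
    """Normalized enrichment score of one regulon in one signature column.

    Targets absent from the signature (or unobserved there) are dropped;
    if fewer than ``min_targets`` remain the result is ``NaN``.
    """
    if len(regulon) == 0:
        raise ValidationError("empty regulon")
    scores = quantile_transform(signature)
    pos = scores.features.get_indexer(list(regulon.targets))
    keep = pos >= 0
    if keep.sum() < min_targets:
        return float("nan")
    idx = pos[keep]
    return _nes_from_scores(
        scores.q2[idx], scores.q1[idx], regulon.mor[keep], regulon.likelihood[keep]
    )


def _network_activity(
    signatures: FeatureMatrix, regulons: list[Regulon], min_targets: int
) -> pd.DataFrame:
    """NES of every regulon in every signature column of one network."""
    data = signatures.data
    arr = np.full((len(regulons), data.shape[1]), np.nan)
    # Columns can differ in their missing-feature pattern; group columns by
    # pattern so the rank transform is vectorized within each group.
    mask = data.notna().to_numpy()
    patterns: dict[bytes, list[int]] = {}
    for j in range(mask.shape[1]):
        patterns.setdefault(mask[:, j].tobytes(), []).append(j)
    values = data.to_numpy()
    for key, cols in patterns.items():
        obs = np.frombuffer(key, dtype=bool)
        if obs.sum() < 2:
            continue
        sub = values[np.ix_(obs, cols)]
        q2, q1 = _quantile_scores(sub)
        feat = data.index[obs]
        for i, r in enumerate(regulons):
            pos = feat.get_indexer(list(r.targets))
            keep = pos >= 0
            if keep.sum() < min_targets:
                continue
            idx = pos[keep]
            for jj, col in enumerate(cols):
                arr[i, col] = _nes_from_scores(
                    q2[idx, jj], q1[idx, jj], r.mor[keep], r.likelihood[keep]
                )
    return pd.DataFrame(
        arr, index=[r.regulator for r in regulons], columns=data.columns
    )


def activity_matrix(
    signatures: FeatureMatrix,
    networks: NetworkSet,
    min_targets: int = DEFAULT_MIN_TARGETS,
    integration: str = "mean",
) -> FeatureMatrix:
    """Integrated regulator x condition activity (NES) over a network set.

    Every network containing a regulator with >= ``min_targets`` observed
    targets contributes one NES per condition; the integrated value is the
    unweighted mean of the available per-network NES (``integration="mean"``)
    or a |NES|-weighted mean (``"weighted"``). Entries with no contributing
    network are missing.
    """
    if not networks.networks:
        raise ValidationError("empty network set")
    if integration not in {"mean", "weighted"}:
        raise ValidationError(f"unknown integration {integration!r}")
    regulators = networks.regulators()
    per_net = [
        _network_activity(signatures, regs, min_targets)
        for regs in networks.networks.values()
    ]
    stacked = np.full(
        (len(per_net), len(regulators), signatures.data.shape[1]), np.nan
    )
    for k, tbl in enumerate(per_net):
        idx = [regulators.index(r) for r in tbl.index]
        stacked[k, idx, :] = tbl.to_numpy()
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN entries stay NaN
        if integration == "mean":
            combined = np.nanmean(stacked, axis=0)
        else:
            w = np.abs(stacked)
            num = np.nansum(stacked * w, axis=0)
            den = np.nansum(w, axis=0)
            have = (~np.isnan(stacked)).any(axis=0)
            ratio = num / np.where(den == 0, 1.0, den)
            combined = np.where(have, ratio, np.nan)
    out = pd.DataFrame(combined, index=regulators, columns=signatures.data.columns)
    return FeatureMatrix(out, "activity", {"integration": integration})


# ---------------------------------------------------------------------------
# Cancer splicing programs
# ---------------------------------------------------------------------------


@dataclass
class ProgramDefinition:
    """Splicing-factor program membership with per-cohort recurrence counts.

    ``classes`` maps each SF to oncogenic-like (recurrently activated),
    tumor-suppressor-like (recurrently inactivated) or non-driver-like.
    ``counts`` maps each SF to (n cohorts activated, n cohorts inactivated).
    """

    classes: dict[str, str]
    counts: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sf, cls in self.classes.items():
            if cls not in PROGRAM_CLASSES:
                raise ValidationError(f"unknown program class {cls!r} for {sf!r}")
        for sf, (a, i) in self.counts.items():
            if a < 0 or i < 0:
                raise ValidationError(f"negative recurrence count for {sf!r}")

    def members(self, cls: str) -> list[str]:
        return [sf for sf, c in self.classes.items() if c == cls]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for sf, cls in self.classes.items():
            a, i = self.counts.get(sf, (0, 0))
            rows.append(
                {"sf": sf, "class": cls, "n_activated": a, "n_inactivated": i}
            )
        return pd.DataFrame(rows)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ProgramDefinition":
        df = pd.read_csv(path, sep="\t")
        classes = dict(zip(df["sf"].astype(str), df["class"].astype(str)))
        counts = {
            str(r["sf"]): (int(r["n_activated"]), int(r["n_inactivated"]))
            for _, r in df.iterrows()
        }
        return cls(classes, counts)


def program_activity(
    activity: FeatureMatrix,
    programs: ProgramDefinition,
    classes: tuple[str, ...] = (ONCOGENIC, TUMOR_SUPPRESSOR),
) -> pd.DataFrame:
    """Per-condition median activity of each program class.

    The program-level activity of a class in a condition is the median NES
    over its member SFs with observed activity.
    """
    rows = {}
    for cls in classes:
        members = [m for m in programs.members(cls) if m in activity.data.index]
        if not members:
            logger.warning("program class %s has no members with activity", cls)
            rows[cls] = pd.Series(np.nan, index=activity.data.columns)
            continue
        med = activity.data.loc[members].median(axis=0, skipna=True)
        if med.isna().any():
            logger.warning(
                "program class %s: no observed member activity in some conditions", cls
            )
        rows[cls] = med
    return pd.DataFrame(rows).T


def program_difference(
    activity: FeatureMatrix, programs: ProgramDefinition
) -> pd.Series:
    """Oncogenic-like minus tumor-suppressor-like median activity.

    Positive values mark dominance of the oncogenic-like program (the
    tumorigenic-like state); negative values, of the tumor-suppressor-like
    program.
    """
    med = program_activity(activity, programs, (ONCOGENIC, TUMOR_SUPPRESSOR))
    diff = med.loc[ONCOGENIC] - med.loc[TUMOR_SUPPRESSOR]
    diff.name = "program_difference"
    return diff


def normalize_vs_control(
    values: FeatureMatrix,
    control: FeatureMatrix,
    match: Mapping[str, str],
) -> FeatureMatrix:
    """Subtract matched negative-control activities, elementwise.

    ``match`` maps each treated condition (column of ``values``) to its
    control condition (column of ``control``). Entries missing on either
    side stay missing.
    """
    unmatched = [c for c in values.data.columns if c not in match]
    if unmatched:
        raise ValidationError(f"conditions without a matched control: {unmatched[:5]}")
    bad = [c for c, ctl in match.items() if ctl not in control.data.columns]
    if bad:
        raise ValidationError(f"matched control conditions absent: {bad[:5]}")
    ctl = control.data[[match[c] for c in values.data.columns]]
    ctl.columns = values.data.columns
    ctl = ctl.reindex(values.data.index)
    out = values.data - ctl
    return FeatureMatrix(out, values.kind, {"normalized_vs": dict(match)})
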