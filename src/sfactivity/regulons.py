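"""Splicing-factor regulons inferred from perturbation signatures.

A regulon links one regulator (a splicing factor) to the targets — exons or
genes — whose signal changed substantially when the factor was perturbed.
The mode of regulation (mor) is the sign of the change, the likelihood is
its absolute size: for exon networks targets require |deltaPSI| >= 15, for
gene networks |log2FC| >= 1 (both inclusive).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import FeatureMatrix, ParseError, ValidationError

logger = logging.getLogger("sfactivity")

#: Default target thresholds, in the units of each signature kind.
EXON_THRESHOLD = 15.0  # |deltaPSI|, percent spliced-in units
GENE_THRESHOLD = 1.0  # |log2FC|


@dataclass
class Regulon:
    """One regulator with signed, weighted targets."""

    regulator: str
    targets: tuple[str, ...]
    mor: np.ndarray
    likelihood: np.ndarray

    def __post_init__(self) -> None:
        self.mor = np.asarray(self.mor, dtype=float)
        self.likelihood = np.asarray(self.likelihood, dtype=float)
        if not (len(self.targets) == len(self.mor) == len(self.likelihood)):
            raise ValidationError("regulon fields have mismatched lengths")
        if len(set(self.targets)) != len(self.targets):
            raise ValidationError(f"regulon {self.regulator!r}: duplicate targets")
        if (np.abs(self.mor) > 1).any():
            raise ValidationError(f"regulon {self.regulator!r}: |mor| > 1")
        if (self.likelihood < 0).any():
            raise ValidationError(f"regulon {self.regulator!r}: likelihood < 0")

    def __len__(self) -> int:
        return len(self.targets)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "regulator": self.regulator,
                "target": list(self.targets),
                "mor": self.mor,
                "likelihood": self.likelihood,
            }
        )


@dataclass
class NetworkSet:
    """A named collection of regulon lists, kept separate for integration.

    Networks are not merged when combined; integration of the per-network
    activity estimates happens downstream in the enrichment engine.
    """

    networks: dict[str, list[Regulon]]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, regs in self.networks.items():
            seen = set()
            for r in regs:
                if r.regulator in seen:
                    raise ValidationError(
                        f"network {name!r}: duplicate regulon for {r.regulator!r}"
                    )
                seen.add(r.regulator)

    @property
    def names(self) -> list[str]:
        return list(self.networks)

    def regulators(self) -> list[str]:
        out: list[str] = []
        for regs in self.networks.values():
            for r in regs:
                if r.regulator not in out:
                    out.append(r.regulator)
        return out


def read_regulons(path: str | Path) -> list[Regulon]:
    """Read a regulon TSV with columns regulator, target, mor, likelihood."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    required = ["regulator", "target", "mor", "likelihood"]
    if list(df.columns[:4]) != required:
        raise ParseError(f"{path}: expected columns {required}")
    if df.duplicated(subset=["regulator", "target"]).any():
        row = df[df.duplicated(subset=["regulator", "target"])].iloc[0]
        raise ValidationError(
            f"{path}: duplicate interaction ({row['regulator']}, {row['target']})"
        )
    if (df["mor"].abs() > 1).any():
        raise ValidationError(f"{path}: |mor| > 1")
    if (df["likelihood"] < 0).any():
        raise ValidationError(f"{path}: likelihood < 0")
    regulons = []
    for reg, sub in df.groupby("regulator", sort=False):
        regulons.append(
            Regulon(
                str(reg),
                tuple(sub["target"].astype(str)),
                sub["mor"].to_numpy(),
                sub["likelihood"].to_numpy(),
            )
        )
    return regulons


def write_regulons(regulons: Iterable[Regulon], path: str | Path) -> None:
    frames = [r.to_frame() for r in regulons]
    if frames:
        df = pd.concat(frames, ignore_index=True)
    else:
        df = pd.DataFrame(columns=["regulator", "target", "mor", "likelihood"])
    df.to_csv(path, sep="\t", index=False)


def infer_regulons(
    signatures: FeatureMatrix,
    condition_to_regulator: Mapping[str, str],
    threshold: float,
) -> list[Regulon]:
    """Build regulons from perturbation signatures.

    A feature becomes a target of the perturbed regulator iff its signature
    value is observed and ``|value| >= threshold`` (inclusive). mor is the
    sign of the value, likelihood its absolute value. When several
    conditions map to the same regulator, the per-target entry with the
    largest likelihood wins. Regulators left with no targets are omitted
    with a warning.
    """
    if threshold <= 0:
        raise ValidationError("threshold must be > 0")
    unmapped = [c for c in signatures.data.columns if c not in condition_to_regulator]
    if unmapped:
        raise ValidationError(f"conditions not mapped to a regulator: {unmapped[:5]}")
    order: list[str] = []
    per_reg: dict[str, dict[str, float]] = {}
    for cond in signatures.data.columns:
        reg = condition_to_regulator[cond]
        if reg not in per_reg:
            per_reg[reg] = {}
            order.append(reg)
        col = signatures.data[cond]
        hits = col[col.abs() >= threshold].dropna()
        best = per_reg[reg]
        for target, value in hits.items():
            if target not in best or abs(value) > abs(best[target]):
                best[target] = float(value)
    regulons = []
    for reg in order:
        best = per_reg[reg]
        if not best:
            logger.warning("regulator %s: no targets pass threshold; omitted", reg)
            continue
        targets = tuple(best)
        values = np.array([best[t] for t in targets])
        mor = np.sign(values)
        regulons.append(Regulon(reg, targets, mor, np.abs(values)))
    return regulons


def combine(network_sets: Sequence[NetworkSet]) -> NetworkSet:
    """Union of named networks; regulons are never merged across networks."""
    if not network_sets:
        raise ValidationError("combine requires at least one NetworkSet")
    merged: dict[str, list[Regulon]] = {}
    for ns in network_sets:
        for name, regs in ns.networks.items():
            if name in merged:
                raise ValidationError(f"duplicate network name {name!r}")
            merged[name] = list(regs)
    return NetworkSet(merged)


def network_stats(net: NetworkSet) -> pd.DataFrame:
    """Per-network and pooled unique (regulator, target) interaction counts."""
    rows = []
    pooled: set[tuple[str, str]] = set()
    for name, regs in net.networks.items():
        pairs = {(r.regulator, t) for r in regs for t in r.targets}
        pooled |= pairs
        rows.append(
            {
                "network": name,
                "n_regulators": len(regs),
                "n_interactions": len(pairs),
            }
        )
    rows.append(
        {
            "network": "pooled",
            "n_regulators": len(net.regulators()),
            "n_interactions": len(pooled),
        }
    )
    return pd.DataFrame(rows)
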