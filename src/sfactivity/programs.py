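"""Cancer splicing programs: recurrence classification and cross-regulation.

Splicing factors recurrently more active in primary tumors than in matched
normal tissue across cohorts form the oncogenic-like program; recurrently
less active ones the tumor-suppressor-like program; the rest are
non-driver-like. Differential activity uses two-sided Mann-Whitney U tests
with Benjamini-Hochberg control within each cohort (significance at
q < 0.05), and a factor joins a program when significant in the same
direction in at least ``min_cohorts`` cohorts (default 5).

The module also quantifies cross-regulation between program classes through
splicing-factor->exon regulons or protein-protein interaction adjacency,
shortest-path distances in an interaction graph, and general correlation
utilities.
"""

from __future__ import annotations

import itertools
import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import networkx as nx
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import FeatureMatrix, ValidationError
from .activity import (
    NON_DRIVER,
    ONCOGENIC,
    PROGRAM_CLASSES,
    TUMOR_SUPPRESSOR,
    ProgramDefinition,
)
from .regulons import NetworkSet

logger = logging.getLogger("sfactivity")

DEFAULT_FDR = 0.05
DEFAULT_MIN_COHORTS = 5


def differential_activity(
    tumor: FeatureMatrix, normal: FeatureMatrix, fdr: float = DEFAULT_FDR
) -> pd.DataFrame:
    """Per-SF differential activity between tumor and normal samples.

    Two-sided Mann-Whitney U (normal approximation with tie and continuity
    correction) per splicing factor, BH-adjusted across factors within the
    cohort. Direction is the sign of (median tumor - median normal
    activity). Factors with fewer than 2 observed samples on either side
    are excluded with a warning.

    Returns a DataFrame indexed by SF with columns ``U``, ``p``, ``q``,
    ``direction`` (activated/inactivated, or missing when medians tie) and
    ``significant`` (q < fdr).
    """
    shared = tumor.data.index.intersection(normal.data.index)
    rows = []
    for sf in shared:
        t = tumor.data.loc[sf].dropna().to_numpy()
        n = normal.data.loc[sf].dropna().to_numpy()
        if len(t) < 2 or len(n) < 2:
            logger.warning("SF %s: fewer than 2 observed samples per side; excluded", sf)
            continue
        res = stats.mannwhitneyu(t, n, alternative="two-sided", method="asymptotic")
        med_diff = float(np.median(t) - np.median(n))
        if med_diff > 0:
            direction = "activated"
        elif med_diff < 0:
            direction = "inactivated"
        else:
            direction = None
        rows.append(
            {
                "sf": sf,
                "U": float(res.statistic),
                "p": float(res.pvalue),
                "direction": direction,
                "median_diff": med_diff,
            }
        )
    if not rows:
        raise ValidationError("no splicing factor testable in this cohort")
    out = pd.DataFrame(rows).set_index("sf")
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    out["significant"] = out["q"] < fdr
    return out[["U", "p", "q", "direction", "median_diff", "significant"]]


def classify_recurrent(
    results: Sequence[pd.DataFrame], min_cohorts: int = DEFAULT_MIN_COHORTS
) -> ProgramDefinition:
    """Classify SFs by recurrent differential activity across cohorts.

    Oncogenic-like: significantly activated in >= ``min_cohorts`` cohorts
    and in strictly more cohorts than inactivated; tumor-suppressor-like
    symmetric; ties and everything else are non-driver-like.
    """
    if not results:
        raise ValidationError("classify_recurrent needs >= 1 cohort")
    sfs: list[str] = []
    for res in results:
        for sf in res.index:
            if sf not in sfs:
                sfs.append(sf)
    classes, counts = {}, {}
    for sf in sfs:
        n_act = n_inact = 0
        for res in results:
            if sf not in res.index or not res.loc[sf, "significant"]:
                continue
            if res.loc[sf, "direction"] == "activated":
                n_act += 1
            elif res.loc[sf, "direction"] == "inactivated":
                n_inact += 1
        counts[sf] = (n_act, n_inact)
        if n_act >= min_cohorts and n_act > n_inact:
            classes[sf] = ONCOGENIC
        elif n_inact >= min_cohorts and n_inact > n_act:
            classes[sf] = TUMOR_SUPPRESSOR
        else:
            classes[sf] = NON_DRIVER
    return ProgramDefinition(classes, counts)


def cross_regulation_ratios(
    source: NetworkSet | nx.Graph,
    programs: ProgramDefinition,
    exon_map: Mapping[str, str] | None = None,
    mode: str = "splicing",
) -> pd.DataFrame:
    """Class-to-class regulation fractions.

    In ``splicing`` mode, SF a regulates SF b iff some regulon target exon
    of a maps (via ``exon_map``) to gene b. In ``ppi`` mode, regulation is
    adjacency in the interaction graph. For each ordered pair of program
    classes, the fraction (and count) of target-class members reached by at
    least one source-class member; self-interactions are excluded.
    """
    members = {cls: set(programs.members(cls)) for cls in PROGRAM_CLASSES}
    edges: set[tuple[str, str]] = set()
    if mode == "splicing":
        if not isinstance(source, NetworkSet):
            raise ValidationError("splicing mode requires a NetworkSet")
        if exon_map is None:
            raise ValidationError("splicing mode requires an exon->gene map")
        all_sfs = set(programs.classes)
        unmapped = sorted(
            {
                t
                for regs in source.networks.values()
                for r in regs
                for t in r.targets
                if t not in exon_map
            }
        )
        if unmapped:
            raise ValidationError(f"exons without gene mapping: {unmapped[:10]}")
        for regs in source.networks.values():
            for r in regs:
                for t in r.targets:
                    gene = exon_map[t]
                    if gene in all_sfs and gene != r.regulator:
                        edges.add((r.regulator, gene))
    elif mode == "ppi":
        if not isinstance(source, nx.Graph):
            raise ValidationError("ppi mode requires an interaction graph")
        for a, b in source.edges():
            if a != b:
                edges.add((a, b))
                edges.add((b, a))
    else:
        raise ValidationError(f"unknown mode {mode!r}")
    rows = []
    for src_cls, tgt_cls in itertools.product(PROGRAM_CLASSES, repeat=2):
        tgt_members = members[tgt_cls]
        reached = {
            b
            for a, b in edges
            if a in members[src_cls] and b in tgt_members and a != b
        }
        frac = len(reached) / len(tgt_members) if tgt_members else np.nan
        rows.append(
            {
                "source_class": src_cls,
                "target_class": tgt_cls,
                "fraction": frac,
                "count": len(reached),
                "n_target_class": len(tgt_members),
            }
        )
    return pd.DataFrame(rows)


def shortest_paths(graph: nx.Graph, nodes: Sequence[str]) -> pd.DataFrame:
    """Pairwise unweighted shortest-path hop distances among ``nodes``.

    Nodes absent from the graph are reported (warning) and skipped.
    Disconnected pairs get ``inf``; d(v, v) = 0.
    """
    present = [n for n in nodes if n in graph]
    absent = [n for n in nodes if n not in graph]
    if absent:
        logger.warning("nodes absent from graph, skipped: %s", absent[:10])
    dist = pd.DataFrame(np.inf, index=present, columns=present)
    for n in present:
        lengths = nx.shortest_path_length(graph, source=n)
        for m in present:
            if m in lengths:
                dist.loc[n, m] = float(lengths[m])
    return dist


def correlate(
    x: Sequence[float], y: Sequence[float], method: str = "pearson"
) -> tuple[float, float]:
    """Pearson or Spearman correlation with a two-sided p-value.

    Incomplete pairs (NaN/inf on either side, including infinite graph
    distances) are dropped; needs >= 3 complete pairs. Zero variance on
    either side yields (NaN, NaN) with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if x.size < 3:
        raise ValidationError("correlate needs >= 3 complete pairs")
    if x.std() == 0 or y.std() == 0:
        logger.warning("zero variance: correlation undefined")
        return float("nan"), float("nan")
    if method == "pearson":
        res = stats.pearsonr(x, y)
    elif method == "spearman":
        res = stats.spearmanr(x, y)
    else:
        raise ValidationError(f"unknown correlation method {method!r}")
    return float(res.statistic), float(res.pvalue)


def target_class_fraction(
    networks: NetworkSet,
    programs: ProgramDefinition,
    exon_map: Mapping[str, str],
    target_class: str = TUMOR_SUPPRESSOR,
) -> pd.Series:
    """Per SF: fraction of its target exons lying in genes of a class.

    Unique target exons are pooled over all networks; SFs with no targets
    are missing. Unmapped exons raise an error.
    """
    class_genes = set(programs.members(target_class))
    per_sf: dict[str, set[str]] = {}
    for regs in networks.networks.values():
        for r in regs:
            per_sf.setdefault(r.regulator, set()).update(r.targets)
    unmapped = sorted(
        {t for targets in per_sf.values() for t in targets if t not in exon_map}
    )
    if unmapped:
        raise ValidationError(f"exons without gene mapping: {unmapped[:10]}")
    out = {}
    for sf, targets in per_sf.items():
        if not targets:
            out[sf] = np.nan
            continue
        in_class = sum(1 for t in targets if exon_map[t] in class_genes)
        out[sf] = in_class / len(targets)
    return pd.Series(out, name=f"fraction_{target_class}")
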