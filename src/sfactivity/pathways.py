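"""Gene-set machinery: preranked GSEA, hypergeometric ORA, overlap
stripping, and the two-stage pathway prioritization.

The preranked GSEA here is the canonical weighted Kolmogorov-Smirnov-like
running sum: genes are ordered by signature value, set members increment
the sum proportionally to |value|^weight_exponent (normalized within the
set), non-members decrement it uniformly, and the enrichment score (ES) is
the maximal deviation from zero. The null is built from seeded gene-label
permutations (equivalently, random sets of the same size); NES divides the
ES by the mean |null ES| of matching sign, and the nominal p-value comes
from the matching-sign null tail with the add-one correction
(1 + b) / (1 + m) so finite permutation counts never yield p = 0.

Prioritization mirrors a two-stage design: pathways whose enrichment
tracks the splicing-program difference concordantly across all stage-1
(carcinogenesis) datasets are shortlisted (top-k positive and top-k
negative by mean correlation), then re-ranked by their correlation in a
stage-2 (perturbation screen) dataset.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import GeneSetCollection, ValidationError

logger = logging.getLogger("sfactivity")

DEFAULT_N_PERM = 1000
DEFAULT_MIN_SET_SIZE = 5
DEFAULT_TOP_K = 5


def _enrichment_score(
    order_values: np.ndarray, hit_positions: np.ndarray, weight_exponent: float
) -> float:
    """ES of a set given positions of its members in the ranked list.

    ``order_values`` are signature values sorted descending; the running
    sum's extreme deviation (largest absolute) is returned with its sign.
    """
    n = order_values.size
    k = hit_positions.size
    w = np.abs(order_values[hit_positions]) ** weight_exponent
    nr = w.sum()
    if nr == 0:
        w = np.ones(k)
        nr = float(k)
    miss_step = 1.0 / (n - k)
    # Running sum evaluated just after each hit and just before each hit.
    order = np.argsort(hit_positions)
    pos = hit_positions[order]
    wcum = np.cumsum(w[order]) / nr
    misses_before = pos - np.arange(k)
    after_hit = wcum - misses_before * miss_step
    before_hit = np.concatenate(([0.0], wcum[:-1])) - misses_before * miss_step
    hi = after_hit.max()
    lo = before_hit.min()
    return float(hi if hi >= -lo else lo)


def gsea_preranked(
    signature: pd.Series,
    sets: GeneSetCollection,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    weight_exponent: float = 1.0,
    min_size: int = DEFAULT_MIN_SET_SIZE,
) -> pd.DataFrame:
    """Preranked GSEA of every gene set against one signature column.

    Returns a DataFrame indexed by set name with columns ``ES``, ``NES``,
    ``p``, ``q`` and ``size`` (set size after intersection with the
    observed signature universe). Sets below ``min_size`` after
    intersection are skipped with a warning.
    """
    obs = signature.dropna()
    universe = set(obs.index)
    # Deterministic ranking: descending value, gene id breaks ties.
    order = sorted(obs.index, key=lambda g: (-obs[g], g))
    order_values = obs[order].to_numpy()
    gene_pos = {g: i for i, g in enumerate(order)}
    n = len(order)
    rng = np.random.default_rng(seed)
    rows = []
    for name, members in sets.sets.items():
        inset = sorted(members & universe)
        k = len(inset)
        if k < min_size:
            logger.warning(
                "set %s: %d genes in universe (< %d); skipped", name, k, min_size
            )
            continue
        if k >= n:
            logger.warning("set %s covers the whole universe; skipped", name)
            continue
        positions = np.array([gene_pos[g] for g in inset])
        es = _enrichment_score(order_values, positions, weight_exponent)
        null = np.array(
            [
                _enrichment_score(
                    order_values,
                    rng.choice(n, size=k, replace=False),
                    weight_exponent,
                )
                for _ in range(n_perm)
            ]
        )
        same = null[null >= 0] if es >= 0 else null[null < 0]
        mean_abs = np.abs(same).mean() if same.size else np.nan
        nes_val = es / mean_abs if mean_abs and np.isfinite(mean_abs) else np.nan
        b = int((np.abs(same) >= abs(es)).sum())
        p = (1 + b) / (1 + same.size) if same.size else 1.0
        rows.append({"set": name, "ES": es, "NES": nes_val, "p": p, "size": k})
    if not rows:
        return pd.DataFrame(columns=["ES", "NES", "p", "q", "size"])
    out = pd.DataFrame(rows).set_index("set")
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    return out[["ES", "NES", "p", "q", "size"]]


def gsea_nes_matrix(
    signatures,  # FeatureMatrix
    sets: GeneSetCollection,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    weight_exponent: float = 1.0,
    min_size: int = DEFAULT_MIN_SET_SIZE,
) -> pd.DataFrame:
    """NES of every set in every signature column (sets x conditions)."""
    cols = {}
    for j, cond in enumerate(signatures.data.columns):
        res = gsea_preranked(
            signatures.data[cond],
            sets,
            n_perm=n_perm,
            seed=seed + j,
            weight_exponent=weight_exponent,
            min_size=min_size,
        )
        cols[cond] = res["NES"]
    return pd.DataFrame(cols)


def ora(
    hits: Iterable[str], universe: Iterable[str], sets: GeneSetCollection
) -> pd.DataFrame:
    """Hypergeometric overrepresentation of each set in a hit list.

    Upper-tail p for an overlap at least as large as observed, BH-adjusted
    across sets; ``gene_ratio`` = overlap / |hits|.
    """
    hits = set(hits)
    universe = set(universe)
    outside = hits - universe
    if outside:
        raise ValidationError(f"hits outside the universe: {sorted(outside)[:10]}")
    m_total = len(universe)
    n_hits = len(hits)
    rows = []
    for name, members in sets.sets.items():
        inset = members & universe
        overlap = len(inset & hits)
        p = float(stats.hypergeom.sf(overlap - 1, m_total, len(inset), n_hits))
        rows.append(
            {
                "set": name,
                "overlap": overlap,
                "set_size": len(inset),
                "gene_ratio": overlap / n_hits if n_hits else np.nan,
                "p": p,
            }
        )
    out = pd.DataFrame(rows).set_index("set")
    out["q"] = multipletests(out["p"], method="fdr_bh")[1] if len(out) else []
    return out


def strip_overlap(
    sets: GeneSetCollection, exclusion_sets: GeneSetCollection
) -> GeneSetCollection:
    """Remove the union of the exclusion sets' genes from every set.

    Sets emptied by the subtraction are dropped with a warning. Idempotent.
    """
    excluded = set().union(*exclusion_sets.sets.values()) if exclusion_sets.sets else set()
    kept, descs = {}, {}
    for name, members in sets.sets.items():
        remaining = members - excluded
        if not remaining:
            logger.warning("set %s fully overlaps the exclusion sets; dropped", name)
            continue
        kept[name] = remaining
        descs[name] = sets.descriptions.get(name, "")
    return GeneSetCollection(kept, descs)


def prioritize(
    stage1: Sequence[tuple[pd.DataFrame, pd.Series]],
    stage2_nes: pd.DataFrame,
    stage2_diff: pd.Series,
    k: int = DEFAULT_TOP_K,
) -> pd.DataFrame:
    """Two-stage pathway prioritization.

    ``stage1`` is a list of (NES matrix [pathways x conditions], program
    difference per condition) pairs, one per carcinogenesis dataset;
    ``stage2_nes``/``stage2_diff`` the same for the perturbation dataset.
    Stage 1 correlates each pathway's NES with the program difference in
    every dataset; pathways with the same correlation sign in all stage-1
    datasets are concordant, and the top-k positive plus top-k negative by
    mean correlation are shortlisted. Stage 2 re-correlates the shortlist
    in the perturbation dataset; the final rank orders shortlisted pathways
    by descending stage-2 correlation.
    """
    from .programs import correlate  # local import avoids cycle at module load

    if not stage1:
        raise ValidationError("prioritize needs >= 1 stage-1 dataset")
    for nes_df, diff in [*stage1, (stage2_nes, stage2_diff)]:
        shared = [c for c in nes_df.columns if c in diff.index]
        if len(shared) < 3:
            raise ValidationError("each dataset needs >= 3 aligned conditions")
    pathways = sorted(set().union(*[set(nes_df.index) for nes_df, _ in stage1]))
    corr = pd.DataFrame(index=pathways, columns=range(len(stage1)), dtype=float)
    for d, (nes_df, diff) in enumerate(stage1):
        shared = [c for c in nes_df.columns if c in diff.index]
        for pw in nes_df.index:
            x = nes_df.loc[pw, shared].to_numpy(dtype=float)
            y = diff[shared].to_numpy(dtype=float)
            if np.isfinite(x).sum() < 3:
                continue
            r, _ = correlate(x, y, "pearson")
            corr.loc[pw, d] = r
    mean_r = corr.mean(axis=1)
    complete = corr.notna().all(axis=1)
    signs = np.sign(corr)
    concordant = complete & signs.apply(
        lambda row: row.nunique() == 1 and 0 not in set(row), axis=1
    )
    pos_pool = mean_r[concordant & (mean_r > 0)].sort_values(ascending=False)
    neg_pool = mean_r[concordant & (mean_r < 0)].sort_values()
    if len(pos_pool) < k or len(neg_pool) < k:
        logger.warning(
            "concordant pool smaller than k=%d (positive %d, negative %d); truncated",
            k, len(pos_pool), len(neg_pool),
        )
    shortlist = list(pos_pool.index[:k]) + list(neg_pool.index[:k])
    out = pd.DataFrame(index=pathways)
    for d in range(len(stage1)):
        out[f"stage1_r_{d}"] = corr[d]
    out["stage1_mean_r"] = mean_r
    out["concordant"] = concordant
    out["shortlisted"] = out.index.isin(shortlist)
    out["stage2_r"] = np.nan
    shared2 = [c for c in stage2_nes.columns if c in stage2_diff.index]
    for pw in shortlist:
        if pw not in stage2_nes.index:
            logger.warning("shortlisted pathway %s absent from stage-2 NES", pw)
            continue
        x = stage2_nes.loc[pw, shared2].to_numpy(dtype=float)
        y = stage2_diff[shared2].to_numpy(dtype=float)
        if np.isfinite(x).sum() < 3:
            continue
        r, _ = correlate(x, y, "pearson")
        out.loc[pw, "stage2_r"] = r
    ranked = out.loc[out["shortlisted"], "stage2_r"].sort_values(ascending=False)
    out["final_rank"] = np.nan
    out.loc[ranked.index, "final_rank"] = np.arange(1, len(ranked) + 1, dtype=float)
    return out.sort_values(
        ["final_rank", "stage1_mean_r"], ascending=[True, False], na_position="last"
    )
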