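"""Seeded synthetic-data generators with planted ground truth.

The generators emulate the statistical structure of the study designs the
pipeline consumes — splicing-factor perturbation screens (deltaPSI
signatures with planted regulons), a cell-line training panel (paired
exon-based and gene-based activities linked by a dense mixing matrix),
tumor/normal cohorts with planted splicing programs, and Perturb-seq style
negative-binomial counts — so that every recovery claim can be checked
against known truth.

Default sizes: 40 splicing factors (15 oncogenic-like, 15 tumor-
suppressor-like, 10 non-driver-like), 2000 exons, 2000 genes, 50 targets
per factor, 8 cohorts of 20+20 samples, 800 panel samples. Effect sizes
default to the scales of the real designs: deltaPSI effects of 20 PSI
units against |deltaPSI| >= 15 regulon thresholds, program shifts of 2 NES
units, knockdown expression responses of 1-2 log2 units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import FeatureMatrix, PerturbCellData, ValidationError
from .activity import NON_DRIVER, ONCOGENIC, TUMOR_SUPPRESSOR, ProgramDefinition
from .regulons import Regulon

DEFAULT_N_SF = 40
DEFAULT_N_ONC = 15
DEFAULT_N_TS = 15
DEFAULT_N_EXONS = 2000
DEFAULT_N_GENES = 2000
DEFAULT_TARGETS_PER_SF = 50
DEFAULT_MIXING_OFFDIAG_SD = 0.12


@dataclass
class GroundTruth:
    """Planted structure shared by all generators.

    ``exon_mor`` holds the knockdown-response sign of each planted target
    exon (the mor an inferred regulon should recover); ``gene_log2fc`` the
    planted knockdown log2 fold-change of each target gene. ``mixing``
    links latent (exon-based) activity to gene-based activity space.
    """

    sf_ids: list[str]
    classes: dict[str, str]
    exon_ids: list[str]
    gene_ids: list[str]
    exon_targets: dict[str, tuple[str, ...]]
    exon_mor: dict[str, np.ndarray]
    gene_targets: dict[str, tuple[str, ...]]
    gene_log2fc: dict[str, np.ndarray]
    exon_gene_map: dict[str, str]
    baseline_psi: np.ndarray
    mixing: np.ndarray
    seed: int

    def programs(self) -> ProgramDefinition:
        """The planted program classification."""
        return ProgramDefinition(dict(self.classes))

    def exon_regulons(self) -> list[Regulon]:
        """The planted splicing-factor->exon regulons (likelihood 1)."""
        return [
            Regulon(
                sf,
                self.exon_targets[sf],
                self.exon_mor[sf],
                np.ones(len(self.exon_targets[sf])),
            )
            for sf in self.sf_ids
        ]


def make_ground_truth(
    n_sf: int = DEFAULT_N_SF,
    n_onc: int = DEFAULT_N_ONC,
    n_ts: int = DEFAULT_N_TS,
    n_exons: int = DEFAULT_N_EXONS,
    n_genes: int = DEFAULT_N_GENES,
    targets_per_sf: int = DEFAULT_TARGETS_PER_SF,
    mixing_offdiag_sd: float = DEFAULT_MIXING_OFFDIAG_SD,
    seed: int = 0,
) -> GroundTruth:
    """Draw one planted configuration; bit-reproducible under ``seed``."""
    if n_onc + n_ts > n_sf:
        raise ValidationError("program sizes exceed the number of SFs")
    rng = np.random.default_rng(seed)
    sf_ids = [f"SF{i + 1:03d}" for i in range(n_sf)]
    # Splicing factors are genes: they occupy the head of the gene list so
    # that regulon targets can land in SF genes (cross-regulation analyses).
    gene_ids = sf_ids + [f"G{i + 1:05d}" for i in range(n_genes - n_sf)]
    exon_ids = [f"E{i + 1:05d}" for i in range(n_exons)]
    exon_gene_map = {e: gene_ids[i % n_genes] for i, e in enumerate(exon_ids)}
    classes = {}
    for i, sf in enumerate(sf_ids):
        if i < n_onc:
            classes[sf] = ONCOGENIC
        elif i < n_onc + n_ts:
            classes[sf] = TUMOR_SUPPRESSOR
        else:
            classes[sf] = NON_DRIVER
    exon_targets, exon_mor = {}, {}
    gene_targets, gene_log2fc = {}, {}
    for sf in sf_ids:
        eidx = rng.choice(n_exons, size=targets_per_sf, replace=False)
        exon_targets[sf] = tuple(exon_ids[i] for i in eidx)
        exon_mor[sf] = rng.choice([-1.0, 1.0], size=targets_per_sf)
        gidx = rng.choice(n_genes, size=targets_per_sf, replace=False)
        gene_targets[sf] = tuple(gene_ids[i] for i in gidx)
        sign = rng.choice([-1.0, 1.0], size=targets_per_sf)
        gene_log2fc[sf] = sign * rng.uniform(1.0, 2.0, size=targets_per_sf)
    baseline_psi = rng.uniform(20.0, 80.0, size=n_exons)
    mixing = np.eye(n_sf) + rng.normal(0.0, mixing_offdiag_sd, size=(n_sf, n_sf)) * (
        1 - np.eye(n_sf)
    )
    return GroundTruth(
        sf_ids,
        classes,
        exon_ids,
        gene_ids,
        exon_targets,
        exon_mor,
        gene_targets,
        gene_log2fc,
        exon_gene_map,
        baseline_psi,
        mixing,
        seed,
    )


def simulate_screen(
    truth: GroundTruth,
    dataset_name: str,
    effect: float = 20.0,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[FeatureMatrix, dict[str, str]]:
    """One perturbation screen: a deltaPSI signature per silenced SF.

    Each signature equals ``mor * effect`` on the factor's planted target
    exons plus Gaussian noise everywhere, clipped so that baseline PSI plus
    the signature stays within [0, 100]. Returns the signature matrix and
    the condition -> perturbed-SF map.
    """
    if effect < 0:
        raise ValidationError("effect must be >= 0")
    rng = np.random.default_rng(seed)
    n_exons = len(truth.exon_ids)
    cols, cond_map = {}, {}
    exon_index = {e: i for i, e in enumerate(truth.exon_ids)}
    for sf in truth.sf_ids:
        sig = rng.normal(0.0, noise_sd, size=n_exons)
        idx = np.array([exon_index[e] for e in truth.exon_targets[sf]])
        sig[idx] += truth.exon_mor[sf] * effect
        sig = np.clip(sig, -truth.baseline_psi, 100.0 - truth.baseline_psi)
        cond = f"{dataset_name}:{sf}"
        cols[cond] = sig
        cond_map[cond] = sf
    data = pd.DataFrame(cols, index=truth.exon_ids)
    return (
        FeatureMatrix(data, "signature", {"dataset": dataset_name, "seed": seed}),
        cond_map,
    )


def simulate_panel(
    truth: GroundTruth,
    n_samples: int = 800,
    noise_sd: float = 0.2,
    seed: int = 0,
) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Paired gene-based (X) and exon-based (Y) activity matrices.

    Latent activity Z ~ N(0, 1) per SF per sample; Y = Z + noise and
    X = M Z + noise with the truth's dense mixing matrix M. Emulates a
    cell-line training panel for the calibration models.
    """
    if n_samples < 10:
        raise ValidationError("panel needs >= 10 samples")
    rng = np.random.default_rng(seed)
    n_sf = len(truth.sf_ids)
    z = rng.normal(size=(n_sf, n_samples))
    y = z + rng.normal(0.0, noise_sd, size=z.shape)
    x = truth.mixing @ z + rng.normal(0.0, noise_sd, size=z.shape)
    samples = [f"S{i + 1:04d}" for i in range(n_samples)]
    x_mat = FeatureMatrix(
        pd.DataFrame(x, index=truth.sf_ids, columns=samples), "activity"
    )
    y_mat = FeatureMatrix(
        pd.DataFrame(y, index=truth.sf_ids, columns=samples), "activity"
    )
    return x_mat, y_mat


def simulate_cohorts(
    truth: GroundTruth,
    n_cohorts: int = 8,
    n_tumor: int = 20,
    n_normal: int = 20,
    program_effect: float = 2.0,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> list[tuple[FeatureMatrix, FeatureMatrix]]:
    """Per-cohort tumor and normal activity matrices with planted programs.

    Tumor samples shift oncogenic-like SFs by ``+program_effect`` and
    tumor-suppressor-like SFs by ``-program_effect`` over a shared
    per-cohort baseline; normal samples are unshifted. Gaussian noise on
    both sides.
    """
    if program_effect < 0:
        raise ValidationError("program_effect must be >= 0")
    rng = np.random.default_rng(seed)
    n_sf = len(truth.sf_ids)
    shift = np.array(
        [
            program_effect
            if truth.classes[sf] == ONCOGENIC
            else -program_effect
            if truth.classes[sf] == TUMOR_SUPPRESSOR
            else 0.0
            for sf in truth.sf_ids
        ]
    )
    cohorts = []
    for c in range(n_cohorts):
        baseline = rng.normal(size=n_sf)
        tum = (
            baseline[:, None]
            + shift[:, None]
            + rng.normal(0.0, noise_sd, size=(n_sf, n_tumor))
        )
        nor = baseline[:, None] + rng.normal(0.0, noise_sd, size=(n_sf, n_normal))
        tum_fm = FeatureMatrix(
            pd.DataFrame(
                tum,
                index=truth.sf_ids,
                columns=[f"C{c + 1:02d}T{i + 1:03d}" for i in range(n_tumor)],
            ),
            "activity",
        )
        nor_fm = FeatureMatrix(
            pd.DataFrame(
                nor,
                index=truth.sf_ids,
                columns=[f"C{c + 1:02d}N{i + 1:03d}" for i in range(n_normal)],
            ),
            "activity",
        )
        cohorts.append((tum_fm, nor_fm))
    return cohorts


def simulate_state_signature(
    truth: GroundTruth,
    state: str = "tumorigenic-like",
    magnitude: float = 5.0,
    noise_sd: float = 1.0,
    n_conditions: int = 1,
    seed: int = 0,
) -> FeatureMatrix:
    """Exon signatures of a planted program state.

    In the ``tumorigenic-like`` state the target exons of oncogenic-like
    SFs move along their regulon mor (so those factors score high NES) and
    tumor-suppressor-like targets move against it; ``pre-tumorigenic-like``
    reverses both. Feeding these signatures through inferred regulons and
    the enrichment engine should reproduce the planted sign of the program
    difference reporter.
    """
    if state not in {"tumorigenic-like", "pre-tumorigenic-like"}:
        raise ValidationError(f"unknown state {state!r}")
    flip = 1.0 if state == "tumorigenic-like" else -1.0
    rng = np.random.default_rng(seed)
    exon_index = {e: i for i, e in enumerate(truth.exon_ids)}
    cols = {}
    for c in range(n_conditions):
        sig = rng.normal(0.0, noise_sd, size=len(truth.exon_ids))
        for sf in truth.sf_ids:
            cls = truth.classes[sf]
            if cls == ONCOGENIC:
                direction = flip
            elif cls == TUMOR_SUPPRESSOR:
                direction = -flip
            else:
                continue
            idx = np.array([exon_index[e] for e in truth.exon_targets[sf]])
            sig[idx] += direction * truth.exon_mor[sf] * magnitude
        cols[f"{state}:{c + 1}"] = sig
    return FeatureMatrix(
        pd.DataFrame(cols, index=truth.exon_ids), "signature", {"state": state}
    )


def simulate_pathway_study(
    n_conditions: int,
    n_genes: int = 500,
    n_sets: int = 10,
    set_size: int = 20,
    coupling: float = 0.5,
    noise_sd: float = 0.5,
    seed: int = 0,
):
    """Gene-level signatures with one planted "mediator" pathway.

    Returns ``(sets, signatures, program_diff)``: ``n_sets`` disjoint gene
    sets (the first, named ``mediator``, has its member genes shifted by
    ``coupling`` times the condition's program difference), log2FC-style
    signatures over ``n_genes`` genes, and the per-condition program
    difference. Feeding the signatures through preranked GSEA and the
    two-stage prioritization should rank the mediator first.
    """
    from .io import GeneSetCollection

    rng = np.random.default_rng(seed)
    gene_ids = [f"PG{i + 1:05d}" for i in range(n_genes)]
    if n_sets * set_size > n_genes:
        raise ValidationError("gene sets exceed the universe")
    sets = {}
    for s in range(n_sets):
        members = set(gene_ids[s * set_size : (s + 1) * set_size])
        sets["mediator" if s == 0 else f"set{s:02d}"] = members
    diffs = pd.Series(
        rng.uniform(-2.0, 2.0, size=n_conditions),
        index=[f"cond{c + 1:02d}" for c in range(n_conditions)],
        name="program_difference",
    )
    mediator_idx = np.arange(set_size)
    cols = {}
    for cond in diffs.index:
        sig = rng.normal(0.0, noise_sd, size=n_genes)
        sig[mediator_idx] += coupling * diffs[cond]
        cols[cond] = sig
    signatures = FeatureMatrix(pd.DataFrame(cols, index=gene_ids), "signature")
    return GeneSetCollection(sets), signatures, diffs


def simulate_perturbseq(
    truth: GroundTruth,
    cells_per_label: int = 50,
    depth: float = 20000.0,
    dispersion: float = 0.3,
    seed: int = 0,
    labels: list[str] | None = None,
    control_label: str = "control",
) -> PerturbCellData:
    """Perturb-seq style counts: negative binomial around planted shifts.

    Gene means follow a log-normal baseline scaled to the stated depth
    (expected total counts per cell). Cells of a perturbed label shift
    their factor's planted target genes by its knockdown log2 fold-change;
    control cells follow the baseline. Counts are negative binomial with
    variance mu + dispersion * mu^2.
    """
    if cells_per_label < 1:
        raise ValidationError("cells_per_label must be >= 1")
    rng = np.random.default_rng(seed)
    if labels is None:
        labels = list(truth.sf_ids)
    n_genes = len(truth.gene_ids)
    gene_index = {g: i for i, g in enumerate(truth.gene_ids)}
    base_weight = rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)
    all_labels = [control_label, *labels]
    counts = np.zeros((cells_per_label * len(all_labels), n_genes), dtype=int)
    cell_ids, mapping = [], {}
    row = 0
    for lab in all_labels:
        weight = base_weight.copy()
        if lab != control_label:
            idx = np.array([gene_index[g] for g in truth.gene_targets[lab]])
            weight[idx] = weight[idx] * 2.0 ** truth.gene_log2fc[lab]
        mu = weight / weight.sum() * depth
        n_param = 1.0 / dispersion
        p_param = n_param / (n_param + mu)
        for _ in range(cells_per_label):
            counts[row] = rng.negative_binomial(n_param, p_param)
            cid = f"cell{row + 1:06d}"
            cell_ids.append(cid)
            mapping[cid] = lab
            row += 1
    return PerturbCellData(
        counts, cell_ids, list(truth.gene_ids), mapping, control_label
    )
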