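"""Readers and writers for every on-disk artifact the pipeline consumes.

All tabular formats are plain tab-separated text. Missing values are
serialized as the literal ``NA`` (the tidy convention of exon-inclusion
quantifiers such as vast-tools) and represented internally as ``NaN``.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import networkx as nx
import scipy.io
import scipy.sparse

logger = logging.getLogger("sfactivity")

MISSING = "NA"

#: Recognised matrix kinds and their admissible value ranges (inclusive).
MATRIX_KINDS = {
    "psi": (0.0, 100.0),
    "tpm": (0.0, np.inf),
    "log_expr": (-np.inf, np.inf),
    "signature": (-np.inf, np.inf),
    "activity": (-np.inf, np.inf),
    "nes": (-np.inf, np.inf),
}


class ParseError(ValueError):
    """A file does not follow the expected dialect."""


class ValidationError(ValueError):
    """A parsed value violates the contract of its kind."""


def file_digest(path: str | Path) -> str:
    """SHA-256 of a file, used to log input provenance."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


# ---------------------------------------------------------------------------
# FeatureMatrix
# ---------------------------------------------------------------------------


@dataclass
class FeatureMatrix:
    """A features x samples real matrix with a kind tag.

    Parameters
    ----------
    data
        DataFrame indexed by feature id with sample ids as columns.
        Missing entries are ``NaN``.
    kind
        One of ``psi`` (exon inclusion, 0-100), ``tpm`` (expression >= 0),
        ``log_expr``, ``signature``, ``activity`` or ``nes``.
    provenance
        Free-form record of how the matrix was derived (reference
        samples, aggregation statistic, ...).
    """

    data: pd.DataFrame
    kind: str
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in MATRIX_KINDS:
            raise ValidationError(f"unknown matrix kind {self.kind!r}")
        if not self.data.index.is_unique:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValidationError(f"duplicate feature id {dup!r}")
        if not self.data.columns.is_unique:
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise ValidationError(f"duplicate sample id {dup!r}")
        self.data = self.data.astype(float)
        _check_range(self.data, self.kind)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def equals(self, other: "FeatureMatrix") -> bool:
        return self.kind == other.kind and self.data.equals(other.data)


def _check_range(data: pd.DataFrame, kind: str) -> None:
    lo, hi = MATRIX_KINDS[kind]
    if not np.isfinite(lo) and not np.isfinite(hi):
        return
    arr = data.to_numpy()
    bad = (arr < lo) | (arr > hi)
    bad &= ~np.isnan(arr)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValidationError(
            f"value {arr[i, j]} out of range [{lo}, {hi}] for kind {kind!r} "
            f"at feature {data.index[i]!r}, sample {data.columns[j]!r}"
        )


def read_matrix(path: str | Path, kind: str) -> FeatureMatrix:
    """Read a TSV matrix (first column feature id, header row sample ids)."""
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            index_col=0,
            na_values=[MISSING],
            keep_default_na=False,
            float_precision="round_trip",
        )
    except Exception as exc:  # malformed file
        raise ParseError(f"cannot parse matrix file {path}: {exc}") from exc
    if df.columns.size == 0:
        raise ParseError(f"{path}: header row has no sample ids")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric value: {exc}") from exc
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return FeatureMatrix(df, kind)


def write_matrix(matrix: FeatureMatrix, path: str | Path) -> None:
    """Write a FeatureMatrix as TSV; NaN becomes ``NA``. Round-trip exact."""
    df = matrix.data.copy()
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t", na_rep=MISSING)


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------


@dataclass
class GeneSetCollection:
    """Named gene sets with optional descriptions."""

    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: ``name TAB description TAB member...`` per line."""
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 tab-separated fields")
            name, desc = fields[0], fields[1]
            if name in sets:
                raise ParseError(f"{path}:{lineno}: duplicate set name {name!r}")
            members = {m for m in fields[2:] if m}
            sets[name] = members
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions) if sets else GeneSetCollection({}, {})


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


# ---------------------------------------------------------------------------
# Interaction graph (STRING-style edge list)
# ---------------------------------------------------------------------------


def read_graph(path: str | Path, min_score: int = 900) -> nx.Graph:
    """Read an undirected edge list TSV (node1, node2, combined_score).

    Only edges with ``combined_score`` strictly greater than ``min_score``
    are kept. Duplicate edges (in either orientation) collapse to the
    maximum score; self-loops are dropped.
    """
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 3:
        raise ParseError(f"{path}: expected columns node1, node2, combined_score")
    n1, n2, sc = df.columns[:3]
    scores = df[sc]
    if not pd.api.types.is_integer_dtype(scores):
        raise ParseError(f"{path}: combined_score column must be integer")
    if ((scores < 0) | (scores > 1000)).any():
        raise ValidationError(f"{path}: combined_score outside [0, 1000]")
    graph = nx.Graph()
    for a, b, s in zip(df[n1].astype(str), df[n2].astype(str), scores):
        if a == b:
            continue
        if s <= min_score:
            continue
        if graph.has_edge(a, b):
            s = max(s, graph.edges[a, b]["combined_score"])
        graph.add_edge(a, b, combined_score=int(s))
    return graph


def write_graph(graph: nx.Graph, path: str | Path) -> None:
    rows = [
        (a, b, data["combined_score"])
        for a, b, data in sorted(graph.edges(data=True))
    ]
    pd.DataFrame(rows, columns=["node1", "node2", "combined_score"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Exon -> gene map
# ---------------------------------------------------------------------------


def read_exon_gene_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV mapping exon id -> gene symbol."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ParseError(f"{path}: expected columns exon_id, gene")
    exons = df.iloc[:, 0].astype(str)
    if exons.duplicated().any():
        dup = exons[exons.duplicated()].iloc[0]
        raise ValidationError(f"{path}: duplicate exon id {dup!r}")
    return dict(zip(exons, df.iloc[:, 1].astype(str)))


def write_exon_gene_map(mapping: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(
        sorted(mapping.items()), columns=["exon_id", "gene"]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Perturb-seq cells
# ---------------------------------------------------------------------------


@dataclass
class PerturbCellData:
    """Single-cell counts with a cell -> perturbation label map.

    ``counts`` is cells x genes, non-negative integers (dense ndarray or
    scipy sparse). ``control_label`` marks non-targeting control cells and
    must occur at least once.
    """

    counts: np.ndarray | scipy.sparse.spmatrix
    cell_ids: list[str]
    gene_ids: list[str]
    cell_to_perturbation: dict[str, str]
    control_label: str

    def __post_init__(self) -> None:
        n_cells, n_genes = self.counts.shape
        if n_cells != len(self.cell_ids) or n_genes != len(self.gene_ids):
            raise ValidationError("counts shape does not match cell/gene ids")
        missing = [c for c in self.cell_ids if c not in self.cell_to_perturbation]
        if missing:
            raise ValidationError(f"cells missing from metadata: {missing[:5]}")
        labels = {self.cell_to_perturbation[c] for c in self.cell_ids}
        if self.control_label not in labels:
            raise ValidationError(
                f"control label {self.control_label!r} absent from metadata"
            )
        arr = self.counts.data if scipy.sparse.issparse(self.counts) else self.counts
        if np.asarray(arr).size and np.asarray(arr).min() < 0:
            raise ValidationError("negative count encountered")
        if not np.allclose(np.asarray(arr, dtype=float) % 1, 0):
            raise ValidationError("non-integer count encountered")

    @property
    def labels(self) -> list[str]:
        seen: list[str] = []
        for c in self.cell_ids:
            lab = self.cell_to_perturbation[c]
            if lab not in seen:
                seen.append(lab)
        return seen


def read_perturb_cells(
    counts_path: str | Path, metadata_path: str | Path, control_label: str
) -> PerturbCellData:
    """Load cell x gene counts plus a metadata TSV (cell_id, perturbation).

    ``counts_path`` may be a dense TSV (first column cell id, header gene
    ids) or a MatrixMarket ``.mtx`` file with sidecars ``<path>.rows``
    (cell ids) and ``<path>.cols`` (gene ids), one id per line.
    """
    counts_path = Path(counts_path)
    if counts_path.suffix == ".mtx":
        counts = scipy.sparse.csr_matrix(scipy.io.mmread(counts_path))
        cell_ids = Path(str(counts_path) + ".rows").read_text().split()
        gene_ids = Path(str(counts_path) + ".cols").read_text().split()
    else:
        df = pd.read_csv(counts_path, sep="\t", index_col=0)
        counts = df.to_numpy()
        cell_ids = [str(c) for c in df.index]
        gene_ids = [str(g) for g in df.columns]
    meta = pd.read_csv(metadata_path, sep="\t")
    if not {"cell_id", "perturbation"} <= set(meta.columns):
        raise ParseError(f"{metadata_path}: expected columns cell_id, perturbation")
    mapping = dict(zip(meta["cell_id"].astype(str), meta["perturbation"].astype(str)))
    return PerturbCellData(counts, cell_ids, gene_ids, mapping, control_label)


def write_perturb_cells(
    cells: PerturbCellData, counts_path: str | Path, metadata_path: str | Path
) -> None:
    counts = cells.counts
    if scipy.sparse.issparse(counts):
        counts = counts.toarray()
    pd.DataFrame(
        np.asarray(counts, dtype=int), index=cells.cell_ids, columns=cells.gene_ids
    ).rename_axis("cell_id").to_csv(counts_path, sep="\t")
    pd.DataFrame(
        {
            "cell_id": cells.cell_ids,
            "perturbation": [cells.cell_to_perturbation[c] for c in cells.cell_ids],
        }
    ).to_csv(metadata_path, sep="\t", index=False)
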