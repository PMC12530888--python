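"""Shallow linear calibration of gene-based onto exon-based activities.

Activities estimated from splicing-factor->gene networks systematically
differ from those estimated from splicing-factor->exon networks (the
reference). Two shallow architectures close that gap:

* ``elementwise`` — an independent scale and bias per splicing factor
  (a per-factor linear model);
* ``dense`` — a single fully connected linear layer, letting every
  factor's adjusted activity draw on all input activities.

Training follows a k-fold scheme: the samples are split into k disjoint
parts; each replicate is trained on k-1 parts by seeded minibatch Adam
minimizing the mean smooth-L1 (Huber, beta = 1) loss, and validated on its
held-out part. Inference averages the k replicate outputs into a consensus
adjusted activity matrix.

Defaults: 20 epochs, batch size 64, learning rate 0.01, k = 5.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import FeatureMatrix, ValidationError

logger = logging.getLogger("sfactivity")

DEFAULT_CONFIG = {
    "epochs": 20,
    "batch_size": 64,
    "learning_rate": 0.01,
    "k": 5,
    "init": "identity",  # or "random"
    "zscore": False,  # train on raw NES by default
    "optimizer": "adam",
}


@dataclass
class Replicate:
    """One fold's trained linear map plus its evaluation record."""

    weights: np.ndarray  # dense: (out, in); elementwise: (n,)
    bias: np.ndarray  # (out,)
    fold: int
    val_samples: list[str]
    train_r: float
    val_r: float
    epoch_losses: list[float] = field(default_factory=list)

    def forward(self, x: np.ndarray, architecture: str) -> np.ndarray:
        """x is (samples, in_features); returns (samples, out_features)."""
        if architecture == "dense":
            return x @ self.weights.T + self.bias
        return x * self.weights + self.bias


@dataclass
class CalibrationEnsemble:
    """k replicate linear maps from gene-based to exon-based activity space."""

    architecture: str
    input_sf_order: list[str]
    output_sf_order: list[str]
    replicates: list[Replicate]
    training_config: dict
    seed: int

    def __post_init__(self) -> None:
        if self.architecture not in {"elementwise", "dense"}:
            raise ValidationError(f"unknown architecture {self.architecture!r}")
        if not self.replicates:
            raise ValidationError("ensemble needs >= 1 replicate")
        if self.architecture == "elementwise" and (
            self.input_sf_order != self.output_sf_order
        ):
            raise ValidationError(
                "elementwise architecture requires identical input/output SF sets"
            )
        for r in self.replicates:
            if not (np.isfinite(r.weights).all() and np.isfinite(r.bias).all()):
                raise ValidationError(f"non-finite weights in fold {r.fold}")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "architecture": self.architecture,
            "input_sf_order": self.input_sf_order,
            "output_sf_order": self.output_sf_order,
            "replicates": [
                {
                    ("W" if self.architecture == "dense" else "a"): r.weights.tolist(),
                    "b": r.bias.tolist(),
                    "fold": r.fold,
                    "val_samples": r.val_samples,
                    "train_r": r.train_r,
                    "val_r": r.val_r,
                }
                for r in self.replicates
            ],
            "training_config": self.training_config,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationEnsemble":
        payload = json.loads(Path(path).read_text())
        arch = payload["architecture"]
        reps = [
            Replicate(
                np.asarray(r["W" if arch == "dense" else "a"], dtype=float),
                np.asarray(r["b"], dtype=float),
                r["fold"],
                list(r.get("val_samples", [])),
                r.get("train_r", float("nan")),
                r.get("val_r", float("nan")),
            )
            for r in payload["replicates"]
        ]
        return cls(
            arch,
            list(payload["input_sf_order"]),
            list(payload["output_sf_order"]),
            reps,
            dict(payload["training_config"]),
            int(payload["seed"]),
        )


@dataclass
class CalibrationReport:
    """Pooled Pearson correlations per fold and overall."""

    per_fold: pd.DataFrame  # columns: fold, train_r, val_r
    overall_train_r: float
    overall_val_r: float


# ---------------------------------------------------------------------------
# Training internals
# ---------------------------------------------------------------------------


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson r over pooled finite pairs; NaN (with warning) at zero variance."""
    mask = np.isfinite(a) & np.isfinite(b)
    a, b = a[mask], b[mask]
    if a.size < 3:
        raise ValidationError("fewer than 3 paired values for correlation")
    if a.std() == 0 or b.std() == 0:
        logger.warning("zero variance: correlation undefined")
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def _smooth_l1(residual: np.ndarray) -> float:
    """Mean smooth-L1 (beta=1): quadratic for |r|<1, linear beyond."""
    a = np.abs(residual)
    return float(np.where(a < 1, 0.5 * a**2, a - 0.5).mean())


def _folds(n: int, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Disjoint, exhaustive, seeded k-fold split of range(n)."""
    perm = rng.permutation(n)
    return [np.sort(part) for part in np.array_split(perm, k)]


class _Adam:
    def __init__(self, shapes: list[tuple[int, ...]], lr: float):
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g**2
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _train_replicate(
    x: np.ndarray,
    y: np.ndarray,
    architecture: str,
    config: dict,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """Minibatch Adam on smooth-L1; returns (weights, bias, epoch losses)."""
    n, n_in = x.shape
    n_out = y.shape[1]
    if architecture == "dense":
        if config["init"] == "identity":
            w = np.zeros((n_out, n_in))
            w[: min(n_out, n_in), : min(n_out, n_in)] = np.eye(min(n_out, n_in))
        else:
            w = rng.normal(0, 0.1, size=(n_out, n_in))
        params = [w, np.zeros(n_out)]
    else:
        if config["init"] == "identity":
            a = np.ones(n_in)
        else:
            a = rng.normal(1, 0.1, size=n_in)
        params = [a, np.zeros(n_in)]
    opt = _Adam([p.shape for p in params], config["learning_rate"])
    batch = int(config["batch_size"])
    losses = []
    for _epoch in range(int(config["epochs"])):
        order = rng.permutation(n)
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, n, batch):
            idx = order[start : start + batch]
            xb, yb = x[idx], y[idx]
            if architecture == "dense":
                pred = xb @ params[0].T + params[1]
            else:
                pred = xb * params[0] + params[1]
            residual = pred - yb
            loss = _smooth_l1(residual)
            if not np.isfinite(loss):
                raise ValidationError(f"non-finite training loss at epoch {_epoch}")
            epoch_loss += loss
            n_batches += 1
            dpred = np.clip(residual, -1.0, 1.0) / residual.size
            if architecture == "dense":
                grads = [dpred.T @ xb, dpred.sum(axis=0)]
            else:
                grads = [(dpred * xb).sum(axis=0), dpred.sum(axis=0)]
            opt.step(params, grads)
        losses.append(epoch_loss / max(n_batches, 1))
    return params[0], params[1], losses


def _aligned_arrays(
    x_mat: FeatureMatrix, y_mat: FeatureMatrix
) -> tuple[np.ndarray, np.ndarray, list[str], list[str], list[str]]:
    shared = [s for s in x_mat.data.columns if s in set(y_mat.data.columns)]
    if not shared:
        raise ValidationError("X and Y share no samples")
    x = np.nan_to_num(x_mat.data[shared].to_numpy().T, nan=0.0)
    y = np.nan_to_num(y_mat.data[shared].to_numpy().T, nan=0.0)
    return x, y, shared, list(x_mat.data.index), list(y_mat.data.index)


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------


def fit(
    x_mat: FeatureMatrix,
    y_mat: FeatureMatrix,
    architecture: str = "dense",
    config: dict | None = None,
    seed: int = 0,
) -> CalibrationEnsemble:
    """Train a k-fold ensemble mapping X (gene-based) onto Y (exon-based).

    Missing activities are imputed as 0 (the NES null value). Samples are
    the shared columns of X and Y; each fold's replicate trains on the
    other k-1 folds and is scored (pooled Pearson) on its training and
    held-out samples.
    """
    cfg = dict(DEFAULT_CONFIG)
    if config:
        cfg.update(config)
    x, y, samples, in_order, out_order = _aligned_arrays(x_mat, y_mat)
    if architecture == "elementwise" and in_order != out_order:
        raise ValidationError("elementwise requires identical input/output SFs")
    k = int(cfg["k"])
    if len(samples) < 2 * k:
        raise ValidationError(f"need >= {2 * k} samples for k={k} folds")
    if cfg["zscore"]:
        x = (x - x.mean(axis=0)) / np.where(x.std(axis=0) == 0, 1, x.std(axis=0))
        y = (y - y.mean(axis=0)) / np.where(y.std(axis=0) == 0, 1, y.std(axis=0))
    rng = np.random.default_rng(seed)
    folds = _folds(len(samples), k, rng)
    replicates = []
    for fold_id, val_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(len(samples)), val_idx)
        w, b, losses = _train_replicate(
            x[train_idx], y[train_idx], architecture, cfg, rng
        )
        rep = Replicate(w, b, fold_id, [samples[i] for i in val_idx], 0.0, 0.0, losses)
        rep.train_r = _pearson(
            rep.forward(x[train_idx], architecture).ravel(), y[train_idx].ravel()
        )
        rep.val_r = _pearson(
            rep.forward(x[val_idx], architecture).ravel(), y[val_idx].ravel()
        )
        replicates.append(rep)
        logger.info(
            "fold %d: train r=%.4f, validation r=%.4f", fold_id, rep.train_r, rep.val_r
        )
    return CalibrationEnsemble(
        architecture, in_order, out_order, replicates, cfg, seed
    )


def apply(ensemble: CalibrationEnsemble, x_mat: FeatureMatrix) -> FeatureMatrix:
    """Consensus-adjusted activities: mean over replicate forward passes.

    Input SFs missing from X are imputed as all-zero rows.
    """
    aligned = x_mat.data.reindex(ensemble.input_sf_order)
    x = np.nan_to_num(aligned.to_numpy().T, nan=0.0)
    preds = [r.forward(x, ensemble.architecture) for r in ensemble.replicates]
    consensus = np.mean(preds, axis=0).T
    out = pd.DataFrame(
        consensus, index=ensemble.output_sf_order, columns=x_mat.data.columns
    )
    return FeatureMatrix(out, "activity", {"adjusted_by": ensemble.architecture})


def evaluate(
    ensemble: CalibrationEnsemble, x_mat: FeatureMatrix, y_mat: FeatureMatrix
) -> CalibrationReport:
    """Pearson of predictions vs Y, per fold (on each fold's held-out
    samples present in X/Y) and overall for the consensus prediction."""
    x_in = x_mat.data.reindex(ensemble.input_sf_order)
    y_out = y_mat.data.reindex(ensemble.output_sf_order)
    shared = [s for s in x_in.columns if s in set(y_out.columns)]
    if not shared:
        raise ValidationError("X and Y share no samples")
    x = np.nan_to_num(x_in[shared].to_numpy().T, nan=0.0)
    y = y_out[shared].to_numpy().T
    rows = []
    for rep in ensemble.replicates:
        pred = rep.forward(x, ensemble.architecture)
        val_mask = np.array([s in set(rep.val_samples) for s in shared])
        train_r = (
            _pearson(pred[~val_mask].ravel(), y[~val_mask].ravel())
            if (~val_mask).sum() else float("nan")
        )
        val_r = (
            _pearson(pred[val_mask].ravel(), y[val_mask].ravel())
            if val_mask.sum() else float("nan")
        )
        rows.append({"fold": rep.fold, "train_r": train_r, "val_r": val_r})
    per_fold = pd.DataFrame(rows)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_train = float(np.nanmean(per_fold["train_r"]))
        mean_val = float(np.nanmean(per_fold["val_r"]))
    return CalibrationReport(per_fold, mean_train, mean_val)
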