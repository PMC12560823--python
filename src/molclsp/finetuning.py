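"""Fine-tuning: attention pooling over fused rows, prediction head, training
loop and per-substructure attention export.

The fused matrix H_f (one row per 1D substructure token, per 2D atom and —
when the 3D branch is on — per 3D atom) is pooled with a learned scoring
vector w:

    alpha_i = softmax_i( w . tanh(h_i) ),     z = sum_i alpha_i h_i

so alpha is a strict probability vector over the k = e + n (+ n) rows and z
lies in their convex hull.  z feeds a small MLP head; classification heads
emit a sigmoid probability, regression heads a raw value.  The alpha vector
itself is the interpretability surface: `export_substructure_attention`
labels every weight with its modality and fragment/atom.
"""

from __future__ import annotations

import copy
import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.metrics import roc_auc_score

from .autodiff import Tensor, softmax, tensor
from .backbone import Backbone, ModalityEmbeddings, save_checkpoint
from .chemio import DatasetSplit, MoleculeRecord
from .errors import ConfigurationError, InputError
from .espf import SubstructureVocab
from .nn import Adam, Linear, Module
from .pretraining import PreparedMolecule, prepare_molecules

__all__ = [
    "PooledRepresentation",
    "FinetuneConfig",
    "FinetuneModel",
    "attention_pool",
    "predict",
    "run_finetune",
    "export_substructure_attention",
    "auroc",
]


@dataclass
class PooledRepresentation:
    H_f: Tensor          # (k, d) rows entering pooling
    alpha: Tensor        # (k,) strict probability vector
    pooled: Tensor       # (d,) convex combination of the rows

    def validate(self) -> None:
        a = self.alpha.data
        if abs(a.sum() - 1.0) > 1e-6 or np.any(a <= 0):
            raise InputError("attention weights are not a strict probability vector")


def attention_pool(H_f, w) -> PooledRepresentation:
    """Softmax-weighted aggregation of rows: alpha_i ∝ exp(w . tanh(h_i))."""
    H_f, w = tensor(H_f), tensor(w)
    if H_f.ndim != 2 or H_f.shape[0] < 1:
        raise InputError(f"pooling needs a (k>=1, d) matrix, got {H_f.shape}")
    scores = H_f.tanh() @ w
    alpha = softmax(scores, axis=-1)
    pooled = alpha @ H_f
    rep = PooledRepresentation(H_f=H_f, alpha=alpha, pooled=pooled)
    rep.validate()
    return rep


@dataclass
class FinetuneConfig:
    task: str = "classification"       # or "regression"
    label: str = "halogen"
    use_3d: bool = False
    head_hidden: int = 64
    lr: float = 5e-4    # full-network tuning at 1e-3 tends to oscillate
    epochs: int = 40
    batch_size: int = 8
    seed: int = 0
    freeze_encoders: bool = False

    def validate(self) -> None:
        if self.task not in ("classification", "regression"):
            raise ConfigurationError(f"unknown task type {self.task!r}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


class FinetuneModel(Module):
    """Pretrained backbone + pooling vector + prediction MLP."""

    def __init__(self, backbone: Backbone, cfg: FinetuneConfig):
        cfg.validate()
        rng = np.random.default_rng(cfg.seed + 1)
        d = backbone.cfg.d
        self.backbone = backbone
        self.cfg = cfg
        self.w = Tensor(rng.normal(0, 0.1, size=d), requires_grad=True)
        self.head1 = Linear(d, cfg.head_hidden, rng)
        self.head2 = Linear(cfg.head_hidden, 1, rng)

    def trainable_parameters(self):
        head = [self.w] + self.head1.parameters() + self.head2.parameters()
        if self.cfg.freeze_encoders:
            return head
        return head + self.backbone.parameters()

    def forward(self, prep: PreparedMolecule) -> tuple[Tensor, PooledRepresentation]:
        """Clean (unperturbed) forward pass -> (raw score, pooled rows)."""
        rec = prep.record
        if self.cfg.use_3d and rec.conformer is None:
            raise InputError(f"use_3d=True but record {rec.id!r} has no conformer")
        x1d = self.backbone.encode_1d(prep.tok.token_ids)
        x2d = self.backbone.encode_2d(prep.graph)
        x3d = (
            self.backbone.encode_3d(prep.graph, rec.conformer) if self.cfg.use_3d else None
        )
        fused = self.backbone.fuse(ModalityEmbeddings(x1d=x1d, x2d=x2d, x3d=x3d))
        rep = attention_pool(fused.fused, self.w)
        score = self.head2(self.head1(rep.pooled).tanh())
        return score.reshape(()), rep


def _sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    return np.where(np.asarray(x) >= 0, 1.0 / (1.0 + np.exp(-np.asarray(x))),
                    np.exp(np.asarray(x)) / (1.0 + np.exp(np.asarray(x))))


def _softplus(x: Tensor) -> Tensor:
    # log(1 + e^x) = relu(x) + log(1 + e^{-|x|}), overflow-safe
    absx = x.relu() + (-x).relu()
    return x.relu() + (1.0 + (-absx).exp()).log()


def predict(record: MoleculeRecord, model: FinetuneModel, vocab: SubstructureVocab) -> float:
    """Probability (classification) or raw value (regression) for one molecule."""
    prep = prepare_molecules([record], vocab, model.backbone.cfg.max_len)[0]
    score, _ = model.forward(prep)
    val = score.item()
    return float(_sigmoid(val)) if model.cfg.task == "classification" else float(val)


def export_substructure_attention(
    record: MoleculeRecord, model: FinetuneModel, vocab: SubstructureVocab
) -> list[dict]:
    """Per-row attention weights of the pooled representation, each labeled
    by (modality, index, fragment string or atom symbol).  Sums to 1."""
    prep = prepare_molecules([record], vocab, model.backbone.cfg.max_len)[0]
    _, rep = model.forward(prep)
    mol = record.mol()
    rows = []
    e, n = prep.tok.e, prep.graph.n
    alpha = rep.alpha.data
    for i in range(e):
        rows.append({"modality": "1d", "index": i,
                     "descriptor": prep.tok.fragments[i], "alpha": float(alpha[i])})
    for i in range(n):
        rows.append({"modality": "2d", "index": i,
                     "descriptor": mol.GetAtomWithIdx(i).GetSymbol(), "alpha": float(alpha[e + i])})
    if model.cfg.use_3d:
        for i in range(n):
            rows.append({"modality": "3d", "index": i,
                         "descriptor": mol.GetAtomWithIdx(i).GetSymbol(),
                         "alpha": float(alpha[e + n + i])})
    return rows


def auroc(labels: list[float], scores: list[float]) -> float:
    """Area under the ROC curve; NaN when only one class is present."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        return float("nan")
    return float(roc_auc_score(labels, np.asarray(scores)))


def _evaluate(model, preps, label, task):
    ys, ss = [], []
    for prep in preps:
        if prep.record.labels is None or label not in prep.record.labels:
            continue
        score, _ = model.forward(prep)
        ys.append(prep.record.labels[label])
        ss.append(score.item())
    if not ys:
        return float("nan"), [], []
    if task == "classification":
        return auroc(ys, ss), ys, [float(_sigmoid(s)) for s in ss]
    preds = ss
    return float(np.mean(np.abs(np.asarray(ys) - np.asarray(preds)))), ys, preds


def run_finetune(
    records: list[MoleculeRecord],
    split: DatasetSplit,
    backbone: Backbone,
    vocab: SubstructureVocab,
    cfg: FinetuneConfig,
    out_dir: str | Path | None = None,
) -> dict:
    """Fine-tune on `split.train`, select the epoch by the validation metric,
    report the test metric at the chosen epoch.

    Classification minimizes binary cross entropy on sigmoid outputs and
    reports AUROC; regression minimizes (and reports) mean absolute error.
    With `cfg.epochs == 0` the report reflects the frozen checkpoint.
    """
    cfg.validate()
    by_id = {r.id: r for r in records}
    def subset(ids):
        recs = [by_id[i] for i in ids if i in by_id]
        labeled = [r for r in recs if r.labels and cfg.label in r.labels]
        return labeled
    train = subset(split.train)
    if not train:
        raise InputError(f"no training record carries label {cfg.label!r}")
    valid, test = subset(split.valid), subset(split.test)

    model = FinetuneModel(backbone, cfg)
    max_len = backbone.cfg.max_len
    train_p = prepare_molecules(train, vocab, max_len)
    valid_p = prepare_molecules(valid, vocab, max_len) if valid else []
    test_p = prepare_molecules(test, vocab, max_len) if test else []

    optimizer = Adam(model.trainable_parameters(), lr=cfg.lr)
    rng = np.random.default_rng(cfg.seed)
    higher_better = cfg.task == "classification"
    history: list[dict] = []
    best = None  # (metric, epoch, param snapshot)

    def snapshot():
        return [p.data.copy() for p in model.parameters()]

    def restore(snap):
        for p, arr in zip(model.parameters(), snap):
            p.data = arr.copy()

    for epoch in range(cfg.epochs):
        order = rng.permutation(len(train_p))
        for lo in range(0, len(order), cfg.batch_size):
            batch = [train_p[i] for i in order[lo : lo + cfg.batch_size]]
            total = None
            for prep in batch:
                score, _ = model.forward(prep)
                y = float(prep.record.labels[cfg.label])
                if cfg.task == "classification":
                    loss = _softplus(score) - y * score  # BCE with logits
                else:
                    diff = score - y
                    loss = (diff * diff + 1e-12) ** 0.5  # smooth |error|
                total = loss if total is None else total + loss
            total = total / float(len(batch))
            optimizer.zero_grad()
            total.backward()
            optimizer.step()
        vmetric, _, _ = _evaluate(model, valid_p, cfg.label, cfg.task)
        history.append({"epoch": epoch, "valid_metric": vmetric})
        if not np.isnan(vmetric):
            # ties go to the later epoch: keep refining calibration while the
            # validation metric does not degrade
            better = best is None or (
                vmetric >= best[0] if higher_better else vmetric <= best[0]
            )
            if better:
                best = (vmetric, epoch, snapshot())

    if best is not None:
        restore(best[2])
        chosen_epoch, valid_metric = best[1], best[0]
    else:
        chosen_epoch = cfg.epochs - 1 if cfg.epochs else -1
        valid_metric = float("nan")
        if cfg.epochs and valid_p:
            warnings.warn("validation metric undefined every epoch; keeping final parameters")
    test_metric, _, _ = _evaluate(model, test_p, cfg.label, cfg.task)
    train_metric, train_y, train_pred = _evaluate(model, train_p, cfg.label, cfg.task)
    if cfg.task == "classification" and train_y:
        train_acc = float(np.mean((np.asarray(train_pred) >= 0.5) == (np.asarray(train_y) >= 0.5)))
    else:
        train_acc = float("nan")

    report = {
        "task": cfg.task,
        "label": cfg.label,
        "metric": "auroc" if higher_better else "mae",
        "chosen_epoch": chosen_epoch,
        "valid_metric": valid_metric,
        "test_metric": test_metric,
        "train_metric": train_metric,
        "train_accuracy": train_acc,
        "history": history,
        "seed": cfg.seed,
        "config": cfg.to_dict(),
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "finetune_report.json").write_text(json.dumps(report, indent=1))
        head = {"w": model.w.data,
                "head1.weight": model.head1.weight.data, "head1.bias": model.head1.bias.data,
                "head2.weight": model.head2.weight.data, "head2.bias": model.head2.bias.data}
        save_checkpoint(out / "finetuned.npz", model.backbone, extra=head)
    report["model"] = model
    return report
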