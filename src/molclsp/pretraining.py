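"""Self-supervised pretraining: perturb -> encode -> fuse -> decode -> loss.

One step draws a batch of molecules, builds a fresh perturbed view of each
(the augmentation seed mixes the global seed, the molecule id and the step
index, so augmentations vary across steps but never depend on batch
order), runs the full backbone, averages the per-molecule loss sums and
takes one Adam step.  Runs are bit-reproducible given (corpus, config).
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .autodiff import Tensor
from .backbone import (
    Backbone,
    BackboneConfig,
    ModalityEmbeddings,
    MolecularGraph,
    graph_from_smiles,
    save_checkpoint,
)
from .chemio import MoleculeRecord
from .errors import InputError
from .espf import SubstructureVocab, TokenizedMolecule, tokenize
from .nn import Adam
from .objectives import (
    LossReport,
    loss_1d_ce,
    loss_2d_sce,
    loss_3d_cos,
    loss_3d_mse,
    total_loss,
)
from .perturb import PerturbRatios, make_views, molecule_seed

__all__ = ["PretrainConfig", "PreparedMolecule", "prepare_molecules",
           "pretrain_step", "run_pretraining", "masked_token_accuracy"]


@dataclass
class PretrainConfig:
    ratios: PerturbRatios = field(default_factory=PerturbRatios)
    sigma: float = 0.1          # coordinate noise scale, Angstrom
    gamma: float = 2.0          # sharpness of the 2D cosine penalty
    lambda_l2: float = 1.0
    lambda_cos: float = 1.0
    backbone: BackboneConfig = field(default_factory=BackboneConfig)
    lr: float = 1e-3
    weight_decay: float = 0.0
    batch_size: int = 16
    steps: int = 200
    seed: int = 0
    checkpoint_every: int = 0   # 0: final checkpoint only

    @classmethod
    def from_dict(cls, d: dict) -> "PretrainConfig":
        d = dict(d)
        if "ratios" in d and not isinstance(d["ratios"], PerturbRatios):
            r = d["ratios"]
            d["ratios"] = PerturbRatios(*r) if isinstance(r, (list, tuple)) else PerturbRatios(**r)
        if "backbone" in d and not isinstance(d["backbone"], BackboneConfig):
            d["backbone"] = BackboneConfig(**d["backbone"])
        return cls(**d)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PreparedMolecule:
    record: MoleculeRecord
    tok: TokenizedMolecule
    graph: MolecularGraph


def prepare_molecules(
    records: list[MoleculeRecord], vocab: SubstructureVocab, max_len: int
) -> list[PreparedMolecule]:
    """Tokenize and featurize once up front; molecules whose token sequence
    exceeds `max_len` are skipped with a warning."""
    out = []
    for rec in records:
        tok = tokenize(rec.smiles, vocab)
        if tok.e > max_len:
            warnings.warn(f"molecule {rec.id!r} has {tok.e} tokens > max_len {max_len}; skipped")
            continue
        out.append(PreparedMolecule(record=rec, tok=tok, graph=graph_from_smiles(rec.smiles)))
    if not out:
        raise InputError("no molecule fits within max_len")
    return out


def _molecule_loss(
    backbone: Backbone,
    vocab: SubstructureVocab,
    prep: PreparedMolecule,
    cfg: PretrainConfig,
    aug_seed: int,
) -> tuple[Tensor, LossReport]:
    use_3d = backbone.cfg.use_3d and prep.record.conformer is not None
    conf = prep.record.conformer if use_3d else None
    plan, views = make_views(
        prep.tok, prep.graph, conf, vocab, cfg.ratios, cfg.sigma, seed=aug_seed
    )
    x1d = backbone.encode_1d(views.tokens_masked)
    x2d = backbone.encode_2d(views.graph_masked)
    x3d = backbone.encode_3d(prep.graph, views.coords_noised) if use_3d else None
    fused = backbone.fuse(ModalityEmbeddings(x1d=x1d, x2d=x2d, x3d=x3d))

    if views.mask_1d:
        ce = loss_1d_ce(backbone.decode_1d(fused.x1d_out), prep.tok.token_ids, views.mask_1d)
    else:
        ce = Tensor(0.0)
    if views.masked_atoms_2d:
        pred2d = backbone.decode_2d(fused.x2d_out, prep.graph)
        target2d = backbone.node_feature_targets(prep.graph)
        sce = loss_2d_sce(pred2d, target2d, views.masked_atoms_2d, cfg.gamma)
    else:
        sce = Tensor(0.0)
    if use_3d:
        pred3d = backbone.decode_3d(fused.x3d_out, prep.graph)
        target3d = prep.record.conformer.coords
        mse = loss_3d_mse(pred3d, target3d)
        cos = loss_3d_cos(pred3d, target3d)
    else:
        mse = cos = None
    counts = {"M1D": len(views.mask_1d), "M2D": len(views.masked_atoms_2d), "n": prep.graph.n}
    return total_loss(ce, sce, mse, cos, cfg.lambda_l2, cfg.lambda_cos, counts, use_3d)


def _mean_report(reports: list[LossReport]) -> LossReport:
    mean = lambda key: float(np.mean([getattr(r, key) for r in reports]))
    return LossReport(
        l_ce_1d=mean("l_ce_1d"),
        l_sce_2d=mean("l_sce_2d"),
        l_mse=mean("l_mse"),
        l_cos=mean("l_cos"),
        l_denoise_3d=mean("l_denoise_3d"),
        total=mean("total"),
        counts={
            "M1D": sum(r.counts["M1D"] for r in reports),
            "M2D": sum(r.counts["M2D"] for r in reports),
            "n": sum(r.counts["n"] for r in reports),
            "use_3d": min(r.counts["use_3d"] for r in reports),
        },
    )


def pretrain_step(
    batch: list[PreparedMolecule],
    backbone: Backbone,
    vocab: SubstructureVocab,
    cfg: PretrainConfig,
    step: int,
    optimizer: Adam | None = None,
) -> LossReport:
    """One optimizer step on the mean per-molecule loss of `batch`."""
    losses, reports = [], []
    for prep in batch:
        aug_seed = molecule_seed(cfg.seed, prep.record.id, step)
        loss, rep = _molecule_loss(backbone, vocab, prep, cfg, aug_seed)
        if not np.isfinite(rep.total):
            raise RuntimeError(f"non-finite loss on molecule {prep.record.id!r}: {rep.to_dict()}")
        losses.append(loss)
        reports.append(rep)
    mean_loss = losses[0]
    for l in losses[1:]:
        mean_loss = mean_loss + l
    mean_loss = mean_loss / float(len(losses))
    if optimizer is not None:
        optimizer.zero_grad()
        mean_loss.backward()
        optimizer.step()
    return _mean_report(reports)


def run_pretraining(
    corpus: list[MoleculeRecord],
    vocab: SubstructureVocab,
    cfg: PretrainConfig,
    out_dir: str | Path | None = None,
    backbone: Backbone | None = None,
) -> tuple[Backbone, list[LossReport]]:
    """Full pretraining run; returns the trained backbone and the per-step
    loss trajectory.  When `out_dir` is given, writes `loss_log.jsonl` and
    `checkpoint.npz` (plus periodic `checkpoint_step*.npz`)."""
    if not corpus:
        raise InputError("empty pretraining corpus")
    if backbone is None:
        backbone = Backbone(cfg.backbone, vocab.n_ids, vocab.fingerprint, seed=cfg.seed)
    prepared = prepare_molecules(corpus, vocab, cfg.backbone.max_len)
    optimizer = Adam(backbone.parameters(), lr=cfg.lr, weight_decay=cfg.weight_decay)
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
    log: list[LossReport] = []
    log_lines = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # empty-mask notices are routine here
        for step in range(cfg.steps):
            lo = (step * cfg.batch_size) % len(prepared)
            batch = [prepared[(lo + i) % len(prepared)] for i in range(min(cfg.batch_size, len(prepared)))]
            rep = pretrain_step(batch, backbone, vocab, cfg, step, optimizer)
            log.append(rep)
            log_lines.append(json.dumps({"step": step, **rep.to_dict()}))
            if out_path is not None and cfg.checkpoint_every and (step + 1) % cfg.checkpoint_every == 0:
                save_checkpoint(out_path / f"checkpoint_step{step + 1}.npz", backbone)
    if out_path is not None:
        (out_path / "loss_log.jsonl").write_text("\n".join(log_lines) + ("\n" if log_lines else ""))
        save_checkpoint(out_path / "checkpoint.npz", backbone)
    return backbone, log


def masked_token_accuracy(
    backbone: Backbone,
    records: list[MoleculeRecord],
    vocab: SubstructureVocab,
    cfg: PretrainConfig,
    eval_seed: int = 0,
) -> float:
    """Top-1 recovery rate of masked substructure tokens under fresh
    perturbations (the 1D self-supervision task, evaluated greedily)."""
    prepared = prepare_molecules(records, vocab, cfg.backbone.max_len)
    hits = trials = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for prep in prepared:
            aug_seed = molecule_seed(eval_seed, prep.record.id, 0)
            use_3d = backbone.cfg.use_3d and prep.record.conformer is not None
            conf = prep.record.conformer if use_3d else None
            plan, views = make_views(
                prep.tok, prep.graph, conf, vocab, cfg.ratios, cfg.sigma, seed=aug_seed
            )
            if not views.mask_1d:
                continue
            x1d = backbone.encode_1d(views.tokens_masked)
            x2d = backbone.encode_2d(views.graph_masked)
            x3d = backbone.encode_3d(prep.graph, views.coords_noised) if use_3d else None
            fused = backbone.fuse(ModalityEmbeddings(x1d=x1d, x2d=x2d, x3d=x3d))
            logits = backbone.decode_1d(fused.x1d_out).data
            for i in sorted(views.mask_1d):
                trials += 1
                hits += int(np.argmax(logits[i]) == prep.tok.token_ids[i])
    return hits / trials if trials else float("nan")
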