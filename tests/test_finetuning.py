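"""Attention pooling, prediction and the fine-tuning loop."""

import dataclasses

import numpy as np
import pytest

from molclsp.autodiff import Tensor
from molclsp.chemio import DatasetSplit, generate_fixture_set
from molclsp.errors import InputError
from molclsp.espf import build_vocab, tokenize
from molclsp.finetuning import (
    FinetuneConfig,
    FinetuneModel,
    attention_pool,
    auroc,
    export_substructure_attention,
    predict,
    run_finetune,
)
from molclsp.pretraining import PretrainConfig, run_pretraining


class TestAttentionPool:
    def test_singleton_row(self):
        rep = attention_pool(np.array([[0.3, -0.7, 2.0]]), np.ones(3))
        np.testing.assert_allclose(rep.alpha.data, [1.0])
        np.testing.assert_allclose(rep.pooled.data, [0.3, -0.7, 2.0])

    def test_identical_rows_give_uniform_weights(self):
        H = np.tile(np.array([[1.0, 2.0]]), (5, 1))
        rep = attention_pool(H, np.array([0.5, -0.2]))
        np.testing.assert_allclose(rep.alpha.data, np.full(5, 0.2), atol=1e-12)

    def test_worked_scalar_example(self):
        rep = attention_pool(np.array([[0.0], [1.0]]), np.array([1.0]))
        s = np.array([0.0, np.tanh(1.0)])
        expected_alpha = np.exp(s) / np.exp(s).sum()
        np.testing.assert_allclose(rep.alpha.data, expected_alpha, atol=1e-9)
        np.testing.assert_allclose(rep.pooled.data, [expected_alpha[1]], atol=1e-9)

    def test_alpha_is_strict_probability_vector_and_pooled_in_hull(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            k = int(rng.integers(1, 9))
            H = rng.normal(size=(k, 4))
            rep = attention_pool(H, rng.normal(size=4))
            a = rep.alpha.data
            assert a.sum() == pytest.approx(1.0, abs=1e-9) and np.all(a > 0)
            lo, hi = H.min(axis=0) - 1e-9, H.max(axis=0) + 1e-9
            assert np.all(rep.pooled.data >= lo) and np.all(rep.pooled.data <= hi)

    def test_empty_input_rejected(self):
        with pytest.raises(InputError):
            attention_pool(np.zeros((0, 3)), np.zeros(3))


def test_auroc_matches_exhaustive_pairwise_count():
    labels = [1.0, 0.0, 1.0, 0.0]
    scores = [0.9, 0.8, 0.3, 0.1]
    # all (pos, neg) pairs: (0.9>0.8), (0.9>0.1), (0.3<0.8), (0.3>0.1) -> 3/4
    assert auroc(labels, scores) == pytest.approx(0.75)
    assert np.isnan(auroc([1.0, 1.0], [0.2, 0.3]))


@pytest.fixture(scope="module")
def finetune_setup(small_cfg):
    records = generate_fixture_set(20, seed=11)
    vocab = build_vocab([r.smiles for r in records], min_frequency=2, max_size=150)
    cfg = PretrainConfig(backbone=small_cfg, seed=1, steps=10)
    backbone, _ = run_pretraining(records, vocab, cfg)
    return records, vocab, backbone


def test_predict_outputs_probability_and_is_deterministic(finetune_setup):
    records, vocab, backbone = finetune_setup
    model = FinetuneModel(backbone, FinetuneConfig(task="classification", use_3d=False))
    for rec in records[:6]:
        p1 = predict(rec, model, vocab)
        p2 = predict(rec, model, vocab)
        assert 0.0 <= p1 <= 1.0 and p1 == p2


def test_predict_requires_conformer_when_3d_enabled(finetune_setup):
    records, vocab, backbone = finetune_setup
    model = FinetuneModel(backbone, FinetuneConfig(use_3d=True))
    rec = dataclasses.replace(records[0], conformer=None)
    with pytest.raises(InputError):
        predict(rec, model, vocab)


def test_attention_export_accounts_for_every_row(finetune_setup):
    records, vocab, backbone = finetune_setup
    rec = records[0]
    tok = tokenize(rec.smiles, vocab)
    n = rec.n_atoms
    for use_3d, k in [(False, tok.e + n), (True, tok.e + 2 * n)]:
        model = FinetuneModel(backbone, FinetuneConfig(use_3d=use_3d))
        rows = export_substructure_attention(rec, model, vocab)
        assert len(rows) == k
        assert sum(r["alpha"] for r in rows) == pytest.approx(1.0, abs=1e-6)
        # exact agreement with attention_pool on the same forward pass
        from molclsp.pretraining import prepare_molecules
        prep = prepare_molecules([rec], vocab, backbone.cfg.max_len)[0]
        _, rep = model.forward(prep)
        np.testing.assert_array_equal([r["alpha"] for r in rows], rep.alpha.data)


def test_zero_epochs_reports_frozen_checkpoint_metric(finetune_setup):
    records, vocab, backbone = finetune_setup
    ids = [r.id for r in records]
    split = DatasetSplit(train=ids[:12], valid=ids[12:16], test=ids[16:])
    cfg = FinetuneConfig(task="classification", label="halogen", epochs=0, seed=0)
    rep = run_finetune(records, split, backbone, vocab, cfg)
    model = rep["model"]
    by_id = {r.id: r for r in records}
    scores = [predict(by_id[i], model, vocab) for i in split.test]
    labels = [by_id[i].labels["halogen"] for i in split.test]
    assert rep["test_metric"] == pytest.approx(auroc(labels, scores), abs=1e-9) or (
        np.isnan(rep["test_metric"]) and np.isnan(auroc(labels, scores))
    )


def test_finetune_regression_reports_mae(finetune_setup):
    records, vocab, backbone = finetune_setup
    ids = [r.id for r in records]
    split = DatasetSplit(train=ids[:14], valid=ids[14:17], test=ids[17:])
    cfg = FinetuneConfig(task="regression", label="mw", epochs=3, seed=0)
    rep = run_finetune(records, split, backbone, vocab, cfg)
    assert rep["metric"] == "mae" and np.isfinite(rep["test_metric"])


def test_finetune_without_3d_never_updates_3d_parameters(finetune_setup):
    records, vocab, backbone_src = finetune_setup
    import copy
    backbone = copy.deepcopy(backbone_src)
    before = {n: p.data.copy() for n, p in backbone.named_parameters()}
    ids = [r.id for r in records]
    split = DatasetSplit(train=ids, valid=[], test=[])
    cfg = FinetuneConfig(task="classification", label="halogen", use_3d=False,
                         epochs=2, seed=3)
    run_finetune(records, split, backbone, vocab, cfg)
    for name, p in backbone.named_parameters():
        if name.startswith("enc3d") or name == "a3d":
            assert np.array_equal(before[name], p.data)


def test_pretrained_start_is_not_slower_than_random_init(finetune_setup):
    """Non-inferiority smoke check: from a pretrained checkpoint the
    separability task is learned at least as fast as from scratch."""
    records, vocab, backbone = finetune_setup
    import copy
    from molclsp.backbone import Backbone
    ids = [r.id for r in records]
    split = DatasetSplit(train=ids, valid=[], test=[])

    def epochs_to_perfect(bb):
        for epochs in (4, 8, 16, 32):
            cfg = FinetuneConfig(task="classification", label="halogen",
                                 epochs=epochs, seed=5)
            rep = run_finetune(records, split, copy.deepcopy(bb), vocab, cfg)
            if rep["train_accuracy"] == 1.0:
                return epochs
        return 64

    random_bb = Backbone(backbone.cfg, vocab.n_ids, vocab.fingerprint, seed=99)
    assert epochs_to_perfect(backbone) <= epochs_to_perfect(random_bb)
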