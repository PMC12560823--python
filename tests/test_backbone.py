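"""Encoder symmetries, fusion algebra and checkpoint round-trips."""

import numpy as np
import pytest

from molclsp.autodiff import Tensor
from molclsp.backbone import (
    Backbone,
    BackboneConfig,
    ModalityEmbeddings,
    MolecularGraph,
    graph_from_smiles,
    load_checkpoint,
    save_checkpoint,
)
from molclsp.chemio import Conformer
from molclsp.errors import ConfigurationError, InputError


def permute_graph(graph: MolecularGraph, perm: np.ndarray) -> MolecularGraph:
    """Relabel atoms: node i of the new graph is node perm[i] of the old."""
    inv = np.argsort(perm)
    edges = inv[graph.edges]
    edges = np.sort(edges, axis=1)
    return MolecularGraph(
        n=graph.n,
        node_features=graph.node_features[perm],
        edges=edges,
        edge_features=graph.edge_features,
    )


def test_encode_1d_shape_and_determinism(small_backbone):
    tokens = [3, 4, 5, 6]
    out1 = small_backbone.encode_1d(tokens)
    out2 = small_backbone.encode_1d(tokens)
    assert out1.shape == (4, small_backbone.cfg.d)
    assert np.array_equal(out1.data, out2.data)


def test_encode_1d_is_position_sensitive(small_backbone):
    a = small_backbone.encode_1d([3, 4, 5]).data
    b = small_backbone.encode_1d([4, 3, 5]).data
    assert not np.allclose(a, b)


def test_encode_1d_respects_max_len(small_backbone):
    with pytest.raises(InputError):
        small_backbone.encode_1d([3] * (small_backbone.cfg.max_len + 1))


def test_encode_2d_permutation_equivariance(small_backbone):
    graph = graph_from_smiles("CCOC(C)=O")
    rng = np.random.default_rng(3)
    out = small_backbone.encode_2d(graph).data
    for _ in range(3):
        perm = rng.permutation(graph.n)
        out_p = small_backbone.encode_2d(permute_graph(graph, perm)).data
        np.testing.assert_allclose(out_p, out[perm], rtol=1e-5, atol=1e-9)


def test_encode_2d_separates_chain_isomers(small_backbone):
    # hexane vs 2-methylpentane: same atom counts, same degree multiset sums differ
    a = small_backbone.encode_2d(graph_from_smiles("CCCCCC")).data
    b = small_backbone.encode_2d(graph_from_smiles("CC(C)CCC")).data
    assert not np.allclose(np.sort(a, axis=0), np.sort(b, axis=0))


def test_encode_3d_rigid_motion_invariance(small_backbone, fixture_records):
    rec = fixture_records[1]
    graph = graph_from_smiles(rec.smiles)
    base = small_backbone.encode_3d(graph, rec.conformer).data
    rng = np.random.default_rng(7)
    # translation
    shifted = Conformer(rec.conformer.coords + np.array([10.0, -3.0, 2.5]))
    np.testing.assert_allclose(
        small_backbone.encode_3d(graph, shifted).data, base, rtol=1e-5, atol=1e-10
    )
    # proper rotation
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    rotated = Conformer(rec.conformer.coords @ q.T)
    np.testing.assert_allclose(
        small_backbone.encode_3d(graph, rotated).data, base, rtol=1e-4, atol=1e-9
    )


def test_encode_3d_cutoff_removes_far_pair_influence(small_cfg, vocab):
    """Pushing one atom beyond the cutoff changes the output only through
    the lost messages: the far atom falls back to its self features."""
    backbone = Backbone(small_cfg, vocab.n_ids, vocab.fingerprint, seed=2)
    graph = graph_from_smiles("CCC")
    near = Conformer(np.array([[0.0, 0, 0], [1.5, 0, 0], [3.0, 0, 0]]))
    far = Conformer(np.array([[0.0, 0, 0], [1.5, 0, 0], [300.0, 0, 0]]))
    out_near = backbone.encode_3d(graph, near).data
    with pytest.warns(UserWarning, match="no neighbor"):
        out_far = backbone.encode_3d(graph, far).data
    assert not np.allclose(out_near[2], out_far[2])
    # atoms 0-1 still interact with each other only -> rows insensitive to
    # atom 2 except via its lost messages
    pair_only = Conformer(np.array([[0.0, 0, 0], [1.5, 0, 0], [600.0, 0, 0]]))
    with pytest.warns(UserWarning, match="no neighbor"):
        out_pair = backbone.encode_3d(graph, pair_only).data
    np.testing.assert_allclose(out_far[:2], out_pair[:2], rtol=1e-9)


def test_fuse_shape_law_and_decomposition(small_backbone):
    d = small_backbone.cfg.d
    rng = np.random.default_rng(0)
    emb = ModalityEmbeddings(
        x1d=Tensor(rng.normal(size=(4, d))),
        x2d=Tensor(rng.normal(size=(6, d))),
        x3d=Tensor(rng.normal(size=(6, d))),
    )
    fe = small_backbone.fuse(emb)
    assert fe.fused.shape == (16, d)
    assert fe.x1d_out.shape == (4, d) and fe.x2d_out.shape == (6, d) and fe.x3d_out.shape == (6, d)
    np.testing.assert_array_equal(fe.fused.data[:4], fe.x1d_out.data)
    np.testing.assert_array_equal(fe.fused.data[4:10], fe.x2d_out.data)
    np.testing.assert_array_equal(fe.fused.data[10:], fe.x3d_out.data)
    # without 3D the row count drops to e + n
    fe2 = small_backbone.fuse(ModalityEmbeddings(x1d=emb.x1d, x2d=emb.x2d, x3d=None))
    assert fe2.fused.shape == (10, d) and fe2.x3d_out is None


def test_fuse_residual_path_closed_form(small_cfg, vocab):
    """With attention output and feed-forward weights zeroed, each pre-norm
    block is the identity, so fusion reduces to adding the modality offsets."""
    backbone = Backbone(small_cfg, vocab.n_ids, vocab.fingerprint, seed=5)
    for blk in backbone.fusion:
        blk.attn.out.weight.data[:] = 0.0
        blk.attn.out.bias.data[:] = 0.0
        blk.ff2.weight.data[:] = 0.0
        blk.ff2.bias.data[:] = 0.0
    d = small_cfg.d
    rng = np.random.default_rng(1)
    emb = ModalityEmbeddings(
        x1d=Tensor(rng.normal(size=(3, d))),
        x2d=Tensor(rng.normal(size=(5, d))),
        x3d=Tensor(rng.normal(size=(5, d))),
    )
    fe = backbone.fuse(emb)
    np.testing.assert_allclose(fe.x1d_out.data, emb.x1d.data + backbone.a1d.data, atol=1e-12)
    np.testing.assert_allclose(fe.x2d_out.data, emb.x2d.data + backbone.a2d.data, atol=1e-12)
    np.testing.assert_allclose(fe.x3d_out.data, emb.x3d.data + backbone.a3d.data, atol=1e-12)


def test_fuse_joint_row_permutation_equivariance(small_backbone):
    """Fusion has no positional table: permuting the 2D rows together with
    their 3D counterparts permutes the corresponding output rows."""
    d = small_backbone.cfg.d
    rng = np.random.default_rng(2)
    x1d = Tensor(rng.normal(size=(3, d)))
    x2d = Tensor(rng.normal(size=(5, d)))
    x3d = Tensor(rng.normal(size=(5, d)))
    perm = rng.permutation(5)
    fe = small_backbone.fuse(ModalityEmbeddings(x1d=x1d, x2d=x2d, x3d=x3d))
    fe_p = small_backbone.fuse(
        ModalityEmbeddings(x1d=x1d, x2d=Tensor(x2d.data[perm]), x3d=Tensor(x3d.data[perm]))
    )
    np.testing.assert_allclose(fe_p.x1d_out.data, fe.x1d_out.data, atol=1e-10)
    np.testing.assert_allclose(fe_p.x2d_out.data, fe.x2d_out.data[perm], atol=1e-10)
    np.testing.assert_allclose(fe_p.x3d_out.data, fe.x3d_out.data[perm], atol=1e-10)


def test_fuse_width_mismatch_raises(small_backbone):
    bad = ModalityEmbeddings(
        x1d=Tensor(np.zeros((2, 7))), x2d=Tensor(np.zeros((3, 7))), x3d=None
    )
    with pytest.raises(ConfigurationError):
        small_backbone.fuse(bad)


def test_decoders_shapes_and_determinism(small_backbone):
    graph = graph_from_smiles("CCO")
    d = small_backbone.cfg.d
    rng = np.random.default_rng(4)
    x1 = Tensor(rng.normal(size=(2, d)))
    x2 = Tensor(rng.normal(size=(3, d)))
    logits = small_backbone.decode_1d(x1)
    assert logits.shape == (2, small_backbone.vocab_size)
    assert np.array_equal(logits.data, small_backbone.decode_1d(x1).data)
    h = small_backbone.decode_2d(x2, graph)
    assert h.shape == (3, d)
    coords = small_backbone.decode_3d(x2, graph)
    assert coords.shape == (3, 3) and np.all(np.isfinite(coords.data))


def test_decode_2d_permutation_equivariance(small_backbone):
    graph = graph_from_smiles("CC(C)O")
    d = small_backbone.cfg.d
    rng = np.random.default_rng(5)
    x = Tensor(rng.normal(size=(graph.n, d)))
    out = small_backbone.decode_2d(x, graph).data
    perm = rng.permutation(graph.n)
    out_p = small_backbone.decode_2d(Tensor(x.data[perm]), permute_graph(graph, perm)).data
    np.testing.assert_allclose(out_p, out[perm], rtol=1e-6, atol=1e-10)


def test_checkpoint_save_load_save_is_byte_identical(tmp_path, small_backbone, vocab):
    p1, p2 = tmp_path / "a.npz", tmp_path / "b.npz"
    save_checkpoint(p1, small_backbone)
    loaded, _ = load_checkpoint(p1, expect_fingerprint=vocab.fingerprint)
    save_checkpoint(p2, loaded)
    assert p1.read_bytes() == p2.read_bytes()
    for (na, a), (nb, b) in zip(small_backbone.named_parameters(), loaded.named_parameters()):
        assert na == nb and np.array_equal(a.data, b.data)


def test_checkpoint_rejects_wrong_vocabulary(tmp_path, small_backbone):
    p = tmp_path / "c.npz"
    save_checkpoint(p, small_backbone)
    with pytest.raises(InputError):
        load_checkpoint(p, expect_fingerprint="deadbeef")


def test_graph_featurization_basics():
    g = graph_from_smiles("CCO")
    assert g.n == 3 and len(g.edges) == 2
    assert g.node_features.shape == (3, 6)
    assert not g.node_features[:, 5].any()
    with pytest.raises(InputError):
        graph_from_smiles("notasmiles")
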