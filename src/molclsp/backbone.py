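"""Modality encoders, fusion block, decomposition and decoder heads.

Three encoders map one molecule's views into a shared d-dimensional space:

* 1D — token + positional embeddings through a pre-norm self-attention
  encoder over the substructure sequence (e rows);
* 2D — GIN message passing with edge-feature injection over the attributed
  molecular graph (n rows, permutation-equivariant);
* 3D — directional message passing over the conformer: messages live on
  directed edges within a distance cutoff, are refined with radial (Gaussian
  distance) and angular (cosine of the k->j->i angle) basis features, and
  are aggregated per atom.  Since only distances and angles enter, the
  encoding is exactly invariant to rigid motions of the coordinates.

A learned length-d modality-identity vector is broadcast-added to each
modality's rows before the rows are concatenated as [1D, 2D, 3D] and passed
through a stack of pre-norm transformer fusion blocks; the fused output is
decomposed back into per-modality slices for the decoder heads.
"""

from __future__ import annotations

import io
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from rdkit import Chem

from .autodiff import Tensor, concat, index_add
from .chemio import Conformer, MoleculeRecord
from .errors import ConfigurationError, InputError
from .nn import (
    MLP,
    Adam,
    Embedding,
    GINLayer,
    LayerNorm,
    Linear,
    Module,
    TransformerBlock,
    gelu,
)

__all__ = [
    "MolecularGraph",
    "ModalityEmbeddings",
    "FusedEmbeddings",
    "BackboneConfig",
    "Backbone",
    "graph_from_smiles",
    "mask_node_row",
    "MASK_FLAG_COLUMN",
    "save_checkpoint",
    "load_checkpoint",
]

# node feature columns: element, degree, formal charge, aromaticity,
# hybridization, mask flag  (categorical codes stored as floats)
_ELEMENTS = ["C", "N", "O", "F", "P", "S", "Cl", "Br", "I", "B"]
_HYBRID = ["S", "SP", "SP2", "SP3", "SP3D", "SP3D2"]
_N_CATS = (len(_ELEMENTS) + 1, 7, 5, 2, len(_HYBRID) + 1)
MASK_FLAG_COLUMN = 5


def mask_node_row() -> np.ndarray:
    """The dedicated mask feature row: all categories cleared, flag set."""
    row = np.zeros(6)
    row[MASK_FLAG_COLUMN] = 1.0
    return row


@dataclass
class MolecularGraph:
    """Attributed heavy-atom graph (undirected edges stored once)."""

    n: int
    node_features: np.ndarray  # (n, 6)
    edges: np.ndarray  # (m, 2) int, i < j
    edge_features: np.ndarray  # (m, 3): bond order, conjugated, in-ring

    def __post_init__(self):
        self.node_features = np.asarray(self.node_features, dtype=np.float64)
        self.edges = np.asarray(self.edges, dtype=np.intp).reshape(-1, 2)
        self.edge_features = np.asarray(self.edge_features, dtype=np.float64).reshape(-1, 3)
        if self.node_features.shape != (self.n, 6):
            raise InputError(f"node features must be ({self.n}, 6)")
        if len(self.edges) and (
            self.edges.min() < 0
            or self.edges.max() >= self.n
            or np.any(self.edges[:, 0] == self.edges[:, 1])
        ):
            raise InputError("edge endpoints out of range or self-loop present")

    def directed(self) -> tuple[np.ndarray, np.ndarray]:
        """Both edge directions plus matching edge-feature rows."""
        if len(self.edges) == 0:
            return np.zeros((0, 2), dtype=np.intp), np.zeros((0, 3))
        both = np.vstack([self.edges, self.edges[:, ::-1]])
        feats = np.vstack([self.edge_features, self.edge_features])
        return both, feats


def graph_from_smiles(smiles: str) -> MolecularGraph:
    """Featurize a SMILES into a :class:`MolecularGraph` (heavy atoms only,
    atom order = RDKit parse order — the package-wide indexing)."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None or mol.GetNumAtoms() == 0:
        raise InputError(f"invalid SMILES: {smiles!r}")
    n = mol.GetNumAtoms()
    feats = np.zeros((n, 6))
    for a in mol.GetAtoms():
        i = a.GetIdx()
        sym = a.GetSymbol()
        feats[i, 0] = _ELEMENTS.index(sym) if sym in _ELEMENTS else len(_ELEMENTS)
        feats[i, 1] = min(a.GetDegree(), 6)
        feats[i, 2] = np.clip(a.GetFormalCharge(), -2, 2) + 2
        feats[i, 3] = float(a.GetIsAromatic())
        hyb = str(a.GetHybridization())
        feats[i, 4] = _HYBRID.index(hyb) if hyb in _HYBRID else len(_HYBRID)
    edges, efeats = [], []
    for b in mol.GetBonds():
        i, j = sorted((b.GetBeginAtomIdx(), b.GetEndAtomIdx()))
        edges.append((i, j))
        efeats.append((b.GetBondTypeAsDouble(), float(b.GetIsConjugated()), float(b.IsInRing())))
    return MolecularGraph(
        n=n,
        node_features=feats,
        edges=np.asarray(edges, dtype=np.intp).reshape(-1, 2),
        edge_features=np.asarray(efeats).reshape(-1, 3),
    )


@dataclass
class ModalityEmbeddings:
    x1d: Tensor  # (e, d)
    x2d: Tensor  # (n, d)
    x3d: Tensor | None  # (n, d) or None when the 3D branch is off


@dataclass
class FusedEmbeddings:
    fused: Tensor  # (e + n [+ n], d), rows ordered [1D, 2D, 3D]
    x1d_out: Tensor
    x2d_out: Tensor
    x3d_out: Tensor | None


@dataclass
class BackboneConfig:
    """Desk-scale architecture sizes (all widths/depths configurable)."""

    d: int = 128           # shared fusion width
    z: int = 128           # token-embedding width
    n_layers_1d: int = 2
    n_heads_1d: int = 4
    n_layers_2d: int = 3
    n_blocks_3d: int = 2
    n_rbf: int = 8         # radial (distance) basis size
    n_abf: int = 4         # angular basis size
    cutoff: float = 5.0    # neighbor cutoff, Angstrom
    fusion_blocks: int = 2
    fusion_heads: int = 4
    max_len: int = 128
    use_3d: bool = True

    def validate(self) -> None:
        for name in ("d", "z", "n_layers_1d", "n_heads_1d", "n_layers_2d",
                     "n_blocks_3d", "n_rbf", "n_abf", "fusion_blocks",
                     "fusion_heads", "max_len"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.cutoff <= 0:
            raise ConfigurationError("cutoff must be positive")


class NodeEmbedder(Module):
    """Sum of per-column categorical embeddings; masked atoms get a single
    dedicated learned row instead (never a zero collision with real atoms)."""

    def __init__(self, d: int, rng: np.random.Generator):
        self.tables = [Embedding(c, d, rng) for c in _N_CATS]
        self.mask_row = Tensor(rng.normal(0, 0.02, size=d), requires_grad=True)

    def __call__(self, graph: MolecularGraph) -> Tensor:
        codes = graph.node_features[:, :5].astype(np.intp)
        h = self.tables[0](codes[:, 0])
        for c in range(1, 5):
            h = h + self.tables[c](codes[:, c])
        flag = graph.node_features[:, MASK_FLAG_COLUMN : MASK_FLAG_COLUMN + 1]
        if flag.any():
            h = Tensor(1.0 - flag) * h + Tensor(flag) * self.mask_row.reshape(1, -1)
        return h


class Encoder1D(Module):
    """Token + positional embedding -> pre-norm transformer over e tokens."""

    def __init__(self, cfg: BackboneConfig, vocab_size: int, rng: np.random.Generator):
        self.tok_emb = Embedding(vocab_size, cfg.z, rng)
        self.pos_emb = Embedding(cfg.max_len, cfg.z, rng)
        self.proj = Linear(cfg.z, cfg.d, rng) if cfg.z != cfg.d else None
        self.blocks = [TransformerBlock(cfg.d, cfg.n_heads_1d, rng) for _ in range(cfg.n_layers_1d)]
        self.max_len = cfg.max_len

    def __call__(self, token_ids: list[int]) -> Tensor:
        e = len(token_ids)
        if e > self.max_len:
            raise InputError(f"sequence length {e} exceeds max_len {self.max_len}")
        x = self.tok_emb(token_ids) + self.pos_emb(np.arange(e))
        if self.proj is not None:
            x = self.proj(x)
        for blk in self.blocks:
            x = blk(x)
        return x


class Encoder2D(Module):
    """GIN over the (possibly feature-masked) molecular graph."""

    def __init__(self, cfg: BackboneConfig, rng: np.random.Generator):
        self.embed = NodeEmbedder(cfg.d, rng)
        self.layers = [GINLayer(cfg.d, 3, rng) for _ in range(cfg.n_layers_2d)]

    def __call__(self, graph: MolecularGraph) -> Tensor:
        h = self.embed(graph)
        edge_index, edge_feats = graph.directed()
        ef = Tensor(edge_feats)
        for layer in self.layers:
            h = layer(h, edge_index, ef)
        return h


def _geometry(coords: np.ndarray, cutoff: float, n_rbf: int, n_abf: int):
    """Neighbor list, radial basis and angular basis (plain NumPy constants:
    gradients never flow into coordinates)."""
    n = coords.shape[0]
    diff = coords[None, :, :] - coords[:, None, :]
    dist = np.sqrt((diff**2).sum(-1))
    src, dst = np.where((dist <= cutoff) & ~np.eye(n, dtype=bool))  # edge: src -> dst
    m = len(src)
    centers = np.linspace(0.0, cutoff, n_rbf)
    gamma = (n_rbf / cutoff) ** 2
    rbf = np.exp(-gamma * (dist[src, dst][:, None] - centers[None, :]) ** 2)
    # triplets: for edge a=(j->i), every edge b=(k->j) with k != i
    edge_id = {}
    in_edges: list[list[int]] = [[] for _ in range(n)]
    for idx in range(m):
        edge_id[(src[idx], dst[idx])] = idx
        in_edges[dst[idx]].append(idx)
    tri_src_edge, tri_dst_edge, cos_angle = [], [], []
    for a in range(m):
        j, i = src[a], dst[a]
        v_ji = coords[i] - coords[j]
        for b in in_edges[j]:
            k = src[b]
            if k == i:
                continue
            v_jk = coords[k] - coords[j]
            c = float(v_ji @ v_jk / (np.linalg.norm(v_ji) * np.linalg.norm(v_jk) + 1e-12))
            tri_src_edge.append(b)
            tri_dst_edge.append(a)
            cos_angle.append(np.clip(c, -1.0, 1.0))
    theta = np.arccos(np.asarray(cos_angle)) if cos_angle else np.zeros(0)
    abf = np.cos(theta[:, None] * np.arange(n_abf)[None, :]) if len(theta) else np.zeros((0, n_abf))
    return (
        np.stack([src, dst], axis=1) if m else np.zeros((0, 2), dtype=np.intp),
        rbf,
        np.asarray(tri_src_edge, dtype=np.intp),
        np.asarray(tri_dst_edge, dtype=np.intp),
        abf,
    )


class Encoder3D(Module):
    """Directional message passing over distances and angles.

    Edge messages are initialized from the two endpoint atom embeddings and
    the radial basis of the edge length; each interaction block refines a
    message m_ji with the angular-basis-weighted sum of its incoming
    messages m_kj (k != i); atoms aggregate their incoming messages.  Atoms
    with no neighbor inside the cutoff fall back to their own embedding.
    """

    def __init__(self, cfg: BackboneConfig, rng: np.random.Generator):
        d = cfg.d
        self.embed = NodeEmbedder(d, rng)
        self.edge_init = MLP([2 * d + cfg.n_rbf, d, d], rng)
        self.blocks = [
            MLP([d + cfg.n_rbf + cfg.n_abf, d, d], rng) for _ in range(cfg.n_blocks_3d)
        ]
        self.block_self = [Linear(d, d, rng) for _ in range(cfg.n_blocks_3d)]
        self.out_self = Linear(d, d, rng)
        self.out = MLP([d, d, d], rng)
        self.cfg = cfg

    def __call__(self, graph: MolecularGraph, conf: Conformer) -> Tensor:
        if conf.n != graph.n:
            raise InputError(f"conformer n={conf.n} does not match graph n={graph.n}")
        cfg = self.cfg
        edges, rbf, tri_src, tri_dst, abf = _geometry(
            conf.coords, cfg.cutoff, cfg.n_rbf, cfg.n_abf
        )
        h = self.embed(graph)
        n = graph.n
        if len(edges) == 0:
            warnings.warn("no atom pair within the 3D cutoff; using self features only")
            return self.out(self.out_self(h))
        isolated = np.setdiff1d(np.arange(n), edges[:, 1])
        if len(isolated):
            warnings.warn(f"{len(isolated)} atom(s) with no neighbor within cutoff; self fallback")
        src, dst = edges[:, 0], edges[:, 1]
        rbf_t = Tensor(rbf)
        msg = self.edge_init(concat([h[src], h[dst], rbf_t], axis=1))
        for blk, self_lin in zip(self.blocks, self.block_self):
            if len(tri_src):
                tri_in = concat([msg[tri_src], rbf_t[tri_src], Tensor(abf)], axis=1)
                agg = index_add(len(edges), tri_dst, blk(tri_in))
                msg = (self_lin(msg) + agg).relu() + msg
            else:
                msg = self_lin(msg).relu() + msg
        node_agg = index_add(n, dst, msg)
        return self.out(self.out_self(h) + node_agg)


class Decoder1D(Module):
    """Masked-token head: dense -> GELU -> layer norm -> vocabulary logits."""

    def __init__(self, cfg: BackboneConfig, vocab_size: int, rng: np.random.Generator):
        self.dense = Linear(cfg.d, cfg.d, rng)
        self.norm = LayerNorm(cfg.d)
        self.proj = Linear(cfg.d, vocab_size, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.proj(self.norm(gelu(self.dense(x))))


class GraphDecoder(Module):
    """Light message-passing head: one GIN layer + linear readout."""

    def __init__(self, cfg: BackboneConfig, d_out: int, rng: np.random.Generator):
        self.gin = GINLayer(cfg.d, 3, rng)
        self.readout = Linear(cfg.d, d_out, rng)

    def __call__(self, x: Tensor, graph: MolecularGraph) -> Tensor:
        edge_index, edge_feats = graph.directed()
        return self.readout(self.gin(x, edge_index, Tensor(edge_feats)))


class Backbone(Module):
    """All trainable components of the pretraining architecture."""

    def __init__(self, cfg: BackboneConfig, vocab_size: int, vocab_fingerprint: str, seed: int):
        cfg.validate()
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        self.vocab_size = vocab_size
        self.vocab_fingerprint = vocab_fingerprint
        self.enc1d = Encoder1D(cfg, vocab_size, rng)
        self.enc2d = Encoder2D(cfg, rng)
        self.enc3d = Encoder3D(cfg, rng) if cfg.use_3d else None
        self.a1d = Tensor(rng.normal(0, 0.02, size=cfg.d), requires_grad=True)
        self.a2d = Tensor(rng.normal(0, 0.02, size=cfg.d), requires_grad=True)
        self.a3d = Tensor(rng.normal(0, 0.02, size=cfg.d), requires_grad=True)
        self.fusion = [
            TransformerBlock(cfg.d, cfg.fusion_heads, rng) for _ in range(cfg.fusion_blocks)
        ]
        self.dec1d = Decoder1D(cfg, vocab_size, rng)
        self.dec2d = GraphDecoder(cfg, cfg.d, rng)
        self.dec3d = GraphDecoder(cfg, 3, rng)

    # -- encoders -----------------------------------------------------------
    def encode_1d(self, token_ids: list[int]) -> Tensor:
        return self.enc1d(token_ids)

    def encode_2d(self, graph: MolecularGraph) -> Tensor:
        return self.enc2d(graph)

    def encode_3d(self, graph: MolecularGraph, conf: Conformer) -> Tensor:
        if self.enc3d is None:
            raise ConfigurationError("3D branch is disabled in this configuration")
        return self.enc3d(graph, conf)

    # -- fusion -------------------------------------------------------------
    def fuse(self, emb: ModalityEmbeddings) -> FusedEmbeddings:
        d = self.cfg.d
        for x in (emb.x1d, emb.x2d) + ((emb.x3d,) if emb.x3d is not None else ()):
            if x.shape[1] != d:
                raise ConfigurationError(f"modality width {x.shape[1]} != fusion width {d}")
        parts = [emb.x1d + self.a1d, emb.x2d + self.a2d]
        if emb.x3d is not None:
            parts.append(emb.x3d + self.a3d)
        fused = concat(parts, axis=0)
        for blk in self.fusion:
            fused = blk(fused)
        e = emb.x1d.shape[0]
        n = emb.x2d.shape[0]
        x1d_out = fused[0:e]
        x2d_out = fused[e : e + n]
        x3d_out = fused[e + n : e + 2 * n] if emb.x3d is not None else None
        return FusedEmbeddings(fused=fused, x1d_out=x1d_out, x2d_out=x2d_out, x3d_out=x3d_out)

    # -- decoders -----------------------------------------------------------
    def decode_1d(self, x1d_out: Tensor) -> Tensor:
        return self.dec1d(x1d_out)

    def decode_2d(self, x2d_out: Tensor, graph: MolecularGraph) -> Tensor:
        return self.dec2d(x2d_out, graph)

    def decode_3d(self, x3d_out: Tensor, graph: MolecularGraph) -> Tensor:
        return self.dec3d(x3d_out, graph)

    def node_feature_targets(self, graph: MolecularGraph) -> Tensor:
        """Input-layer embedding of the CLEAN graph — the gradient-stopped
        target the 2D reconstruction loss compares against."""
        clean = MolecularGraph(
            n=graph.n,
            node_features=graph.node_features.copy(),
            edges=graph.edges,
            edge_features=graph.edge_features,
        )
        clean.node_features[:, MASK_FLAG_COLUMN] = 0.0
        return self.enc2d.embed(clean).detach()


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(path: str | Path, backbone: Backbone, extra: dict | None = None) -> None:
    """Single-archive checkpoint: config snapshot, vocabulary fingerprint and
    all named parameter tensors (float64, bit-exact on reload)."""
    arrays = {f"param:{name}": p.data for name, p in backbone.named_parameters()}
    if extra:
        arrays.update({f"extra:{k}": v for k, v in extra.items()})
    meta = {
        "config": asdict(backbone.cfg),
        "vocab_size": backbone.vocab_size,
        "vocab_fingerprint": backbone.vocab_fingerprint,
    }
    buf = io.BytesIO()
    np.savez(buf, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)
    Path(path).write_bytes(buf.getvalue())


def load_checkpoint(
    path: str | Path, expect_fingerprint: str | None = None, seed: int = 0
) -> tuple[Backbone, dict[str, np.ndarray]]:
    """Rebuild a :class:`Backbone` from a checkpoint; verifies the vocabulary
    fingerprint when one is expected.  Returns (backbone, extra_arrays)."""
    with np.load(Path(path), allow_pickle=False) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        if expect_fingerprint is not None and meta["vocab_fingerprint"] != expect_fingerprint:
            raise InputError(
                "checkpoint was trained with a different substructure vocabulary "
                f"({meta['vocab_fingerprint']} != {expect_fingerprint})"
            )
        cfg = BackboneConfig(**meta["config"])
        backbone = Backbone(cfg, meta["vocab_size"], meta["vocab_fingerprint"], seed=seed)
        params = dict(backbone.named_parameters())
        extra = {}
        for key in data.files:
            if key.startswith("param:"):
                name = key[len("param:"):]
                if name not in params:
                    raise InputError(f"checkpoint parameter {name!r} not in this architecture")
                if params[name].data.shape != data[key].shape:
                    raise InputError(f"shape mismatch for {name!r}")
                params[name].data = data[key].astype(np.float64)
            elif key.startswith("extra:"):
                extra[key[len("extra:"):]] = data[key]
    return backbone, extra
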