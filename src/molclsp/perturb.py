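"""Non-overlapping substructure selection and modality-specific perturbations.

For each molecule, substructures are selected for perturbation in the order
1D -> 2D -> 3D, each later draw excluding everything already selected, so
the three perturbed sets are pairwise disjoint by construction: the three
contrastive views of one molecule lose *different* pieces of information.
Per modality the target count is floor(ratio * e), truncated by how many
substructures remain available.

The perturbations themselves:
  1D  — replace the selected substructures' token ids with the mask id;
  2D  — replace the node-feature rows of the selected substructures' atoms
        with the dedicated mask feature row;
  3D  — add i.i.d. Gaussian coordinate noise N(0, sigma^2) per axis to the
        selected substructures' atoms.
Everything outside the selected sets is bit-identical to the clean view.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

from .backbone import MASK_FLAG_COLUMN, MolecularGraph, mask_node_row
from .chemio import Conformer
from .errors import ConfigurationError, InputError
from .espf import SubstructureVocab, TokenizedMolecule, atoms_of_substructures

__all__ = [
    "PerturbRatios",
    "PerturbationPlan",
    "PerturbedViews",
    "molecule_seed",
    "plan_perturbation",
    "apply_1d",
    "apply_2d",
    "apply_3d",
    "make_views",
]


@dataclass(frozen=True)
class PerturbRatios:
    """Fraction of substructures to perturb in each modality."""

    r1d: float = 0.15
    r2d: float = 0.15
    r3d: float = 0.15

    def __post_init__(self):
        for name, r in (("r1d", self.r1d), ("r2d", self.r2d), ("r3d", self.r3d)):
            if not 0.0 <= r <= 1.0:
                raise ConfigurationError(f"{name}={r} outside [0, 1]")


@dataclass(frozen=True)
class PerturbationPlan:
    sel_1d: frozenset[int]
    sel_2d: frozenset[int]
    sel_3d: frozenset[int]
    seed: int

    def validate(self, e: int) -> None:
        all_sel = [self.sel_1d, self.sel_2d, self.sel_3d]
        for a in range(3):
            for b in range(a + 1, 3):
                if all_sel[a] & all_sel[b]:
                    raise InputError("perturbation selections overlap across modalities")
        for s in all_sel:
            if any(not (0 <= i < e) for i in s):
                raise InputError(f"selection index out of range [0,{e})")


@dataclass
class PerturbedViews:
    """The three perturbed views (T', G', C') of one molecule plus mask sets."""

    tokens_masked: list[int]
    mask_1d: frozenset[int]
    graph_masked: MolecularGraph
    masked_atoms_2d: frozenset[int]
    coords_noised: Conformer | None
    noised_atoms_3d: frozenset[int]


def molecule_seed(global_seed: int, molecule_id: str, step: int = 0) -> int:
    """Stable per-molecule (and per-step) PRNG seed, independent of batch
    order: derived from the global seed and the molecule id by CRC mixing."""
    h = zlib.crc32(f"{molecule_id}|{step}".encode())
    return int((np.uint64(global_seed) * np.uint64(0x9E3779B1) + np.uint64(h)) % np.uint64(2**31))


def plan_perturbation(
    tok: TokenizedMolecule, ratios: PerturbRatios, seed: int
) -> PerturbationPlan:
    """Select disjoint substructure sets for the three modalities.

    Counts are floor(r_m * e) truncated to the size of the remaining pool;
    selection is uniform without replacement, in the order 1D, 2D, 3D, and
    fully determined by `seed`.
    """
    e = tok.e
    if e < 1:
        raise InputError("cannot plan a perturbation for an empty tokenization")
    rng = np.random.default_rng(seed)
    available = list(range(e))
    picks: list[frozenset[int]] = []
    for r in (ratios.r1d, ratios.r2d, ratios.r3d):
        k = min(int(np.floor(r * e)), len(available))
        if k > 0:
            chosen = rng.choice(len(available), size=k, replace=False)
            chosen_vals = frozenset(available[i] for i in chosen)
            available = [a for a in available if a not in chosen_vals]
        else:
            chosen_vals = frozenset()
        picks.append(chosen_vals)
    plan = PerturbationPlan(sel_1d=picks[0], sel_2d=picks[1], sel_3d=picks[2], seed=seed)
    plan.validate(e)
    return plan


def apply_1d(
    tok: TokenizedMolecule, plan: PerturbationPlan, vocab: SubstructureVocab
) -> tuple[list[int], frozenset[int]]:
    """Mask the selected substructures' token ids -> (T', M1D)."""
    plan.validate(tok.e)
    masked = [vocab.mask_id if i in plan.sel_1d else t for i, t in enumerate(tok.token_ids)]
    return masked, plan.sel_1d


def apply_2d(
    graph: MolecularGraph, tok: TokenizedMolecule, plan: PerturbationPlan
) -> tuple[MolecularGraph, frozenset[int]]:
    """Mask the node-feature rows of the selected substructures' atoms -> G'.

    Topology, edge features and all unselected node rows are untouched.
    """
    if graph.n != tok.n_atoms:
        raise InputError(f"graph has {graph.n} atoms but tokenization has {tok.n_atoms}")
    plan.validate(tok.e)
    atoms = frozenset(atoms_of_substructures(tok, set(plan.sel_2d)))
    feats = graph.node_features.copy()
    for a in atoms:
        feats[a] = mask_node_row()
    masked = MolecularGraph(
        n=graph.n,
        node_features=feats,
        edges=graph.edges.copy(),
        edge_features=graph.edge_features.copy(),
    )
    return masked, atoms


def apply_3d(
    conf: Conformer,
    tok: TokenizedMolecule,
    plan: PerturbationPlan,
    sigma: float,
    seed: int,
) -> tuple[Conformer, frozenset[int]]:
    """Add Gaussian N(0, sigma^2) coordinate noise to the selected
    substructures' atoms -> C'.  Unselected atoms are bit-identical."""
    if sigma < 0:
        raise ConfigurationError(f"sigma must be nonnegative, got {sigma}")
    if conf.n != tok.n_atoms:
        raise InputError(f"conformer has {conf.n} atoms but tokenization has {tok.n_atoms}")
    plan.validate(tok.e)
    atoms = sorted(atoms_of_substructures(tok, set(plan.sel_3d)))
    coords = conf.coords.copy()
    if atoms and sigma > 0:
        rng = np.random.default_rng(seed)
        coords[atoms] += rng.normal(0.0, sigma, size=(len(atoms), 3))
    return Conformer(coords=coords), frozenset(atoms)


def make_views(
    tok: TokenizedMolecule,
    graph: MolecularGraph,
    conf: Conformer | None,
    vocab: SubstructureVocab,
    ratios: PerturbRatios,
    sigma: float,
    seed: int,
) -> tuple[PerturbationPlan, PerturbedViews]:
    """One-stop construction of the perturbed triple (T', G', C')."""
    plan = plan_perturbation(tok, ratios, seed)
    tokens_masked, m1d = apply_1d(tok, plan, vocab)
    graph_masked, m2d = apply_2d(graph, tok, plan)
    if conf is not None:
        coords_noised, m3d = apply_3d(conf, tok, plan, sigma, seed=seed + 1)
    else:
        coords_noised, m3d = None, frozenset()
    views = PerturbedViews(
        tokens_masked=tokens_masked,
        mask_1d=m1d,
        graph_masked=graph_masked,
        masked_atoms_2d=m2d,
        coords_noised=coords_noised,
        noised_atoms_3d=m3d,
    )
    return plan, views
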