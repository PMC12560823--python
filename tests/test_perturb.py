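"""Non-overlapping selection and modality-specific perturbation locality."""

import numpy as np
import pytest

from molclsp.backbone import MASK_FLAG_COLUMN, graph_from_smiles, mask_node_row
from molclsp.chemio import Conformer
from molclsp.errors import ConfigurationError
from molclsp.espf import TokenizedMolecule, atoms_of_substructures, tokenize
from molclsp.perturb import (
    PerturbRatios,
    apply_1d,
    apply_2d,
    apply_3d,
    make_views,
    molecule_seed,
    plan_perturbation,
)


def synthetic_tok(e: int) -> TokenizedMolecule:
    """e singleton substructures over e atoms (selection-logic scaffold)."""
    return TokenizedMolecule(
        fragments=["C"] * e,
        token_ids=list(range(3, 3 + e)),
        atom_sets=[frozenset({i}) for i in range(e)],
        n_atoms=e,
    )


def test_zero_ratios_select_nothing():
    plan = plan_perturbation(synthetic_tok(6), PerturbRatios(0, 0, 0), seed=0)
    assert plan.sel_1d == plan.sel_2d == plan.sel_3d == frozenset()


def test_thirds_on_three_substructures_partition_everything():
    plan = plan_perturbation(synthetic_tok(3), PerturbRatios(1 / 3, 1 / 3, 1 / 3), seed=5)
    sets = [plan.sel_1d, plan.sel_2d, plan.sel_3d]
    assert all(len(s) == 1 for s in sets)
    assert plan.sel_1d | plan.sel_2d | plan.sel_3d == {0, 1, 2}


@pytest.mark.parametrize("e,r", [(5, (0.4, 0.4, 0.4)), (8, (0.25, 0.5, 0.5)), (3, (1.0, 1.0, 1.0))])
def test_count_law_floor_then_availability(e, r):
    plan = plan_perturbation(synthetic_tok(e), PerturbRatios(*r), seed=3)
    remaining = e
    for rm, sel in zip(r, (plan.sel_1d, plan.sel_2d, plan.sel_3d)):
        expect = min(int(np.floor(rm * e)), remaining)
        assert len(sel) == expect
        remaining -= expect


def test_non_overlap_over_many_random_cases():
    rng = np.random.default_rng(0)
    for case in range(1000):
        e = int(rng.integers(1, 12))
        ratios = PerturbRatios(*rng.uniform(0, 1, size=3))
        plan = plan_perturbation(synthetic_tok(e), ratios, seed=int(rng.integers(2**31)))
        assert not (plan.sel_1d & plan.sel_2d)
        assert not (plan.sel_1d & plan.sel_3d)
        assert not (plan.sel_2d & plan.sel_3d)


def test_plan_is_deterministic_given_seed():
    tok = synthetic_tok(9)
    ratios = PerturbRatios(0.3, 0.3, 0.3)
    assert plan_perturbation(tok, ratios, 77) == plan_perturbation(tok, ratios, 77)


def test_apply_1d_masks_exactly_the_selected_positions(vocab, fixture_records):
    tok = tokenize(fixture_records[1].smiles, vocab)
    plan = plan_perturbation(tok, PerturbRatios(0.5, 0.2, 0.2), seed=2)
    masked, m1d = apply_1d(tok, plan, vocab)
    assert m1d == plan.sel_1d
    for i in range(tok.e):
        if i in plan.sel_1d:
            assert masked[i] == vocab.mask_id
        else:
            assert masked[i] == tok.token_ids[i]


def test_apply_2d_touches_only_selected_atom_rows(vocab):
    smi = "CCOCC"
    tok = tokenize(smi, vocab)
    graph = graph_from_smiles(smi)
    plan = plan_perturbation(tok, PerturbRatios(0.0, 0.5, 0.0), seed=4)
    masked, atoms = apply_2d(graph, tok, plan)
    assert atoms == frozenset(atoms_of_substructures(tok, set(plan.sel_2d)))
    assert np.array_equal(masked.edges, graph.edges)
    assert np.array_equal(masked.edge_features, graph.edge_features)
    for a in range(graph.n):
        if a in atoms:
            assert np.array_equal(masked.node_features[a], mask_node_row())
        else:
            assert np.array_equal(masked.node_features[a], graph.node_features[a])
    assert not graph.node_features[:, MASK_FLAG_COLUMN].any()  # clean graph untouched


def test_apply_3d_noise_locality_and_degenerate_cases(vocab, fixture_records):
    rec = fixture_records[1]
    tok = tokenize(rec.smiles, vocab)
    plan = plan_perturbation(tok, PerturbRatios(0.0, 0.0, 0.6), seed=6)
    noised, atoms = apply_3d(rec.conformer, tok, plan, sigma=0.1, seed=8)
    untouched = sorted(set(range(rec.n_atoms)) - atoms)
    assert np.array_equal(noised.coords[untouched], rec.conformer.coords[untouched])
    if atoms:
        assert not np.array_equal(noised.coords[sorted(atoms)],
                                  rec.conformer.coords[sorted(atoms)])
    # sigma = 0 and empty selection are exact identities
    same, _ = apply_3d(rec.conformer, tok, plan, sigma=0.0, seed=8)
    assert np.array_equal(same.coords, rec.conformer.coords)
    empty_plan = plan_perturbation(tok, PerturbRatios(0, 0, 0), seed=1)
    same2, sel = apply_3d(rec.conformer, tok, empty_plan, sigma=0.5, seed=8)
    assert sel == frozenset() and np.array_equal(same2.coords, rec.conformer.coords)
    with pytest.raises(ConfigurationError):
        apply_3d(rec.conformer, tok, plan, sigma=-0.1, seed=8)


def test_make_views_fully_deterministic(vocab, fixture_records):
    rec = fixture_records[2]
    tok = tokenize(rec.smiles, vocab)
    graph = graph_from_smiles(rec.smiles)
    args = (tok, graph, rec.conformer, vocab, PerturbRatios(0.4, 0.3, 0.3), 0.1)
    p1, v1 = make_views(*args, seed=123)
    p2, v2 = make_views(*args, seed=123)
    assert p1 == p2
    assert v1.tokens_masked == v2.tokens_masked
    assert np.array_equal(v1.graph_masked.node_features, v2.graph_masked.node_features)
    assert np.array_equal(v1.coords_noised.coords, v2.coords_noised.coords)


def test_molecule_seed_is_stable_and_batch_order_free():
    s = molecule_seed(42, "mol0001", step=3)
    assert s == molecule_seed(42, "mol0001", step=3)
    assert s != molecule_seed(42, "mol0002", step=3)
    assert s != molecule_seed(42, "mol0001", step=4)
    assert 0 <= s < 2**31


def test_gaussian_noise_moments():
    """Sampled displacement of one noised atom matches N(0, sigma^2)."""
    tok = synthetic_tok(1)
    conf = Conformer(np.zeros((1, 3)))
    plan = plan_perturbation(tok, PerturbRatios(0, 0, 1.0), seed=0)
    sigma = 0.1
    deltas = np.array([
        apply_3d(conf, tok, plan, sigma, seed=s)[0].coords[0] for s in range(10_000)
    ])
    assert abs(deltas.mean()) < 3 * sigma / np.sqrt(30_000)
    assert abs(deltas.var() - sigma**2) < 0.05 * sigma**2
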