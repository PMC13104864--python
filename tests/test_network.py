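"""Equivariance and architecture contracts of the GVP denoiser."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from molfm import ad
from molfm.flows import DenoiserOutput
from molfm.molgraph import InterpolantState, MoleculeGraph
from molfm.network import (Denoiser, GVP, GraphBatch, NetworkConfig,
                           load_checkpoint, save_checkpoint)


def _random_state(vocab, rng, n=6, t=0.5, masked=False):
    coords = rng.standard_normal((n, 3))
    coords -= coords.mean(axis=0)
    if masked:
        atoms = np.full(n, vocab.atom_mask_index)
        charges = np.full(n, vocab.charge_mask_index)
        bonds = np.full(n * (n - 1) // 2, vocab.bond_mask_index)
    else:
        atoms = rng.integers(0, 5, n)
        charges = rng.integers(0, 6, n)
        bonds = rng.integers(0, 4, n * (n - 1) // 2)
    return InterpolantState(MoleculeGraph(coords, atoms, charges, bonds), t)


def _rotate_state(state, R):
    g = state.graph.copy()
    g.coords = g.coords @ R.T
    return InterpolantState(g, state.time)


# -- GVP primitive -----------------------------------------------------------

def test_gvp_rotation_equivariance(rng):
    gvp = GVP(5, 4, 6, 3, np.random.default_rng(0))
    s = rng.standard_normal((7, 5))
    V = rng.standard_normal((7, 4, 3))
    R = Rotation.random(random_state=1).as_matrix()
    s1, v1 = gvp(ad.Tensor(s), ad.Tensor(V))
    s2, v2 = gvp(ad.Tensor(s), ad.Tensor(V @ R.T))
    np.testing.assert_allclose(s2.data, s1.data, atol=1e-5)
    np.testing.assert_allclose(v2.data, v1.data @ R.T, atol=1e-5)


def test_gvp_zero_vectors_give_zero_vector_output(rng):
    gvp = GVP(5, 4, 6, 3, np.random.default_rng(0))
    _, v = gvp(ad.Tensor(rng.standard_normal((7, 5))),
               ad.Tensor(np.zeros((7, 4, 3))))
    np.testing.assert_allclose(v.data, 0.0, atol=1e-12)


def test_gvp_reflection_sensitivity(rng):
    # mirroring a generic chiral vector input changes scalar outputs
    gvp = GVP(2, 4, 6, 3, np.random.default_rng(0))
    s = rng.standard_normal((5, 2))
    V = rng.standard_normal((5, 4, 3))
    P = np.diag([1.0, 1.0, -1.0])  # improper rotation
    s1, _ = gvp(ad.Tensor(s), ad.Tensor(V))
    s2, _ = gvp(ad.Tensor(s), ad.Tensor(V @ P.T))
    assert np.abs(s1.data - s2.data).max() > 1e-4


# -- end-to-end contracts ----------------------------------------------------

def test_forward_rotation_equivariance(tiny_model, vocab, rng):
    state = _random_state(vocab, rng)
    R = Rotation.random(random_state=3).as_matrix()
    out = tiny_model.forward(state)
    out_rot = tiny_model.forward(_rotate_state(state, R))
    np.testing.assert_allclose(out_rot.pred_coords, out.pred_coords @ R.T,
                               atol=1e-4)
    np.testing.assert_allclose(out_rot.atom_logits, out.atom_logits, atol=1e-4)
    np.testing.assert_allclose(out_rot.bond_logits, out.bond_logits, atol=1e-4)


def test_forward_translation_covariance(tiny_model, vocab, rng):
    # features depend only on relative geometry: outputs translate exactly
    state = _random_state(vocab, rng)
    tau = np.array([2.0, -1.0, 0.5])
    shifted = InterpolantState(
        MoleculeGraph(state.graph.coords + tau, state.graph.atom_types,
                      state.graph.charges, state.graph.bond_orders), state.time)
    out = tiny_model.forward(state)
    out_shift = tiny_model.forward(shifted)
    np.testing.assert_allclose(out_shift.pred_coords, out.pred_coords + tau,
                               atol=1e-9)
    np.testing.assert_allclose(out_shift.atom_logits, out.atom_logits, atol=1e-9)


def test_forward_permutation_equivariance(tiny_model, vocab, rng):
    state = _random_state(vocab, rng, n=6)
    perm = rng.permutation(6)
    g = state.graph
    dense = g.bond_matrix()[np.ix_(perm, perm)]
    from molfm.molgraph import pair_indices
    iu, ju = pair_indices(6)
    permuted = InterpolantState(
        MoleculeGraph(g.coords[perm], g.atom_types[perm], g.charges[perm],
                      dense[iu, ju]), state.time)
    out = tiny_model.forward(state)
    out_p = tiny_model.forward(permuted)
    np.testing.assert_allclose(out_p.pred_coords, out.pred_coords[perm],
                               atol=1e-8)
    np.testing.assert_allclose(out_p.atom_logits, out.atom_logits[perm],
                               atol=1e-8)


def test_forward_reflection_sensitivity_on_chiral_input(tiny_model, vocab,
                                                        fixture_set):
    # L-alanine fixture: a mirrored conformer must yield different logits
    alanine = next(g for g in fixture_set.graphs if g.n_atoms == 13)
    state = InterpolantState(alanine, 0.5)
    mirrored = InterpolantState(
        MoleculeGraph(alanine.coords * np.array([1.0, 1.0, -1.0]),
                      alanine.atom_types, alanine.charges, alanine.bond_orders),
        0.5)
    out = tiny_model.forward(state)
    out_m = tiny_model.forward(mirrored)
    assert np.abs(out.atom_logits - out_m.atom_logits).max() > 1e-6


def test_forward_deterministic_and_single_atom(tiny_model, vocab, rng):
    state = _random_state(vocab, rng)
    a = tiny_model.forward(state)
    b = tiny_model.forward(state)
    assert np.array_equal(a.pred_coords, b.pred_coords)
    assert np.array_equal(a.atom_logits, b.atom_logits)
    # single-atom graph (no edges) passes through with zero message
    single = InterpolantState(MoleculeGraph(np.zeros((1, 3)), [1], [2], []), 0.3)
    out = tiny_model.forward(single)
    assert out.pred_coords.shape == (1, 3) and out.bond_logits.shape[0] == 0


def test_out_of_vocabulary_token_raises(tiny_model, vocab, rng):
    state = _random_state(vocab, rng)
    state.graph.atom_types[0] = vocab.n_atom_types + 3
    with pytest.raises(ValueError, match="vocabulary"):
        tiny_model.forward(state)


def test_self_conditioning_absent_equals_unconditioned(tiny_model, vocab, rng):
    state = _random_state(vocab, rng)
    out_plain = tiny_model.forward(state)
    out_none = tiny_model.forward(state, prev=None)
    assert np.array_equal(out_plain.pred_coords, out_none.pred_coords)


def test_self_conditioning_residual_equivariance(tiny_model, vocab, rng):
    state = _random_state(vocab, rng)
    prev = tiny_model.forward(state)
    R = Rotation.random(random_state=8).as_matrix()
    prev_rot = DenoiserOutput(pred_coords=prev.pred_coords @ R.T,
                              atom_logits=prev.atom_logits,
                              charge_logits=prev.charge_logits,
                              bond_logits=prev.bond_logits)
    out = tiny_model.forward(state, prev=prev)
    out_rot = tiny_model.forward(_rotate_state(state, R), prev=prev_rot)
    np.testing.assert_allclose(out_rot.pred_coords, out.pred_coords @ R.T,
                               atol=1e-4)
    np.testing.assert_allclose(out_rot.atom_logits, out.atom_logits, atol=1e-4)


def test_batching_matches_single_molecule(tiny_model, vocab, rng):
    states = [_random_state(vocab, rng, n=n) for n in (4, 6, 5)]
    batch = GraphBatch.from_graphs([s.graph for s in states],
                                   np.array([s.time for s in states]))
    with ad.no_grad():
        out = tiny_model.forward_batch(batch)
    from molfm.network import detach_output, split_output
    per_mol = split_output(detach_output(out), batch)
    for st, om in zip(states, per_mol):
        single = tiny_model.forward(st)
        np.testing.assert_allclose(om.pred_coords, single.pred_coords, atol=1e-10)
        np.testing.assert_allclose(om.bond_logits, single.bond_logits, atol=1e-10)


def test_full_scale_parameter_count(vocab):
    # default configuration sits in the single-digit-millions regime
    n = Denoiser(NetworkConfig(), vocab, seed=0).num_parameters()
    assert 3_000_000 < n < 10_000_000


def test_checkpoint_round_trip(tmp_path, tiny_model, vocab, rng):
    path = tmp_path / "model.npz"
    save_checkpoint(path, tiny_model, extra={"step": 42})
    model2, extra, _ = load_checkpoint(path)
    assert extra["step"] == 42
    state = _random_state(vocab, rng)
    a = tiny_model.forward(state)
    b = model2.forward(state)
    np.testing.assert_allclose(a.pred_coords, b.pred_coords, atol=1e-12)
    np.testing.assert_allclose(a.atom_logits, b.atom_logits, atol=1e-12)
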