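"""Conditional paths, transition kernels, and losses for both modalities."""

import numpy as np
import pytest

from molfm import ad
from molfm.augment import AugmentConfig
from molfm.coupling import make_coupling
from molfm.flows import (DenoiserOutput, LossConfig, discrete_transition_probs,
                         endpoint_coord_loss, interpolate_coords,
                         masked_ce_loss, multimodal_sample_path,
                         sample_discrete_path, step_discrete, total_loss)
from molfm.molgraph import MoleculeGraph


# -- continuous path ---------------------------------------------------------

def test_interpolant_endpoints_and_midpoint(rng):
    x0 = rng.standard_normal((6, 3))
    x1 = rng.standard_normal((6, 3))
    assert np.array_equal(interpolate_coords(x0, x1, 0.0), x0)
    assert np.array_equal(interpolate_coords(x0, x1, 1.0), x1)
    np.testing.assert_allclose(
        interpolate_coords([[0, 0, 0]], [[2, 0, 0]], 0.5), [[1, 0, 0]])
    with pytest.raises(ValueError):
        interpolate_coords(x0, x1, 1.2)


def test_endpoint_loss_time_weighting():
    x1 = np.zeros((1, 3))
    pred = np.array([[1.0, 0.0, 0.0]])  # 1 Å error on one axis
    assert endpoint_coord_loss(x1, x1, 0.3) == 0.0
    l0 = endpoint_coord_loss(pred, x1, 0.0)
    assert l0 == pytest.approx(1.0 / 3.0)          # w(0) = 1, mean over 3 coords
    assert endpoint_coord_loss(pred, x1, 0.5) == pytest.approx(4 * l0)  # w = 4
    # clamp: w(t) frozen at w_clamp near t = 1
    cfg = LossConfig(w_clamp=100.0)
    assert endpoint_coord_loss(pred, x1, 0.999, cfg) == pytest.approx(100.0 / 3.0)


def test_endpoint_loss_rotation_invariant(rng):
    from scipy.spatial.transform import Rotation
    pred = rng.standard_normal((5, 3))
    x1 = rng.standard_normal((5, 3))
    R = Rotation.random(random_state=0).as_matrix()
    assert endpoint_coord_loss(pred, x1, 0.4) == pytest.approx(
        endpoint_coord_loss(pred @ R.T, x1 @ R.T, 0.4), abs=1e-9)


# -- discrete path -----------------------------------------------------------

def test_discrete_path_endpoints(rng):
    final = rng.integers(0, 4, size=100)
    assert np.all(sample_discrete_path(final, 0.0, rng, mask_index=4) == 4)
    assert np.array_equal(sample_discrete_path(final, 1.0, rng, mask_index=4), final)


def test_discrete_path_marginal_matches_time(rng):
    n = 10_000
    final = rng.integers(0, 4, size=n)
    t = 0.3
    drawn = sample_discrete_path(final, t, rng, mask_index=4)
    frac = np.mean(drawn != 4)
    assert abs(frac - t) < 3 * np.sqrt(t * (1 - t) / n)


def test_masked_ce_closed_forms():
    # no masked tokens → 0
    logits = np.zeros((3, 5))
    assert masked_ce_loss(logits, [0, 1, 2], [0, 1, 2], mask_index=5) == 0.0
    # point mass on truth → ~0
    sharp = np.full((1, 5), -50.0)
    sharp[0, 2] = 50.0
    assert masked_ce_loss(sharp, [2], [5], mask_index=5) < 1e-6
    # uniform over D=5 → ln 5
    assert masked_ce_loss(np.zeros((1, 5)), [3], [5], mask_index=5) == \
        pytest.approx(np.log(5))


def test_transition_probs_closed_forms():
    # masked token, eta=0, point-mass denoiser: unmask prob dt/(1−t)
    probs = np.zeros((1, 5))
    probs[0, 2] = 1.0
    rates = discrete_transition_probs(probs, np.array([4]), t=0.5, dt=0.1, eta=0.0)
    assert rates.probs[0, 2] == pytest.approx(0.2)
    assert rates.probs[0, 4] == pytest.approx(0.8)
    # unmasked token, eta=2, dt=0.01: remask prob 0.02
    rates = discrete_transition_probs(np.full((1, 5), 0.2), np.array([1]),
                                      t=0.5, dt=0.01, eta=2.0)
    assert rates.probs[0, 4] == pytest.approx(0.02)
    assert rates.probs[0, 1] == pytest.approx(0.98)


def test_transition_rows_sum_to_one(rng):
    probs = rng.dirichlet(np.ones(5), size=64)
    current = rng.integers(0, 5, size=64)
    for t, eta in [(0.1, 0.0), (0.5, 3.0), (0.996, 1.0)]:
        rates = discrete_transition_probs(probs, current, t=t, dt=1 / 250, eta=eta)
        np.testing.assert_allclose(rates.probs.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(rates.probs >= 0)


def test_step_discrete_identity_rows_and_determinism(rng):
    current = np.array([0, 3, 2])
    eye_rows = np.eye(5)[current]
    from molfm.flows import DiscreteRates
    out = step_discrete(current, DiscreteRates(eye_rows), rng)
    assert np.array_equal(out, current)
    r1 = step_discrete(current, DiscreteRates(np.full((3, 5), 0.2)),
                       np.random.default_rng(0))
    r2 = step_discrete(current, DiscreteRates(np.full((3, 5), 0.2)),
                       np.random.default_rng(0))
    assert np.array_equal(r1, r2)


def _simulate_ctmc(final, n_steps, eta, rng, mask_index=4, n_cat=5):
    """CTMC with the exact oracle denoiser (point mass on the truth)."""
    tokens = np.full_like(final, mask_index)
    oracle = np.eye(n_cat)[final]
    dt = 1.0 / n_steps
    for k in range(n_steps):
        t = k / n_steps
        rates = discrete_transition_probs(oracle, tokens, t, dt, eta=eta,
                                          mask_index=mask_index)
        tokens = step_discrete(tokens, rates, rng)
    return tokens


def test_ctmc_oracle_reaches_target(rng):
    final = rng.integers(0, 4, size=10_000)
    tokens = _simulate_ctmc(final, n_steps=250, eta=0.0, rng=rng)
    assert np.mean(tokens == final) >= 0.99


def test_ctmc_oracle_with_remasking(rng):
    final = rng.integers(0, 4, size=5_000)
    tokens = _simulate_ctmc(final, n_steps=250, eta=1.0, rng=rng)
    assert np.mean(tokens == final) >= 0.95


# -- multi-modal composition -------------------------------------------------

def _toy_target(vocab, rng, n=6):
    coords = rng.standard_normal((n, 3))
    coords -= coords.mean(axis=0)
    return MoleculeGraph(coords, rng.integers(0, 5, n), rng.integers(0, 6, n),
                         rng.integers(0, 4, n * (n - 1) // 2))


def test_multimodal_endpoints(vocab, rng):
    g1 = _toy_target(vocab, rng)
    pair = make_coupling(g1.coords, rng)
    # t = 1, distortion disabled → exactly g1
    state = multimodal_sample_path(g1, pair, 1.0, rng, vocab,
                                   AugmentConfig(p_distort=0.0))
    assert state.graph == g1
    # t = 0 → all MASK, coords equal the prior endpoint
    state0 = multimodal_sample_path(g1, pair, 0.0, rng, vocab)
    assert np.all(state0.graph.atom_types == vocab.atom_mask_index)
    assert np.all(state0.graph.charges == vocab.charge_mask_index)
    assert np.all(state0.graph.bond_orders == vocab.bond_mask_index)
    np.testing.assert_allclose(state0.graph.coords, pair.x0)


def test_multimodal_modalities_independent(vocab, rng):
    # unmask indicators of atom types vs charges are uncorrelated
    g1 = _toy_target(vocab, rng, n=4)
    pair = make_coupling(g1.coords, rng)
    a_ind, c_ind = [], []
    for _ in range(10_000):
        st = multimodal_sample_path(g1, pair, 0.5, rng, vocab)
        a_ind.append(st.graph.atom_types[0] != vocab.atom_mask_index)
        c_ind.append(st.graph.charges[0] != vocab.charge_mask_index)
    corr = np.corrcoef(np.array(a_ind, float), np.array(c_ind, float))[0, 1]
    assert abs(corr) < 3.0 / np.sqrt(10_000)


def test_total_loss_composition(vocab, rng):
    g1 = _toy_target(vocab, rng)
    pair = make_coupling(g1.coords, rng)
    state = multimodal_sample_path(g1, pair, 0.0, rng, vocab)
    n, p = g1.n_atoms, len(g1.bond_orders)

    def onehot_logits(tokens, width):
        out = np.full((len(tokens), width), -30.0)
        out[np.arange(len(tokens)), tokens] = 30.0
        return out

    perfect = DenoiserOutput(
        pred_coords=g1.coords.copy(),
        atom_logits=onehot_logits(g1.atom_types, vocab.n_atom_types),
        charge_logits=onehot_logits(g1.charges, vocab.n_charges),
        bond_logits=onehot_logits(g1.bond_orders, vocab.n_bond_orders))
    total, parts = total_loss(perfect, g1, state, LossConfig(), vocab)
    assert parts["coords"] == 0.0
    assert all(v < 1e-6 for v in parts.values())

    noisy = DenoiserOutput(pred_coords=rng.standard_normal((n, 3)),
                           atom_logits=rng.standard_normal((n, vocab.n_atom_types)),
                           charge_logits=rng.standard_normal((n, vocab.n_charges)),
                           bond_logits=rng.standard_normal((p, vocab.n_bond_orders)))
    only_coords, parts2 = total_loss(
        noisy, g1, state, LossConfig(weight_atom_types=0, weight_charges=0,
                                     weight_bonds=0), vocab)
    assert only_coords == pytest.approx(parts2["coords"])
    single, _ = total_loss(noisy, g1, state, LossConfig(), vocab)
    doubled, _ = total_loss(noisy, g1, state, LossConfig(
        weight_coords=2, weight_atom_types=2, weight_charges=2, weight_bonds=2),
        vocab)
    assert doubled == pytest.approx(2 * single)


def test_loss_config_validation():
    with pytest.raises(ValueError):
        LossConfig(weight_coords=0, weight_atom_types=0, weight_charges=0,
                   weight_bonds=0)
    with pytest.raises(ValueError):
        LossConfig(w_clamp=0.5)
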