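"""Quality metrics: validity, FG deviation, OOD rings, CIs, additive effects."""

import numpy as np
import pytest
from rdkit import Chem

from molfm.metrics import (additive_effects, fg_deviation, fg_frequencies,
                           load_alert_smarts, load_ring_reference,
                           ood_ring_rate, pb_validity, relax_metrics,
                           ring_system_keys, subset_ci, subset_stats_ci,
                           validity_rate, MetricsReport)
from molfm.molgraph import MoleculeGraph


def test_bundled_alert_smarts_parse():
    smarts = load_alert_smarts()
    assert len(smarts) >= 30
    for name, sm in smarts.items():
        assert Chem.MolFromSmarts(sm) is not None, name


def test_validity_rates(fixture_set, vocab):
    pct, flags = validity_rate(fixture_set.graphs, vocab)
    assert pct == 100.0 and flags.all()
    # constructed pentavalent carbon is flagged invalid
    n = 6
    bad = MoleculeGraph(np.random.default_rng(0).standard_normal((n, 3)),
                        [vocab.element_index("C")] + [vocab.element_index("H")] * 5,
                        [vocab.charge_index(0)] * n,
                        [1, 1, 1, 1, 1] + [0] * 10)  # C bonded to 5 H
    good = fixture_set.graphs[:3]
    pct, flags = validity_rate(good + [bad], vocab)
    assert pct == pytest.approx(75.0)
    assert not flags[-1]
    with pytest.raises(ValueError):
        validity_rate([], vocab)


def test_fg_deviation_arithmetic(fixture_set, vocab):
    smarts = load_alert_smarts()
    freqs = fg_frequencies(fixture_set.graphs, smarts, vocab)
    # identical reference → deviation 0
    assert fg_deviation(fixture_set.graphs, freqs, smarts, vocab).deviation == 0.0
    # one group off by 0.2, all others matched → deviation 0.2
    shifted = dict(freqs)
    name = next(iter(smarts))
    shifted[name] = freqs[name] + 0.2
    rep = fg_deviation(fixture_set.graphs, shifted, smarts, vocab)
    assert rep.deviation == pytest.approx(0.2)
    # symmetry |a−b| = |b−a|
    rep2 = fg_deviation(fixture_set.graphs, {k: v - 0.2 if k == name else v
                                             for k, v in freqs.items()},
                        smarts, vocab)
    assert rep2.deviation == pytest.approx(rep.deviation)


def test_fg_deviation_order_and_duplication_invariant(fixture_set, vocab):
    smarts = load_alert_smarts()
    ref = {k: 0.1 for k in list(smarts)[:5]}
    sub = {k: smarts[k] for k in ref}
    mols = fixture_set.graphs
    d1 = fg_deviation(mols, ref, sub, vocab).deviation
    d2 = fg_deviation(mols[::-1], ref, sub, vocab).deviation
    d3 = fg_deviation(mols + mols, ref, sub, vocab).deviation
    assert d1 == pytest.approx(d2) == pytest.approx(d3)


def test_fg_rare_group_counted(fixture_set, vocab):
    # the single epoxide catalog entry gives a skewed nonzero frequency
    freqs = fg_frequencies(fixture_set.graphs, load_alert_smarts(), vocab)
    assert freqs["epoxide"] == pytest.approx(1 / len(fixture_set.graphs))


def test_unparsable_smarts_raises(fixture_set, vocab):
    with pytest.raises(ValueError, match="broken"):
        fg_deviation(fixture_set.graphs, {}, {"broken": "C((("}, vocab)


def test_ring_system_extraction():
    # naphthalene: one fused system; biphenyl: two benzene systems
    naph = Chem.MolFromSmiles("c1ccc2ccccc2c1")
    assert len(ring_system_keys(naph)) == 1
    biph = Chem.MolFromSmiles("c1ccc(-c2ccccc2)cc1")
    keys = ring_system_keys(biph)
    assert len(keys) == 2 and len(set(keys)) == 1
    # exocyclic double bond is part of the system key
    cyclohexanone = Chem.MolFromSmiles("O=C1CCCCC1")
    (key,) = ring_system_keys(cyclohexanone)
    assert "O" in key
    assert ring_system_keys(Chem.MolFromSmiles("CCO")) == []


def test_ood_ring_rate(fixture_set, vocab):
    reference = load_ring_reference()
    # acyclic-only batch → 0
    acyclic = [g for g in fixture_set.graphs if g.n_atoms <= 8][:5]
    assert ood_ring_rate(acyclic, reference, vocab)[0] == 0.0
    # every fixture ring system is in the bundled toy reference → 0
    rate, novel = ood_ring_rate(fixture_set.graphs, reference, vocab)
    assert rate == 0.0 and novel == []
    # a 4-membered all-nitrogen ring is OOD: 1 occurrence / 10 molecules = 0.1
    tetrazetidine = Chem.MolFromSmiles("N1NNN1")
    batch = [Chem.MolFromSmiles("CCO")] * 9 + [tetrazetidine]
    rate, novel = ood_ring_rate(batch, reference, vocab)
    assert rate == pytest.approx(0.1) and len(novel) == 1


def test_optional_wrappers_absent_tools(fixture_set, vocab, monkeypatch):
    # posebusters not installed → None with a warning, never a crash
    with pytest.warns(UserWarning, match="posebusters"):
        assert pb_validity(fixture_set.graphs[:2], vocab) is None
    monkeypatch.setattr("shutil.which", lambda name: None)
    with pytest.warns(UserWarning, match="xtb"):
        assert relax_metrics(fixture_set.graphs[:2], vocab) is None


def test_subset_ci_closed_form():
    mean, half = subset_stats_ci(np.array([1.0, 2.0, 3.0, 4.0, 5.0]))
    assert mean == pytest.approx(3.0)
    assert half == pytest.approx(1.96 * np.sqrt(2.5) / np.sqrt(5))
    mean, half = subset_stats_ci(np.full(5, 7.0))
    assert half == 0.0


def test_subset_ci_behavior(rng):
    values = rng.normal(10.0, 2.0, size=4000)
    m, h = subset_ci(values, k_subsets=5, rng=np.random.default_rng(0))
    assert m == pytest.approx(10.0, abs=0.2)
    with pytest.raises(ValueError):
        subset_ci([1.0, 2.0], k_subsets=5)
    # at fixed subset size the half-width scales as 1/√k (Monte-Carlo):
    # sd of subset means is fixed, so 1.96·sd/√k shrinks with more subsets
    size = 200
    hw5 = np.mean([subset_ci(rng.normal(0, 1, 5 * size), 5,
                             rng=np.random.default_rng(s))[1]
                   for s in range(60)])
    hw20 = np.mean([subset_ci(rng.normal(0, 1, 20 * size), 20,
                              rng=np.random.default_rng(s))[1]
                    for s in range(60)])
    assert hw20 == pytest.approx(hw5 / 2, rel=0.25)


def test_additive_effects_exact_recovery():
    # movement = 1.0 + 0.25·flag, no noise → coefficient 0.25, relative 0.25
    T = 6
    runs = [((False, False, False), np.full(T, 1.0)),
            ((True, False, False), np.full(T, 1.25))]
    fx = additive_effects(runs)
    np.testing.assert_allclose(fx.coefficients["self_conditioning"], 0.25)
    np.testing.assert_allclose(fx.relative_effects["self_conditioning"], 0.25)
    np.testing.assert_allclose(fx.intercept, 1.0)
    assert np.isnan(fx.coefficients["fake_atoms"]).all()  # did not vary
    # all-zero movement → zero coefficients
    zero = additive_effects([((False, False, False), np.zeros(T)),
                             ((True, False, False), np.zeros(T))])
    np.testing.assert_allclose(zero.coefficients["self_conditioning"], 0.0,
                               atol=1e-12)


def test_additive_effects_noisy_factorial(rng):
    # full 2³ factorial with known coefficients + noise: recovery within 3 SE
    from itertools import product
    true = {"b0": 2.0, "sc": -0.5, "fa": 0.3, "di": 0.4}
    T = 4
    runs = []
    n_rep = 50
    sigma = 0.2
    for flags in product([False, True], repeat=3):
        for _ in range(n_rep):
            y = (true["b0"] + true["sc"] * flags[0] + true["fa"] * flags[1]
                 + true["di"] * flags[2] + rng.normal(0, sigma, T))
            runs.append((flags, y))
    fx = additive_effects(runs)
    se = sigma / np.sqrt(len(runs) / 4)  # rough OLS standard error scale
    assert np.all(np.abs(fx.coefficients["self_conditioning"] - true["sc"]) < 3 * se * 4)
    assert np.all(np.abs(fx.coefficients["fake_atoms"] - true["fa"]) < 3 * se * 4)
    assert np.all(np.abs(fx.coefficients["distortion"] - true["di"]) < 3 * se * 4)


def test_additive_effects_errors():
    with pytest.raises(ValueError, match="distinct"):
        additive_effects([((False, False, False), np.zeros(3))] * 2)
    # two flags perfectly confounded → rank-deficient, names missing combos
    runs = [((False, False, False), np.zeros(3)),
            ((True, True, False), np.ones(3))]
    with pytest.raises(ValueError, match="missing"):
        additive_effects(runs)


def test_metrics_report_validation():
    with pytest.raises(ValueError):
        MetricsReport(percent_valid=120.0, fg_deviation=0.0, ood_ring_rate=0.0)
    rep = MetricsReport(percent_valid=90.0, fg_deviation=0.1, ood_ring_rate=0.0)
    assert "percent_pb_valid" not in rep.to_dict()  # omitted when absent
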