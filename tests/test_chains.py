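"""Chain sampling: bond geometry, ideal-chain statistics, excluded volume,
and agreement between the independent samplers."""

import numpy as np
import pytest

from knotcost import (ChainParams, generate_chain, generate_ensemble,
                      has_overlap, radius_of_gyration, sample_open_mcmc)
from knotcost.chains import bond_lengths

from oracles import brute_min_segment_distance, segment_pair_distance


def test_bond_lengths_exact(rng):
    params = ChainParams(n_segments=20, kuhn_length=1.4, diameter=0.49)
    chain = generate_chain(params, rng)
    assert np.allclose(bond_lengths(chain), 1.4, rtol=1e-9)


def test_single_bond_end_to_end(rng):
    params = ChainParams(n_segments=1, kuhn_length=2.5, diameter=0.0)
    chain = generate_chain(params, rng)
    assert np.linalg.norm(chain[-1] - chain[0]) == pytest.approx(2.5)


def test_phantom_mean_squared_end_to_end(rng):
    # ideal freely-jointed chain: <R^2> = N l^2
    n, l, n_chains = 50, 1.4, 10_000
    ens = generate_ensemble(ChainParams(n, l, 0.0), n_chains, rng)
    r2 = ((ens[:, -1] - ens[:, 0]) ** 2).sum(axis=1)
    expected = n * l * l
    sem = r2.std(ddof=1) / np.sqrt(n_chains)
    assert abs(r2.mean() - expected) < 3 * sem


def test_excluded_volume_constraint_holds(rng):
    params = ChainParams(n_segments=32, kuhn_length=1.4, diameter=0.49)
    for _ in range(5):
        chain = generate_chain(params, rng)
        assert brute_min_segment_distance(chain) >= 0.49 - 1e-6


def test_has_overlap_matches_brute_force(rng):
    # 200 phantom chains against a dense-sampling distance oracle
    params = ChainParams(n_segments=12, kuhn_length=1.0, diameter=0.0)
    diameter = 0.6
    n_disagree = 0
    for _ in range(200):
        chain = generate_chain(params, rng)
        d_min = brute_min_segment_distance(chain)
        fast = has_overlap(chain, diameter)
        # dense sampling overestimates the minimum: skip borderline cases
        if abs(d_min - diameter) < 0.01:
            continue
        n_disagree += fast != (d_min < diameter)
    assert n_disagree == 0


def test_has_overlap_straight_chain_false():
    chain = np.column_stack([np.arange(8.0), np.zeros(8), np.zeros(8)])
    assert not has_overlap(chain, 0.9)


def test_has_overlap_parallel_offset_segments_true():
    # segments 0 and 3 are parallel, offset by 0.4 of a unit bond
    chain = np.array([[0, 0, 0], [1, 0, 0], [1.5, 0.2, 0.2],
                      [0.0, 0.0, 0.4], [1.0, 0.0, 0.4]], dtype=float)
    assert segment_pair_distance(chain[3], chain[4], chain[0],
                                 chain[1]) < 0.5
    assert has_overlap(chain, 0.5)


def test_straight_collinear_chain_radius_of_gyration():
    # collinear equally spaced vertices: Rg^2 = l^2 (V^2 - 1)/12 exactly
    n_seg, l = 10, 1.4
    chain = np.column_stack([l * np.arange(n_seg + 1.0),
                             np.zeros(n_seg + 1), np.zeros(n_seg + 1)])
    v = n_seg + 1
    expected = l * np.sqrt((v * v - 1) / 12.0)
    mean, _ = radius_of_gyration(chain)
    assert mean == pytest.approx(expected, rel=1e-12)


def test_phantom_rg_matches_ideal_chain(rng):
    # <Rg^2> ~ N l^2 / 6 for the ideal chain
    n, l = 50, 1.4
    ens = generate_ensemble(ChainParams(n, l, 0.0), 4000, rng)
    centred = ens - ens.mean(axis=1, keepdims=True)
    rg2 = (centred ** 2).sum(axis=2).mean(axis=1)
    expected = n * l * l / 6.0
    sem = rg2.std(ddof=1) / np.sqrt(len(rg2))
    assert abs(rg2.mean() - expected) < 3 * sem + 0.02 * expected


def test_dimerization_agrees_with_mcmc_sampler(rng):
    # the two independent samplers target the same hard-cylinder ensemble
    params = ChainParams(n_segments=32, kuhn_length=1.4, diameter=0.49)
    rg_a, sem_a = radius_of_gyration(generate_ensemble(params, 2000, rng))
    rg_b, sem_b = radius_of_gyration(
        sample_open_mcmc(params, 2000, rng, stride=60))
    # MCMC samples are correlated; allow an inflated combined error
    assert abs(rg_a - rg_b) < 3 * np.sqrt(sem_a**2 + (3 * sem_b) ** 2)


def test_samplers_agree_on_knot_fraction(rng):
    # i.i.d. dimerization vs crankshaft/pivot MCMC: same phantom
    # ensemble, so the closed-at-infinity knot fractions must agree
    from knotcost import close_chain, knot_invariant
    params = ChainParams(n_segments=32, kuhn_length=1.4, diameter=0.0)
    n = 2500
    k_iid = sum(knot_invariant(close_chain(c)).is_knotted
                for c in generate_ensemble(params, n, rng))
    k_mcmc = sum(knot_invariant(close_chain(c)).is_knotted
                 for c in sample_open_mcmc(params, n, rng, stride=40))
    p1, p2 = k_iid / n, k_mcmc / n
    se = np.sqrt((p1 * (1 - p1) + p2 * (1 - p2)) / n)
    # MCMC samples are correlated: widen the combined error accordingly
    assert abs(p1 - p2) < 3 * 2 * se + 0.01


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        ChainParams(n_segments=0)
    with pytest.raises(ValueError):
        ChainParams(n_segments=5, kuhn_length=1.0, diameter=1.2)
    with pytest.raises(ValueError):
        ChainParams(n_segments=5, temperature=-1.0)
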