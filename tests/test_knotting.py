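"""Knotting-probability estimator, ΔG_S conversion, and the scans."""

import numpy as np
import pandas as pd
import pytest

from knotcost import (ChainParams, ExtrapolationError, delta_g_s,
                      interpolate_effective_diameter, knotting_probability,
                      scan_chain_length, scan_diameter)
from knotcost.constants import R_KCAL
from knotcost.knotting import DiameterScan


def test_hexagon_chains_never_knot():
    # six-segment equilibrium rings essentially cannot knot (equilateral
    # hexagonal trefoils have negligible measure)
    params = ChainParams(n_segments=6, kuhn_length=1.4, diameter=0.0)
    est = knotting_probability(params, 10_000, seed=3, ensemble="ring")
    assert est.p_knot == 0.0
    assert np.isinf(est.delta_g_s)
    assert est.delta_g_s_lower_bound is not None
    # open six-segment chains acquire a tiny knot fraction purely from
    # the closure construction (buried termini); it stays well below 1e-3
    est_open = knotting_probability(params, 10_000, seed=3, ensemble="open")
    assert est_open.p_knot <= 1e-3


def test_excluded_volume_lowers_knotting():
    phantom = knotting_probability(
        ChainParams(32, 1.4, 0.0), 30_000, seed=5, ensemble="open")
    thick = knotting_probability(
        ChainParams(32, 1.4, 0.49), 30_000, seed=5, ensemble="open")
    assert phantom.p_knot > thick.ci95[1]


def test_delta_g_s_symmetry_and_inversion():
    assert delta_g_s(0.5, temperature=298.0) == pytest.approx(0.0)
    p = np.exp(-10) / (1 + np.exp(-10))
    assert delta_g_s(p, temperature=298.0) == pytest.approx(
        10 * R_KCAL * 298.0, rel=1e-9)
    for bad in (0.0, 1.0):
        with pytest.raises(ValueError):
            delta_g_s(bad)


def test_small_fraction_limit():
    # dG_S ~ -RT ln p to within RT*p for p < 0.01
    rt = R_KCAL * 298.15
    for p in (1e-3, 5e-3):
        # |ln(1-p)| = p + p^2/2 + ..., so allow the quadratic remainder
        assert abs(delta_g_s(p) - (-rt * np.log(p))) < rt * p * 1.01


def test_estimate_bookkeeping():
    est = knotting_probability(ChainParams(32, 1.4, 0.0), 4000, seed=9)
    assert est.n_total == 4000
    assert sum(est.n_knot.values()) == 4000
    assert est.ci95[0] <= est.p_knot <= est.ci95[1]
    assert 0 < est.mean_rg < 32 * 1.4


def test_ring_and_open_phantom_agree():
    # equilibrium rings and closed-at-infinity open chains give similar
    # (not identical) knot fractions at this length; sanity-band check
    ring = knotting_probability(ChainParams(32, 1.4, 0.0), 20_000, seed=11,
                                ensemble="ring", classify="any")
    open_ = knotting_probability(ChainParams(32, 1.4, 0.0), 20_000, seed=11,
                                 ensemble="open", classify="any")
    assert 0.5 < ring.p_knot / open_.p_knot < 2.5


def test_scan_chain_length_consistency():
    scan = scan_chain_length([32], 0.0, 5000, seed=21)
    direct = knotting_probability(ChainParams(32, 1.4, 0.0), 5000,
                                  seed=21 + 0 * 7919)
    assert scan.table.loc[0, "p_knot"] == pytest.approx(direct.p_knot)
    with pytest.raises(ExtrapolationError):
        scan.predict(10)


def test_knotting_monotone_in_length_within_cis():
    scan = scan_chain_length([20, 50, 100], 0.0, 4000, seed=2)
    his = scan.table["ci_hi"].to_numpy()
    los = scan.table["ci_lo"].to_numpy()
    for i in range(len(los) - 1):
        assert his[i + 1] >= los[i]  # non-decreasing within 95% CIs


def _fake_scan(slope, intercept, xs, err=0.05):
    rows = [{"d_over_2p": x, "n": 1000, "n_trefoil": 10, "n_other": 0,
             "n_events": 10, "p_knot": 1e-3, "ci_lo": 0, "ci_hi": 1,
             "dG_S": intercept + slope * x, "dG_S_err": err,
             "mean_rg": 3.0} for x in xs]
    scan = DiameterScan(table=pd.DataFrame(rows), estimates=[])
    import statsmodels.api as sm
    x = np.array(xs)
    y = scan.table["dG_S"].to_numpy()
    res = sm.WLS(y, sm.add_constant(x), weights=np.full_like(x, 1 / err**2)).fit()
    scan.intercept, scan.slope = map(float, res.params)
    scan.cov = np.asarray(res.normalized_cov_params)
    return scan


def test_interpolation_exact_on_collinear_points():
    scan = _fake_scan(10.0, 2.0, [0.1, 0.3, 0.5])
    x, (lo, hi) = interpolate_effective_diameter(scan, 5.8)
    assert x == pytest.approx((5.8 - 2.0) / 10.0, abs=1e-9)
    assert lo <= x <= hi


def test_interpolation_rejects_extrapolation():
    scan = _fake_scan(10.0, 2.0, [0.1, 0.3, 0.5])
    with pytest.raises(ExtrapolationError):
        interpolate_effective_diameter(scan, 20.0)


def test_interpolation_coverage():
    # synthetic lines + Gaussian noise: the 95% CI covers the true
    # crossing in >= 93/100 replicates
    rng = np.random.default_rng(99)
    slope, intercept, err = 11.0, 2.0, 0.25
    xs = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
    truth = (5.8 - intercept) / slope
    import statsmodels.api as sm
    hits = 0
    for _ in range(100):
        y = intercept + slope * xs + rng.normal(0, err, size=xs.size)
        scan = _fake_scan(slope, intercept, list(xs), err)
        res = sm.WLS(y, sm.add_constant(xs),
                     weights=np.full_like(xs, 1 / err**2)).fit()
        scan.intercept, scan.slope = map(float, res.params)
        scan.cov = np.asarray(res.normalized_cov_params)
        scan.table["dG_S"] = y
        try:
            x, (lo, hi) = interpolate_effective_diameter(scan, 5.8)
        except ExtrapolationError:
            continue
        hits += lo <= truth <= hi
    assert hits >= 93


def test_scan_diameter_requires_increasing_grid():
    with pytest.raises(ValueError):
        scan_diameter([0.3, 0.1], 32, 100)
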