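"""CFT crossing, coexistence-force free energy, Boltzmann populations
and the thermodynamic cycle."""

import numpy as np
import pytest

from knotcost import (FitQualityError, GaussianWorkFit, WLCParams,
                      boltzmann_state_probabilities, cft_delta_g,
                      delta_g_f_half, delta_g_native, f_half,
                      fit_work_distribution, knotting_cost_cycle,
                      stretch_work, wlc_extension)
from knotcost.constants import KCAL_MOL_PER_PN_NM, R_KCAL
from knotcost.synth import gen_cft_work_samples


def _fit(mean, sd, direction="unfold", n=100):
    return GaussianWorkFit(mean=mean, sd=sd, n=n, direction=direction)


def test_cft_equal_sds_midpoint():
    assert cft_delta_g(_fit(4, 1, "fold"), _fit(8, 1)) == pytest.approx(6.0)


def test_cft_unequal_sds_matches_grid_search():
    fold, unfold = _fit(4.0, 1.0, "fold"), _fit(8.0, 2.0)
    got = cft_delta_g(fold, unfold)
    w = np.linspace(4, 8, 2_000_001)
    pdf_f = np.exp(-0.5 * ((w - 4) / 1) ** 2) / 1
    pdf_u = np.exp(-0.5 * ((w - 8) / 2) ** 2) / 2
    grid = w[np.argmin(np.abs(pdf_f - pdf_u))]
    assert got == pytest.approx(grid, abs=1e-5)
    assert 4 < got < 8


def test_cft_pathological_fit_raises():
    # identical means with different spreads: the equal-density points
    # are symmetric about the (degenerate) between-means interval
    with pytest.raises(FitQualityError):
        cft_delta_g(_fit(5.0, 1.0, "fold"), _fit(5.0, 2.0))


def test_cft_recovery_on_synthetic_work_samples():
    # generator truth 12.2 kcal/mol; mean recovered crossing within 0.2
    vals = []
    rng = np.random.default_rng(42)
    for _ in range(100):
        s = gen_cft_work_samples(12.2, 2.0, 500, seed=rng)
        vals.append(cft_delta_g(
            fit_work_distribution(s.fold_flipped, "fold"),
            fit_work_distribution(s.unfold, "unfold")))
    vals = np.array(vals)
    assert abs(vals.mean() - 12.2) < 0.2
    assert vals.std(ddof=1) < 0.5


def test_f_half_symmetric_construction():
    forces = np.linspace(2, 8, 7)
    folded = np.column_stack([forces, np.exp(-forces)])
    unfolded = np.column_stack([forces, np.exp(forces - 10)])
    assert f_half(folded, unfolded) == pytest.approx(5.0)


def test_f_half_exchange_symmetric(rng):
    a = np.column_stack([np.linspace(2, 9, 6),
                         np.exp(-0.8 * np.linspace(2, 9, 6) + 3)])
    b = np.column_stack([np.linspace(2, 9, 6),
                         np.exp(0.5 * np.linspace(2, 9, 6) - 6)])
    assert f_half(a, b) == pytest.approx(f_half(b, a))


def test_f_half_parallel_lines_raise():
    f = np.linspace(2, 8, 5)
    with pytest.raises(ValueError):
        f_half(np.column_stack([f, np.exp(-f)]),
               np.column_stack([f, 2 * np.exp(-f)]))


def test_f_half_bell_lifetime_recovery(rng):
    # Bell lifetimes tau = 1/k with crossing constructed at 7 pN
    f = np.linspace(4, 10, 8)
    tau_fold = np.exp(-1.1 * (f - 7.0))
    tau_unfold = np.exp(0.9 * (f - 7.0))
    noise = lambda: rng.lognormal(0.0, 0.05, size=f.size)
    got = f_half(np.column_stack([f, tau_fold * noise()]),
                 np.column_stack([f, tau_unfold * noise()]))
    assert got == pytest.approx(7.0, abs=0.3)


def test_delta_g_f_half_limit_and_arithmetic():
    p = WLCParams(contour_length=37.0)
    assert delta_g_f_half(0.0, p) == 0.0
    f = 7.3
    expected = (f * wlc_extension(f, p) * KCAL_MOL_PER_PN_NM
                - stretch_work(f, p))
    assert delta_g_f_half(f, p) == pytest.approx(expected, rel=1e-6)


def test_boltzmann_probabilities():
    p = boltzmann_state_probabilities([1.0] * 7)
    assert np.allclose(p, 1 / 7)
    p = boltzmann_state_probabilities([0.0, 1.0], kt=1.0)
    assert p[0] == pytest.approx(1 / (1 + np.exp(-1)))
    assert p[1] == pytest.approx(np.exp(-1) / (1 + np.exp(-1)))
    rng = np.random.default_rng(0)
    p = boltzmann_state_probabilities(rng.normal(0, 5, size=6000))
    assert p.sum() == pytest.approx(1.0, abs=1e-12)


def test_delta_g_native_counts_and_symmetry():
    assert delta_g_native(10, 10) == 0.0
    got = delta_g_native(6, 26, rt=0.593)
    assert got == pytest.approx(-0.593 * np.log(6 / 26), rel=1e-12)
    assert delta_g_native(2, 8) == pytest.approx(-delta_g_native(8, 2))
    with pytest.raises(ValueError):
        delta_g_native(0, 5)


def test_delta_g_native_consistent_with_boltzmann_two_level():
    gap = 0.9  # kcal/mol, knotted state lower
    rt = R_KCAL * 298.15
    p = boltzmann_state_probabilities([gap, 0.0], kt=rt)
    assert delta_g_native(p[0], p[1], rt=rt) == pytest.approx(gap)


def test_cycle_trivial_and_closure():
    assert knotting_cost_cycle(5.0, 5.0, 0.0).dg_unfolded_knotting == 0.0
    cyc = knotting_cost_cycle(12.2, 6.2, 0.9, err_knotted=0.2,
                              err_unknotted=0.2, err_native=0.1)
    # recompute each edge from the other three
    assert cyc.dg_unfold_knotted == pytest.approx(
        cyc.dg_unfolded_knotting + cyc.dg_unfold_unknotted + cyc.dg_native,
        abs=1e-12)
    assert cyc.propagated_err == pytest.approx(np.sqrt(0.04 + 0.04 + 0.01))
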