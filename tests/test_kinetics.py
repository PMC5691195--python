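"""Bell/DHS rate laws, histogram transformation, fits and first-passage
simulation."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from knotcost import (KineticModel, LoadingProtocol, bell_rate, dhs_rate,
                      fit_kinetic_model, rates_from_force_histogram,
                      simulate_rupture_forces)
from knotcost.constants import kt_pn_nm

PROT = LoadingProtocol()  # 100 nm/s, 0.1 pN/nm -> 10 pN/s, 2-30 pN


def test_bell_trivials():
    m = KineticModel(k0=0.02, dx_ddagger=2.0)
    assert bell_rate(0.0, m) == pytest.approx(0.02)
    flat = KineticModel(k0=0.02, dx_ddagger=0.0)
    assert bell_rate(17.0, flat) == pytest.approx(0.02)
    # exact log-linearity
    kt = kt_pn_nm(m.temperature)
    lhs = np.log(bell_rate(9.0, m)) - np.log(bell_rate(4.0, m))
    assert lhs == pytest.approx(5.0 * 2.0 / kt, rel=1e-12)


def test_dhs_nu_one_collapses_to_bell():
    m = KineticModel(k0=0.01, dx_ddagger=2.0, dg_ddagger=12.0, nu=1.0)
    b = KineticModel(k0=0.01, dx_ddagger=2.0)
    for f in (0.0, 3.0, 8.0):
        assert dhs_rate(f, m) == pytest.approx(bell_rate(f, b), rel=1e-12)


def test_dhs_high_barrier_limit_is_bell():
    b = KineticModel(k0=0.01, dx_ddagger=2.0)
    # relative deviation scales as 1/barrier; convergence and the limit
    errs = []
    for dg in (1e3, 1e5, 1e7):
        m = KineticModel(k0=0.01, dx_ddagger=2.0, dg_ddagger=dg, nu=0.5)
        errs.append(abs(dhs_rate(10.0, m) / bell_rate(10.0, b) - 1.0))
    assert errs[0] > errs[1] > errs[2]
    assert errs[2] < 1e-6
    m = KineticModel(k0=0.01, dx_ddagger=2.0, dg_ddagger=1e7, nu=0.5)
    assert dhs_rate(0.0, m) == pytest.approx(0.01)


def test_dhs_critical_force_domain_error():
    m = KineticModel(k0=0.01, dx_ddagger=2.0, dg_ddagger=2.0, nu=0.5)
    with pytest.raises(ValueError):
        dhs_rate(100.0, m)


def test_histogram_transform_matches_bell_rate():
    truth = KineticModel(k0=0.01, dx_ddagger=2.0)
    forces = simulate_rupture_forces(truth, PROT, 20_000, seed=2)
    table = rates_from_force_histogram(forces, PROT)
    # central 80% of the sampled force range within 20% of the true law
    f_lo, f_hi = np.quantile(forces, [0.1, 0.9])
    sel = table[(table["force_pN"] >= f_lo) & (table["force_pN"] <= f_hi)]
    assert len(sel) >= 3
    ratio = sel["k_per_s"] / bell_rate(sel["force_pN"].to_numpy(), truth)
    assert np.all((ratio > 0.8) & (ratio < 1.25))


def test_histogram_transform_survival_monotone():
    truth = KineticModel(k0=0.01, dx_ddagger=2.0)
    forces = simulate_rupture_forces(truth, PROT, 5000, seed=3)
    f = np.sort(forces)
    surv = 1.0 - np.arange(len(f)) / len(f)
    assert np.all(np.diff(surv) <= 0)


def test_fit_recovers_exact_bell_table():
    truth = KineticModel(k0=0.013, dx_ddagger=1.7)
    f = np.linspace(4, 16, 9)
    table = pd.DataFrame({"force_pN": f, "k_per_s": bell_rate(f, truth)})
    fit, _ = fit_kinetic_model(table, "bell")
    assert fit.k0 == pytest.approx(truth.k0, rel=1e-8)
    assert fit.dx_ddagger == pytest.approx(truth.dx_ddagger, rel=1e-8)


def test_dhs_fit_recovery_on_noisy_replicates():
    truth = KineticModel(k0=0.01, dx_ddagger=2.0, dg_ddagger=10.0, nu=0.5)
    # a wide force window keeps the three-parameter fit identifiable
    f = np.linspace(3, 30, 15)
    k_true = dhs_rate(f, truth)
    rng = np.random.default_rng(7)
    ok = 0
    for _ in range(100):
        table = pd.DataFrame({
            "force_pN": f,
            "k_per_s": k_true * rng.lognormal(0.0, 0.1, size=f.size),
            "se_ln_k": np.full(f.size, 0.1)})
        try:
            fit, errs = fit_kinetic_model(table, "dhs", nu=0.5)
        except Exception:
            continue
        if (abs(fit.dx_ddagger - 2.0) < 2 * max(errs["dx_ddagger"], 0.05)
                and abs(fit.dg_ddagger - 10.0)
                < 2 * max(errs["dg_ddagger"], 0.5)):
            ok += 1
    assert ok >= 90


def test_bell_fit_on_dhs_data_shows_curvature():
    # residuals of a straight-line fit to DHS data carry a systematic
    # concave sign pattern: negative at both ends, positive in the middle
    truth = KineticModel(k0=0.005, dx_ddagger=3.0, dg_ddagger=8.0, nu=0.5)
    f = np.linspace(2, 12, 15)
    lnk = np.log(dhs_rate(f, truth))
    coef = np.polyfit(f, lnk, 1)
    resid = lnk - np.polyval(coef, f)
    assert resid[0] < 0 and resid[-1] < 0
    assert resid[len(resid) // 2] > 0


def test_constant_hazard_rupture_distribution():
    # dx = 0: constant rate k on a linear ramp -> exponential in (F - F0)
    k0 = 1.0
    m = KineticModel(k0=k0, dx_ddagger=0.0)
    prot = LoadingProtocol(force_window=(2.0, 500.0))
    forces = simulate_rupture_forces(m, prot, 10_000, seed=5)
    r = prot.pulling_speed * prot.effective_stiffness
    stat = kstest((forces - 2.0), "expon", args=(0, r / k0))
    assert stat.pvalue > 0.01


def test_mean_rupture_force_increases_with_speed():
    m = KineticModel(k0=0.01, dx_ddagger=2.0)
    means = []
    for speed in (30.0, 100.0, 300.0):
        prot = LoadingProtocol(pulling_speed=speed)
        means.append(simulate_rupture_forces(m, prot, 4000,
                                             seed=11).mean())
    assert means[0] < means[1] < means[2]


def test_refolding_dx_shift_moves_distribution():
    # shrinking |dx| of the refolding branch by ~4 nm raises the mean
    # refolding force and broadens the distribution
    wide = KineticModel(k0=1e4, dx_ddagger=-8.0)
    narrow = KineticModel(k0=1e4, dx_ddagger=-4.0)
    f_wide = simulate_rupture_forces(wide, PROT, 5000, seed=13,
                                     direction="fold")
    f_narrow = simulate_rupture_forces(narrow, PROT, 5000, seed=13,
                                       direction="fold")
    assert f_narrow.mean() > f_wide.mean()
    assert f_narrow.std(ddof=1) > f_wide.std(ddof=1)


def test_model_validation():
    with pytest.raises(ValueError):
        KineticModel(k0=-1.0, dx_ddagger=2.0)
    with pytest.raises(ValueError):
        KineticModel(k0=1.0, dx_ddagger=2.0, dg_ddagger=5.0, nu=1.5)
    with pytest.raises(ValueError):
        dhs_rate(1.0, KineticModel(k0=1.0, dx_ddagger=2.0))
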