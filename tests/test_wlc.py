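"""WLC force law, inversion, works, contour lengths and rip detection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from knotcost import (Rip, WLCParams, detect_rips,
                      experimental_contour_length, observed_work,
                      stretch_work, theoretical_contour_length,
                      wlc_extension, wlc_force, work_at_zero_force)
from knotcost.constants import KCAL_MOL_PER_PN_NM, kt_pn_nm
from knotcost.synth import ExperimentSpec, gen_pulling_dataset

from oracles import marko_siggia_work_closed_form

P37 = WLCParams(persistence_length=0.65, contour_length=37.0)
P42 = WLCParams(persistence_length=0.65, contour_length=42.0)


def test_zero_extension_zero_force():
    assert wlc_force(0.0, P37) == 0.0
    assert wlc_extension(0.0, P37) == 0.0


def test_force_at_half_contour_direct_arithmetic():
    kt_over_p = kt_pn_nm(298.15) / 0.65
    expected = kt_over_p * (1.0 / (4 * 0.25) - 0.25 + 0.5)
    assert wlc_force(0.5 * 37.0, P37) == pytest.approx(expected, rel=1e-12)


@given(st.floats(0.1, 0.9))
@settings(deadline=None, max_examples=25)
def test_force_extension_round_trip(frac):
    x = frac * P37.contour_length
    assert wlc_extension(wlc_force(x, P37), P37) == pytest.approx(
        x, rel=1e-9)


def test_force_diverges_at_contour_length():
    with pytest.raises(ValueError):
        wlc_force(37.0, P37)


def test_extension_monotone_to_contour_length():
    forces = np.linspace(0.5, 200.0, 50)
    xs = [wlc_extension(f, P37) for f in forces]
    assert np.all(np.diff(xs) > 0)
    assert xs[-1] < 37.0


@pytest.mark.parametrize("n_res, expected",
                         [(120, 42.0), (103, 36.05), (1, 0.35)])
def test_theoretical_contour_length(n_res, expected):
    assert theoretical_contour_length(n_res) == pytest.approx(expected)


def test_stretch_work_matches_analytic_antiderivative():
    for f in (1.0, 4.7, 7.3, 14.7, 25.0):
        ref = marko_siggia_work_closed_form(f, 37.0, 0.65,
                                            kt_pn_nm(298.15))
        assert stretch_work(f, P37) == pytest.approx(
            ref * KCAL_MOL_PER_PN_NM, rel=1e-6)
    assert stretch_work(0.0, P37) == 0.0


def test_stretch_work_monotone():
    w = [stretch_work(f, P42) for f in (1, 5, 10, 20)]
    assert np.all(np.diff(w) > 0)


def test_observed_work_unit_conversion():
    # 10 pN x 20 nm = 200 pN nm = 28.78 kcal/mol
    rip = Rip(force=10.0, delta_x=20.0, direction="unfold")
    assert observed_work(rip) == pytest.approx(200 * KCAL_MOL_PER_PN_NM)
    assert observed_work(rip) == pytest.approx(28.78, abs=0.01)


def test_work_record_invariant(rng):
    for _ in range(100):
        rip = Rip(force=float(rng.uniform(2, 20)),
                  delta_x=float(rng.uniform(5, 25)),
                  direction="unfold")
        rec = work_at_zero_force(rip, P42)
        assert rec.w_zero == pytest.approx(rec.w_obs - rec.w_s)


def test_experimental_contour_length_ratio_identity():
    # delta_x equal to the WLC prediction returns the theoretical L_c
    for f in (5.0, 10.0):
        dx = wlc_extension(f, P42)
        assert experimental_contour_length(f, P42, delta_x=dx) \
            == pytest.approx(42.0)


def test_experimental_contour_length_recovers_true_lc(rng):
    # rips generated from a 37-nm chain, evaluated against 42-nm theory
    vals = []
    for _ in range(200):
        f = float(rng.uniform(5, 18))
        dx = wlc_extension(f, P37)
        vals.append(experimental_contour_length(f, P42, delta_x=dx))
    vals = np.array(vals)
    assert abs(vals.mean() - 37.0) < 3 * vals.std(ddof=1) / np.sqrt(len(vals)) + 0.05


def test_detect_rips_noiseless_round_trip():
    spec = ExperimentSpec(n_molecules=(1, 1), cycles_per_molecule=2,
                          noise_sd=0.0, seed=4)
    traces, truth = gen_pulling_dataset(spec)
    rips = detect_rips(traces)
    assert len(rips) == len(truth)
    got = sorted(r.force for r in rips)
    exp = sorted(truth["force_pN"])
    assert np.allclose(got, exp, atol=0.15)


def test_detect_rips_pure_wlc_trace_empty():
    import pandas as pd
    f = np.linspace(2, 28, 300)
    trace = pd.DataFrame({"time_s": np.arange(300) / 1e3,
                          "extension_nm": np.linspace(0, 20, 300),
                          "force_pN": f, "ramp_id": 0, "direction": "pull"})
    assert detect_rips(trace) == []


def test_detect_rips_recall_on_noisy_cycles():
    spec = ExperimentSpec(n_molecules=(3, 3), cycles_per_molecule=10,
                          seed=8)
    traces, truth = gen_pulling_dataset(spec)
    rips = detect_rips(traces)
    assert len(rips) / len(truth) >= 0.99


def test_rip_validation():
    with pytest.raises(ValueError):
        Rip(force=-1.0, delta_x=5.0, direction="unfold")
    with pytest.raises(ValueError):
        Rip(force=1.0, delta_x=0.0, direction="unfold")
    with pytest.raises(ValueError):
        Rip(force=1.0, delta_x=5.0, direction="sideways")
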