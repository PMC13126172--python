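"""Unit and property tests for the binding isotherm and its MCMC fit."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.optimize import brentq

import lamella as lm
from lamella.binding import DilutionSchedule
from lamella.synthetic import standard_titration_schedule
from lamella.types import BindingParameters, ValidationError

PARAMS = BindingParameters(kd=11.2e-6, n_lipids=19.0, nmre_max=14.7)


def _oracle_fraction_bound(c_lt, c_pt, p):
    """Bisection on the mass-action balance, independent of the quadratic."""

    def balance(f):
        free_lipid = c_lt - p.n_lipids * f * c_pt
        return f * (p.kd + free_lipid / p.n_lipids) - free_lipid / p.n_lipids

    return brentq(balance, 0.0, 1.0, xtol=1e-14)


@given(
    c_lt=st.floats(min_value=1e-6, max_value=1e-2),
    c_pt=st.floats(min_value=1e-7, max_value=1e-4),
    kd=st.floats(min_value=1e-8, max_value=1e-3),
    n=st.floats(min_value=1.0, max_value=60.0),
)
def test_fraction_bound_matches_bisection_oracle(c_lt, c_pt, kd, n):
    p = BindingParameters(kd=kd, n_lipids=n, nmre_max=10.0)
    f = lm.fraction_bound(c_lt, c_pt, p)
    f_oracle = _oracle_fraction_bound(c_lt, c_pt, p)
    assert 0.0 <= f <= 1.0
    assert f == pytest.approx(f_oracle, abs=1e-9)


@given(c_pt=st.floats(min_value=1e-7, max_value=1e-4))
def test_fraction_bound_monotone_in_lipid(c_pt):
    lipids = np.logspace(-5, -2, 30)
    f = np.array([lm.fraction_bound(c, c_pt, PARAMS) for c in lipids])
    assert np.all(np.diff(f) >= -1e-12)


def test_fraction_bound_limits():
    assert lm.fraction_bound(0.0, 2e-5, PARAMS) == pytest.approx(0.0)
    f_sat = lm.fraction_bound(1.0, 2e-5, PARAMS)
    assert f_sat == pytest.approx(1.0, abs=1e-3)


def test_predict_nmre_endpoints():
    assert lm.predict_nmre(0.0, PARAMS) == pytest.approx(1.0)
    assert lm.predict_nmre(1.0, PARAMS) == pytest.approx(PARAMS.nmre_max)


def test_schedule_concentrations():
    sched = standard_titration_schedule()
    c_lt = sched.lipid_concs()
    c_pt = 20e-6 * sched.peptide_dilution_factors()
    assert len(c_lt) == 21          # zero-lipid point + 20 additions
    assert c_lt[0] == 0.0
    # first addition: 10 uL of 3 mM into 310 uL total
    assert c_lt[1] == pytest.approx(3e-3 * 10.0 / 310.0)
    # peptide dilutes monotonically
    assert np.all(np.diff(c_pt) < 0)
    assert c_pt[-1] == pytest.approx(20e-6 * 300.0 / 500.0)


def test_generate_titration_noiseless_on_model():
    curve, gt = lm.generate_titration(PARAMS, noise_sd=0.0, seed=1)
    for pt in curve.points:
        f = lm.fraction_bound(pt.lipid_conc, pt.peptide_conc, PARAMS)
        assert pt.nmre == pytest.approx(lm.predict_nmre(f, PARAMS), abs=1e-10)


def test_generate_titration_deterministic():
    c1, _ = lm.generate_titration(PARAMS, noise_sd=0.3, seed=7)
    c2, _ = lm.generate_titration(PARAMS, noise_sd=0.3, seed=7)
    assert [p.nmre for p in c1.points] == [p.nmre for p in c2.points]


def test_fit_binding_recovers_on_low_noise():
    curve, _ = lm.generate_titration(PARAMS, noise_sd=0.05, seed=3)
    post = lm.fit_binding(
        curve, sampler_settings=lm.SamplerSettings(n_walkers=16, n_steps=1500,
                                                   seed=4))
    assert set(post.medians) == {"kd", "n_lipids", "nmre_max", "noise_sd"}
    assert post.medians["kd"] == pytest.approx(PARAMS.kd, rel=1.0)
    assert post.medians["n_lipids"] == pytest.approx(PARAMS.n_lipids, rel=0.5)
    assert post.medians["nmre_max"] == pytest.approx(PARAMS.nmre_max, rel=0.1)
    lo, hi = post.ci68["nmre_max"]
    assert lo < post.medians["nmre_max"] < hi


def test_fit_binding_flags_no_binding():
    curve, _ = lm.generate_titration(
        BindingParameters(kd=1e-5, n_lipids=19.0, nmre_max=1.05),
        noise_sd=0.02, seed=5)
    post = lm.fit_binding(
        curve, sampler_settings=lm.SamplerSettings(n_walkers=16, n_steps=400,
                                                   seed=6))
    assert post.no_binding


def test_generate_titration_rejects_short_schedule():
    sched = DilutionSchedule(initial_volume=3e-4, step_volumes=[1e-5] * 2,
                             titrant_lipid_conc=3e-3)
    with pytest.raises(ValidationError):
        lm.generate_titration(PARAMS, lipid_schedule=sched, seed=0)
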