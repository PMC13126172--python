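"""Tests for phasing, Fourier synthesis, Gaussian fitting, and water math."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import lamella as lm
from lamella.profiles import ComponentSpec, component_structure_factors
from lamella.synthetic import ContrastComponent
from lamella.types import BilayerModel, StructureFactorSet, ValidationError


def _pair_model(center=1.87, fwhm=15.0, area=0.5, d=54.9):
    return BilayerModel(d=d, components=[
        ContrastComponent(name="label", center=center, fwhm=fwhm,
                          base_area=area, pair=True)])


# ---------------------------------------------------------------------------
# Fourier synthesis
# ---------------------------------------------------------------------------

@given(
    center=st.floats(min_value=0.0, max_value=20.0),
    fwhm=st.floats(min_value=5.0, max_value=20.0),
    area=st.floats(min_value=0.1, max_value=2.0),
)
def test_fourier_synthesis_matches_closed_form(center, fwhm, area):
    """Synthesized profile equals the truncated cosine series of the planted
    Gaussian pair, computed independently here."""
    d = 54.9
    model = _pair_model(center, fwhm, area, d)
    sf = lm.forward_structure_factors(model, hmax=5)
    sf = sf.copy_with(sds=np.full(5, 1e-9), signed=True)
    prof = lm.fourier_synthesis(sf, n_grid=256)
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    expected = np.zeros_like(prof.z)
    for h in range(1, 6):
        F = (2.0 * area * np.cos(2 * np.pi * h * center / d)
             * np.exp(-2 * np.pi ** 2 * h ** 2 * sigma ** 2 / d ** 2))
        expected += (2.0 / d) * F * np.cos(2 * np.pi * h * prof.z / d)
    np.testing.assert_allclose(prof.rho, expected, atol=1e-10)


def test_fourier_synthesis_even_symmetry():
    model = lm.default_bilayer_model()
    sf = lm.forward_structure_factors(model, hmax=5)
    sf = sf.copy_with(sds=np.full(5, 1e-9), signed=True)
    prof = lm.fourier_synthesis(sf, n_grid=257)
    mid = np.isclose(prof.z, 0.0)
    assert mid.any()
    rho = prof.rho
    np.testing.assert_allclose(rho, rho[::-1], atol=1e-10)


def test_fourier_synthesis_requires_signed():
    model = lm.default_bilayer_model()
    sf = lm.forward_structure_factors(model, hmax=5)
    sf = sf.copy_with(amplitudes=np.abs(sf.amplitudes), signed=False)
    with pytest.raises(ValidationError):
        lm.fourier_synthesis(sf)


# ---------------------------------------------------------------------------
# Phasing
# ---------------------------------------------------------------------------

@settings(max_examples=15)
@given(seed=st.integers(min_value=0, max_value=10 ** 6))
def test_phasing_recovers_planted_signs_water_axis(seed):
    """Signs recovered on every well-determined order.

    Orders lying near a node of the contrast line (amplitude comparable to
    its uncertainty) have genuinely undetermined signs, so the check is
    restricted to amplitudes above 10 sd."""
    model = lm.default_bilayer_model()
    series, gt = lm.generate_contrast_series(
        model, x_list=(0.0, 0.5, 1.0), d7_list=(0.0,),
        noise_level=0.02, noise_floor_frac=0.002, seed=seed)
    result = lm.phase_by_contrast(series, axis="d2o")
    truth = gt.structure_factors["per_set"]
    for s in result.sets:
        key = f"x={s.d2o_fraction:g},d7={s.d7_fraction:g}"
        t_signs = np.array(truth[key]["signs"])
        t_F = np.array(truth[key]["F"])
        meaningful = np.abs(t_F) > 10.0 * s.sds
        got = np.sign(s.amplitudes)
        assert np.all(got[meaningful] == t_signs[meaningful])


def test_phasing_needs_multiple_contrasts():
    model = lm.default_bilayer_model()
    series, _ = lm.generate_contrast_series(model, x_list=(0.0,),
                                            d7_list=(0.0,), seed=0)
    with pytest.raises(ValidationError):
        lm.phase_by_contrast(series, axis="d2o")


# ---------------------------------------------------------------------------
# Difference profiles
# ---------------------------------------------------------------------------

def test_deuterium_difference_is_pointwise_subtraction():
    model = lm.default_bilayer_model()
    a = lm.forward_structure_factors(model, hmax=5, d2o_fraction=1.0)
    b = lm.forward_structure_factors(model, hmax=5, d2o_fraction=0.0)
    a = a.copy_with(sds=np.full(5, 1e-9), signed=True)
    b = b.copy_with(sds=np.full(5, 1e-9), signed=True)
    pa, pb = lm.fourier_synthesis(a), lm.fourier_synthesis(b)
    diff = lm.deuterium_difference(pa, pb)
    np.testing.assert_allclose(diff.rho, pa.rho - pb.rho, atol=1e-12)
    np.testing.assert_allclose(diff.amplitudes, a.amplitudes - b.amplitudes,
                               atol=1e-12)


def test_deuterium_difference_rejects_mismatched_cells():
    m1 = lm.default_bilayer_model(d=54.9)
    m2 = lm.default_bilayer_model(d=50.0)
    a = lm.forward_structure_factors(m1, hmax=5).copy_with(
        sds=np.full(5, 1e-9), signed=True)
    b = lm.forward_structure_factors(m2, hmax=5).copy_with(
        sds=np.full(5, 1e-9), signed=True)
    with pytest.raises(ValidationError):
        lm.deuterium_difference(lm.fourier_synthesis(a), lm.fourier_synthesis(b))


# ---------------------------------------------------------------------------
# Gaussian component fitting
# ---------------------------------------------------------------------------

def test_pair_fit_exact_on_noiseless_data():
    model = _pair_model()
    sf = lm.forward_structure_factors(model, hmax=5)
    sf = sf.copy_with(sds=0.02 * np.abs(sf.amplitudes), signed=True)
    prof = lm.fourier_synthesis(sf)
    comps, info = lm.fit_gaussian_components(
        prof, [ComponentSpec(center=3.0, fwhm=10.0, area=0.3,
                             pair_constraint=True)])
    assert info["f_space"]
    assert abs(comps[0].center) == pytest.approx(1.87, abs=1e-3)
    assert comps[0].fwhm == pytest.approx(15.0, abs=1e-3)
    assert comps[0].total_area() == pytest.approx(2 * 0.5, rel=1e-3)


def test_component_structure_factors_roundtrip():
    """Closed-form transform of the fitted components reproduces the data."""
    model = _pair_model()
    sf = lm.forward_structure_factors(model, hmax=5)
    sfn = sf.copy_with(sds=0.02 * np.abs(sf.amplitudes), signed=True)
    prof = lm.fourier_synthesis(sfn)
    comps, _ = lm.fit_gaussian_components(
        prof, [ComponentSpec(center=3.0, fwhm=10.0, area=0.3,
                             pair_constraint=True)])
    F_fit = component_structure_factors(comps, 54.9, np.arange(1, 6))
    np.testing.assert_allclose(F_fit, sf.amplitudes, rtol=1e-6, atol=1e-9)


# ---------------------------------------------------------------------------
# Monte-Carlo resampling
# ---------------------------------------------------------------------------

def test_mc_resample_zero_sds_gives_zero_spread():
    model = _pair_model()
    sf = lm.forward_structure_factors(model, hmax=5)
    sf = sf.copy_with(sds=np.full(5, 1e-9), signed=True)

    def downstream(mock):
        prof = lm.fourier_synthesis(mock)
        comps, _ = lm.fit_gaussian_components(
            prof, [ComponentSpec(center=3.0, fwhm=10.0, area=0.3,
                                 pair_constraint=True)],
            weights=np.ones(prof.z.size))
        return {"center": abs(comps[0].center)}

    out = lm.mc_resample(sf, downstream, n_mock=20, seed=0)
    assert not out["flagged"]
    assert out["params"]["center"]["sd"] == pytest.approx(0.0, abs=1e-6)
    assert out["params"]["center"]["mean"] == pytest.approx(1.87, abs=1e-3)


def test_mc_resample_flags_failing_downstream():
    model = _pair_model()
    sf = lm.forward_structure_factors(model, hmax=5)
    sf = sf.copy_with(sds=0.05 * np.abs(sf.amplitudes), signed=True)

    def downstream(mock):
        raise RuntimeError("always fails")

    out = lm.mc_resample(sf, downstream, n_mock=10, seed=0)
    assert out["flagged"]


# ---------------------------------------------------------------------------
# Calibration and water accounting
# ---------------------------------------------------------------------------

def test_calibrate_amplitude_exact_on_noiseless_difference():
    model = _pair_model(area=5.0 * 7.0 * lm.DELTA_B / 2.0)  # pair halves
    # difference profile carrying exactly label_fraction*7*delta_b per lipid
    sf = lm.forward_structure_factors(model, hmax=5)
    sf = sf.copy_with(sds=np.full(5, 1e-9), signed=True)
    prof = lm.fourier_synthesis(sf)
    scale, info = lm.calibrate_amplitude(prof, label_fraction=5.0,
                                         n_bias_correct=0)
    assert scale == pytest.approx(1.0, rel=1e-4)


def test_waters_per_peptide_closed_form():
    q = lm.WaterQuantification(waters_per_lipid_baseline=9.4,
                               exchangeable_protons_per_peptide=57.0,
                               peptide_per_lipid=0.04)
    w_p = 114.0
    B = lm.DELTA_B * (2 * 0.04 * w_p + 57.0 * 0.04 + 2 * 9.4)
    out = lm.waters_per_peptide(B, x=1.0, quant=q)
    assert out.waters_per_peptide == pytest.approx(w_p, rel=1e-12)
    assert not out.flagged_negative


@given(b_scale=st.floats(min_value=0.5, max_value=2.0),
       x=st.floats(min_value=0.25, max_value=1.0))
def test_waters_per_peptide_linear_in_integral_over_x(b_scale, x):
    q = lm.WaterQuantification(peptide_per_lipid=0.04)
    B0 = lm.DELTA_B * 30.0
    out1 = lm.waters_per_peptide(B0 * b_scale * x, x=x, quant=q)
    out2 = lm.waters_per_peptide(B0 * b_scale, x=1.0, quant=q)
    assert out1.waters_per_peptide == pytest.approx(out2.waters_per_peptide,
                                                    rel=1e-9)


def test_waters_per_peptide_flags_negative():
    q = lm.WaterQuantification(peptide_per_lipid=0.04)
    out = lm.waters_per_peptide(1e-6, x=1.0, quant=q)
    assert out.flagged_negative


def test_percent_thinning_arithmetic():
    assert lm.percent_thinning(30.44, 3.68) == pytest.approx(12.0, abs=0.1)
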