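"""Tests for the forward simulators and their ground-truth audits."""

import json

import numpy as np
import pytest
from scipy.integrate import quad

import lamella as lm
from lamella.profiles import component_structure_factors
from lamella.synthetic import ContrastComponent
from lamella.types import BilayerModel, BindingParameters

PARAMS = BindingParameters(kd=11.2e-6, n_lipids=19.0, nmre_max=14.7)


# ---------------------------------------------------------------------------
# Determinism
# ---------------------------------------------------------------------------

def test_generators_deterministic():
    c1, _ = lm.generate_titration(PARAMS, seed=3)
    c2, _ = lm.generate_titration(PARAMS, seed=3)
    assert [p.nmre for p in c1.points] == [p.nmre for p in c2.points]

    p1, _ = lm.generate_two_phase_pattern(58.6, 55.3, seed=3)
    p2, _ = lm.generate_two_phase_pattern(58.6, 55.3, seed=3)
    np.testing.assert_array_equal(p1.counts, p2.counts)

    s1, _ = lm.generate_contrast_series(lm.default_bilayer_model(), seed=3)
    s2, _ = lm.generate_contrast_series(lm.default_bilayer_model(), seed=3)
    for a, b in zip(s1.sets, s2.sets):
        np.testing.assert_array_equal(a.amplitudes, b.amplitudes)

    f1, _ = lm.generate_hydration_frames([3.0, 5.0], [10, 20], seed=3)
    f2, _ = lm.generate_hydration_frames([3.0, 5.0], [10, 20], seed=3)
    np.testing.assert_array_equal(f1[0].water_positions,
                                  f2[0].water_positions)


# ---------------------------------------------------------------------------
# Ground-truth audits
# ---------------------------------------------------------------------------

def test_audit_files_record_planted_truth(tmp_path):
    audit = tmp_path / "audit.json"
    _, gt = lm.generate_titration(PARAMS, seed=1, audit_path=audit)
    rec = json.loads(audit.read_text())
    assert rec["binding"]["kd"] == pytest.approx(PARAMS.kd)
    assert rec["binding"]["n_lipids"] == pytest.approx(PARAMS.n_lipids)

    audit2 = tmp_path / "audit2.json"
    _, gt2 = lm.generate_two_phase_pattern(58.6, 55.3, seed=1,
                                           audit_path=audit2)
    rec2 = json.loads(audit2.read_text())
    assert sorted(rec2["lattices"]) == [55.3, 58.6]

    audit3 = tmp_path / "audit3.json"
    _, gt3 = lm.generate_contrast_series(lm.default_bilayer_model(), seed=1,
                                         audit_path=audit3)
    rec3 = json.loads(audit3.read_text())
    assert "per_set" in rec3["structure_factors"]
    assert rec3["water_per_peptide"] == pytest.approx(gt3.water_per_peptide)


# ---------------------------------------------------------------------------
# Forward model correctness
# ---------------------------------------------------------------------------

def test_forward_structure_factors_match_quadrature():
    """Closed-form F(h) equals direct numerical integration of the planted
    density over the unit cell."""
    model = BilayerModel(d=54.9, components=[
        ContrastComponent(name="a", center=20.0, fwhm=9.0, base_area=1.2,
                          pair=True),
        ContrastComponent(name="b", center=0.0, fwhm=12.0, base_area=-0.6,
                          pair=False)])
    sf = lm.forward_structure_factors(model, hmax=5)
    comps = [c.at_contrast(0.0, 0.0) for c in model.components]

    def rho(z):
        total = 0.0
        for c in comps:
            sigma = c.fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
            amp = c.area / (sigma * np.sqrt(2.0 * np.pi))
            if c.pair_constraint:
                total += amp * (np.exp(-((z - c.center) ** 2) / (2 * sigma ** 2))
                                + np.exp(-((z + c.center) ** 2) / (2 * sigma ** 2)))
            else:
                total += amp * np.exp(-((z - c.center) ** 2) / (2 * sigma ** 2))
        return total

    # integrate over the full line: equivalent to integrating the
    # periodized (wrapped) density over one unit cell, since the cosine
    # kernel has period d
    d = model.d
    for h, F in zip(sf.orders, sf.amplitudes):
        val, _ = quad(lambda z: rho(z) * np.cos(2 * np.pi * h * z / d),
                      -np.inf, np.inf, limit=400)
        assert F == pytest.approx(val, rel=1e-4, abs=1e-8)


def test_render_pattern_zero_amplitudes_is_pure_background():
    sf = lm.forward_structure_factors(lm.default_bilayer_model(), hmax=3)
    sf = sf.copy_with(amplitudes=np.zeros(3), sds=np.full(3, 1e-9))
    pattern = lm.render_pattern(sf, background=25.0, total_counts=1e5, seed=0)
    assert len(lm.detect_peaks(pattern)) == 0
    # Poisson background around the flat level
    assert float(np.mean(pattern.counts)) == pytest.approx(25.0, rel=0.1)


def test_render_pattern_peak_positions():
    model = lm.default_bilayer_model(d=54.9)
    sf = lm.forward_structure_factors(model, hmax=4)
    pattern = lm.render_pattern(sf, total_counts=1e6, seed=1)
    peaks = lm.detect_peaks(pattern)
    expected = 2 * np.pi * np.arange(1, 5) / 54.9
    got = sorted(p.center_q for p in peaks)
    assert len(got) == 4
    np.testing.assert_allclose(got, expected, atol=0.002)


def test_contrast_series_planted_water_count():
    """The default model's audit reports the planted waters per peptide used
    by the acceptance chain."""
    _, gt = lm.generate_contrast_series(lm.default_bilayer_model(), seed=0)
    assert gt.water_per_peptide == pytest.approx(114.0, abs=0.5)


def test_contrast_series_label_axis_scales_with_d7():
    """The labelled-minus-base difference amplitudes scale linearly in the
    deuteration fraction."""
    model = lm.default_bilayer_model()
    base = lm.forward_structure_factors(model, hmax=5, d7_fraction=0.0)
    half = lm.forward_structure_factors(model, hmax=5, d7_fraction=0.5)
    full = lm.forward_structure_factors(model, hmax=5, d7_fraction=1.0)
    np.testing.assert_allclose(half.amplitudes - base.amplitudes,
                               0.5 * (full.amplitudes - base.amplitudes),
                               rtol=1e-10, atol=1e-14)
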