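"""Forward simulation of every input the analysis stages consume.

Each generator plants known ground truth (binding parameters, lattices,
component distributions, water counts, shell radii), records it in a
:class:`~lamella.types.GroundTruth` audit structure (optionally written to a
JSON file), and emits data in exactly the containers/formats the analysis
modules read.  All generators are bit-reproducible under a fixed seed.

The default bilayer model is a plausible fluid-PC anatomy — mirrored
headgroup maxima near ±20 Å, a terminal-methyl trough at the center, an
inter-bilayer water envelope at the cell boundary whose amplitude grows
linearly with the 2H2O fraction, an acyl-terminus label distribution and a
buried peptide envelope carrying the exchangeable-proton response.  The
shapes are test fixtures, not structural claims.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .binding import DilutionSchedule, fraction_bound
from .profiles import component_structure_factors
from .types import (
    DELTA_B,
    BilayerModel,
    BindingParameters,
    ContrastSeries,
    CoordinateFrame,
    DiffractionPattern,
    GaussianComponent,
    GroundTruth,
    StructureFactorSet,
    TitrationCurve,
    TitrationPoint,
    ValidationError,
    _require,
)

__all__ = [
    "ContrastComponent",
    "default_bilayer_model",
    "standard_titration_schedule",
    "generate_titration",
    "forward_structure_factors",
    "render_pattern",
    "generate_contrast_series",
    "generate_two_phase_pattern",
    "generate_hydration_frames",
    "write_audit",
    "BINDING_PRESETS",
]

#: CD-fit ground truths used as planting presets (K_D mol/L, n, nMRE_max)
BINDING_PRESETS = {
    "POPC": BindingParameters(kd=11.2e-6, n_lipids=19.0, nmre_max=14.7),
    "POPC/POPS": BindingParameters(kd=1.9e-6, n_lipids=25.0, nmre_max=13.0),
    "POPC/POPS/CHOL": BindingParameters(kd=7.5e-6, n_lipids=23.0, nmre_max=8.4),
}


def write_audit(truth: GroundTruth, path) -> None:
    Path(path).write_text(json.dumps(truth.to_dict(), indent=2, default=float))


# ---------------------------------------------------------------------------
# Titration curves
# ---------------------------------------------------------------------------

def standard_titration_schedule(titrant_lipid_conc: float = 3e-3,
                             initial_volume: float = 300e-6,
                             n_steps: int = 20,
                             step_volume: float = 10e-6) -> DilutionSchedule:
    """The standard automated titration: 300 µL of peptide solution receiving
    20 additions of 10 µL of 3 mmol/L SUVs (P/L spanning ~1:5 to 1:100 for a
    20 µmol/L peptide)."""
    return DilutionSchedule(initial_volume=initial_volume,
                            step_volumes=[step_volume] * n_steps,
                            titrant_lipid_conc=titrant_lipid_conc)


def generate_titration(truth: BindingParameters, c_pt: float = 20e-6,
                       lipid_schedule: Optional[DilutionSchedule] = None,
                       noise_sd: float = 0.3, seed: int = 0,
                       composition_label: str = "",
                       audit_path=None) -> tuple[TitrationCurve, GroundTruth]:
    """nMRE-vs-lipid curve from the forward binding model plus Gaussian noise."""
    sched = lipid_schedule or standard_titration_schedule()
    _require(len(sched.step_volumes) >= 5, "schedule must cover at least 6 points")
    rng = np.random.default_rng(seed)
    factors = sched.peptide_dilution_factors()
    lipids = sched.lipid_concs()
    points = []
    for cl, f in zip(lipids, factors):
        cpt_i = c_pt * f
        fb = fraction_bound(cl, cpt_i, truth) if cl > 0 else 0.0
        nmre = 1.0 + fb * (truth.nmre_max - 1.0) + rng.normal(0.0, noise_sd)
        points.append(TitrationPoint(lipid_conc=float(cl), nmre=float(nmre),
                                     peptide_conc=float(cpt_i)))
    curve = TitrationCurve(peptide_conc=c_pt, points=points,
                           composition_label=composition_label)
    gt = GroundTruth(seed=seed,
                     binding={"kd": truth.kd, "n_lipids": truth.n_lipids,
                              "nmre_max": truth.nmre_max, "noise_sd": noise_sd,
                              "c_pt": c_pt})
    if audit_path is not None:
        write_audit(gt, audit_path)
    return curve, gt


# ---------------------------------------------------------------------------
# Bilayer model and structure factors
# ---------------------------------------------------------------------------

@dataclass
class ContrastComponent:
    """A Gaussian profile component with linear contrast response.

    Effective area = base_area + x*x_coeff + d7*d7_coeff, where x is the
    2H2O mole fraction and d7 the labeled-lipid mole fraction.  Areas are in
    Å of scattering length per lipid; ``pair`` doubles the density (mirrored
    members at ±center, each of the effective area).
    """

    name: str
    center: float
    fwhm: float
    base_area: float
    x_coeff: float = 0.0
    d7_coeff: float = 0.0
    pair: bool = False

    def at_contrast(self, x: float, d7: float) -> GaussianComponent:
        return GaussianComponent(center=self.center, fwhm=self.fwhm,
                                 area=self.base_area + x * self.x_coeff + d7 * self.d7_coeff,
                                 pair_constraint=self.pair)


def default_bilayer_model(d: float = 54.9,
                          water_per_peptide: float = 114.0,
                          peptide_per_lipid: float = 1.0 / 25.0,
                          waters_per_lipid: float = 9.4,
                          exchangeable_protons: float = 57.0,
                          label_center: float = 1.87,
                          label_fwhm: float = 15.0,
                          delta_b: float = DELTA_B) -> BilayerModel:
    """Fluid-PC bilayer fixture with physically pinned contrast responses.

    The x-response of the water envelope is 2 protons per water over the
    baseline headgroup hydration plus the peptide-recruited pool; the
    peptide envelope carries the exchangeable-proton response; the label
    pair carries 7 deuterons per labeled lipid.
    """
    r = peptide_per_lipid
    water_protons = 2.0 * (waters_per_lipid + water_per_peptide * r)
    comps = [
        ContrastComponent("headgroups", center=20.0, fwhm=9.0,
                          base_area=4.0e-4, pair=True),
        ContrastComponent("methyl_trough", center=0.0, fwhm=10.0,
                          base_area=-5.0e-4),
        ContrastComponent("label", center=label_center, fwhm=label_fwhm,
                          base_area=0.0, d7_coeff=7.0 * delta_b / 2.0, pair=True),
        ContrastComponent("water", center=d / 2.0, fwhm=14.0,
                          base_area=0.0, x_coeff=water_protons * delta_b),
        ContrastComponent("peptide", center=0.0, fwhm=12.0,
                          base_area=2.0e-4 * (r / 0.04),
                          x_coeff=exchangeable_protons * r * delta_b),
    ]
    return BilayerModel(d=d, components=comps, metadata={
        "water_per_peptide": water_per_peptide,
        "peptide_per_lipid": peptide_per_lipid,
        "waters_per_lipid": waters_per_lipid,
        "exchangeable_protons": exchangeable_protons})


def forward_structure_factors(model: BilayerModel, hmax: int = 5,
                              d2o_fraction: float = 0.0,
                              d7_fraction: float = 0.0,
                              scale: float = 1.0,
                              sds: Optional[np.ndarray] = None,
                              ) -> StructureFactorSet:
    """Exact signed F(h), h = 1..hmax, from the closed-form cosine transform."""
    orders = np.arange(1, hmax + 1)
    comps = [c.at_contrast(d2o_fraction, d7_fraction) for c in model.components]
    F = scale * component_structure_factors(comps, model.d, orders)
    if sds is None:
        sds = np.full(hmax, max(1e-12, 1e-9 * float(np.max(np.abs(F)) or 1.0)))
    return StructureFactorSet(d=model.d, orders=orders, amplitudes=F,
                              sds=np.asarray(sds, float), d2o_fraction=d2o_fraction,
                              d7_fraction=d7_fraction, signed=True)


# ---------------------------------------------------------------------------
# Pattern rendering
# ---------------------------------------------------------------------------

def render_pattern(signed_set: StructureFactorSet, wavelength: float = 5.0,
                   peak_fwhm_q: float = 0.005, background: float = 20.0,
                   total_counts: float = 2e5, seed: Optional[int] = 0,
                   q_range: Optional[tuple[float, float]] = None,
                   n_bins: int = 3000) -> DiffractionPattern:
    """Render |F(h)|^2 Bragg peaks on a constant background, Poisson sampled.

    ``total_counts`` is the expected number of counts integrated over all
    peaks (excluding background); ``seed=None`` returns the noise-free
    analytic curve.
    """
    _require(peak_fwhm_q > 0 and total_counts > 0, "widths and counts must be positive")
    d = signed_set.d
    q_h = 2.0 * np.pi * signed_set.orders / d
    if q_range is None:
        q_range = (max(q_h.min() - 20 * peak_fwhm_q, peak_fwhm_q),
                   q_h.max() + 20 * peak_fwhm_q)
    q = np.linspace(q_range[0], q_range[1], n_bins)
    sigma = peak_fwhm_q / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    intens = np.zeros_like(q)
    weights = signed_set.amplitudes ** 2
    total_w = weights.sum() or 1.0
    for qc, w in zip(q_h, weights):
        intens += (w / total_w) * np.exp(-0.5 * ((q - qc) / sigma) ** 2) \
            / (sigma * np.sqrt(2 * np.pi))
    dq = q[1] - q[0]
    intens = total_counts * intens * dq + background
    if seed is not None:
        rng = np.random.default_rng(seed)
        counts = rng.poisson(intens).astype(float)
    else:
        counts = intens
    return DiffractionPattern(q=q, counts=counts, wavelength=wavelength,
                              metadata={"d_true": d})


def generate_two_phase_pattern(d1: float, d2: float, weight: float = 0.5,
                               hmax: int = 5, peak_fwhm_q: float = 0.005,
                               background: float = 20.0,
                               total_counts: float = 2e6, seed: int = 0,
                               audit_path=None,
                               ) -> tuple[DiffractionPattern, GroundTruth]:
    """Superposition of two rendered lamellar lattices (weight on lattice 1)."""
    _require(0.0 <= weight <= 1.0, "weight must lie in [0, 1]")
    sets = []
    for d in (d1, d2):
        m = default_bilayer_model(d=d)
        sets.append(forward_structure_factors(m, hmax=hmax))
    qmax = 2.0 * np.pi * hmax / min(d1, d2) + 20 * peak_fwhm_q
    qmin = 2.0 * np.pi / max(d1, d2) - 20 * peak_fwhm_q
    pats = []
    for i, (s, w) in enumerate(zip(sets, (weight, 1.0 - weight))):
        if w == 0:
            continue
        pats.append(render_pattern(s, peak_fwhm_q=peak_fwhm_q, background=0.0,
                                   total_counts=total_counts * w, seed=None,
                                   q_range=(qmin, qmax)))
    q = pats[0].q
    intens = sum(p.counts for p in pats) + background
    rng = np.random.default_rng(seed)
    counts = rng.poisson(intens).astype(float)
    pattern = DiffractionPattern(q=q, counts=counts, wavelength=1.54,
                                 metadata={"d1": d1, "d2": d2, "weight": weight})
    gt = GroundTruth(seed=seed, lattices=[d1, d2] if weight not in (0.0, 1.0)
                     else [d1 if weight else d2],
                     extra={"weight": weight, "degenerate": abs(d1 - d2) < 1e-9})
    if audit_path is not None:
        write_audit(gt, audit_path)
    return pattern, gt


# ---------------------------------------------------------------------------
# Contrast series
# ---------------------------------------------------------------------------

def generate_contrast_series(model: BilayerModel,
                             x_list: Sequence[float] = (0.0, 0.5, 1.0),
                             d7_list: Sequence[float] = (0.0,),
                             noise_level: float = 0.05,
                             hmax: int = 5, seed: int = 0,
                             instrument_scale: float = 1000.0,
                             peptide_per_lipid: float = 1.0 / 25.0,
                             noise_floor_frac: float = 0.01,
                             audit_path=None,
                             ) -> tuple[ContrastSeries, GroundTruth]:
    """Unsigned, noised structure-factor sets over water and label contrasts.

    Produces one set per x in ``x_list`` at the base label fraction, plus one
    per additional label fraction at the first x.  Amplitudes carry an
    arbitrary common instrument scale (recoverable only via the d7
    calibration); true signed F and signs are logged to the audit record.
    """
    rng = np.random.default_rng(seed)
    combos = [(x, d7_list[0]) for x in x_list] + \
             [(x_list[0], d7) for d7 in d7_list[1:]]
    sets, truth_F = [], {}
    for x, d7 in combos:
        exact = forward_structure_factors(model, hmax=hmax, d2o_fraction=x,
                                          d7_fraction=d7, scale=instrument_scale)
        F = exact.amplitudes
        floor = noise_floor_frac * float(np.max(np.abs(F)))
        sds = noise_level * np.abs(F) + floor
        noisy = F + rng.normal(0.0, sds)
        sets.append(StructureFactorSet(
            d=model.d, orders=exact.orders, amplitudes=np.abs(noisy), sds=sds,
            d2o_fraction=x, d7_fraction=d7, signed=False,
            label=f"x={x:g},d7={d7:g}"))
        truth_F[f"x={x:g},d7={d7:g}"] = {
            "F": F.tolist(), "signs": np.sign(F).tolist()}
    series = ContrastSeries(sets=sets, peptide_per_lipid=peptide_per_lipid)
    gt = GroundTruth(seed=seed,
                     structure_factors={"instrument_scale": instrument_scale,
                                        "per_set": truth_F, "d": model.d,
                                        "hmax": hmax},
                     water_per_peptide=model.metadata.get("water_per_peptide"),
                     extra={"components": [dataclasses.asdict(c) for c in model.components]})
    if audit_path is not None:
        write_audit(gt, audit_path)
    return series, gt


# ---------------------------------------------------------------------------
# Hydration frames
# ---------------------------------------------------------------------------

def generate_hydration_frames(shell_radii: Sequence[float],
                              shell_counts: Sequence[int],
                              jitter: float = 0.1, n_frames: int = 5,
                              seed: int = 0,
                              n_background: int = 0,
                              background_extent: float = 15.0,
                              audit_path=None,
                              ) -> tuple[list[CoordinateFrame], GroundTruth]:
    """Waters planted on spherical shells around a point solute at the origin.

    Angular placement is uniform on each sphere; radial jitter is Gaussian.
    Optional uniform background waters fill a cube of half-width
    ``background_extent`` (excluding the planted-shell region is not
    attempted — background is a large-r ideal-gas bath for g(r) -> 1 tests).
    """
    _require(len(shell_radii) == len(shell_counts), "radii and counts must align")
    _require(all(b > a for a, b in zip(shell_radii, shell_radii[1:])),
             "shell radii must be strictly increasing")
    rng = np.random.default_rng(seed)
    frames = []
    for fid in range(n_frames):
        pts = []
        for radius, count in zip(shell_radii, shell_counts):
            v = rng.normal(size=(count, 3))
            v /= np.linalg.norm(v, axis=1, keepdims=True)
            rr = radius + rng.normal(0.0, jitter, size=(count, 1)) if jitter > 0 \
                else np.full((count, 1), radius)
            pts.append(v * rr)
        if n_background:
            pts.append(rng.uniform(-background_extent, background_extent,
                                   size=(n_background, 3)))
        frames.append(CoordinateFrame(solute_positions=np.zeros((1, 3)),
                                      water_positions=np.vstack(pts),
                                      frame_id=fid))
    gt = GroundTruth(seed=seed,
                     shells={"radii": list(map(float, shell_radii)),
                             "counts": list(map(int, shell_counts)),
                             "jitter": jitter, "n_frames": n_frames,
                             "n_background": n_background})
    if audit_path is not None:
        write_audit(gt, audit_path)
    return frames, gt
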