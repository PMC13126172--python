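"""Domain containers shared across the analysis stages.

Concentrations are mol/L internally, lengths are Å, scattering lengths are Å.
All containers are plain dataclasses; stages communicate only through them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

# Neutron coherent scattering lengths (Å)
B_DEUTERIUM = 6.67e-5
B_HYDROGEN = -3.74e-5
#: scattering-length gain per H→D exchange (Å)
DELTA_B = B_DEUTERIUM - B_HYDROGEN  # 1.041e-4


class ValidationError(ValueError):
    """Raised when a container or operation input violates its contract."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValidationError(msg)


# ---------------------------------------------------------------------------
# Binding isotherm
# ---------------------------------------------------------------------------

@dataclass
class TitrationPoint:
    """One step of a lipid-into-peptide CD titration.

    ``peptide_conc`` may differ per point because each titrant addition
    dilutes the peptide; when None the curve-level concentration applies.
    """

    lipid_conc: float           # mol/L total lipid (free + bound)
    mre222: float = np.nan      # deg·cm²/dmol at 222 nm
    nmre: float = np.nan        # normalized MRE (buffer baseline = 1)
    peptide_conc: Optional[float] = None

    def __post_init__(self) -> None:
        _require(self.lipid_conc >= 0, f"lipid_conc must be >= 0, got {self.lipid_conc}")
        if self.peptide_conc is not None:
            _require(self.peptide_conc > 0,
                     f"peptide_conc must be > 0, got {self.peptide_conc}")


@dataclass
class TitrationCurve:
    """An nMRE-vs-lipid binding curve at fixed (initial) peptide concentration."""

    peptide_conc: float                     # mol/L, before titrant dilution
    points: list[TitrationPoint] = field(default_factory=list)
    composition_label: str = ""
    nmre_min: float = 1.0                   # buffer baseline, fixed
    sign_warning: bool = False              # buffer reference/sample sign mismatch

    def __post_init__(self) -> None:
        _require(self.peptide_conc > 0, "peptide_conc must be > 0")
        _require(self.nmre_min == 1.0, "nmre_min is fixed to 1 by convention")
        lips = [p.lipid_conc for p in self.points]
        _require(all(b > a for a, b in zip(lips, lips[1:])),
                 "titration points must be strictly increasing in lipid_conc")

    @property
    def lipid_concs(self) -> np.ndarray:
        return np.array([p.lipid_conc for p in self.points])

    @property
    def peptide_concs(self) -> np.ndarray:
        return np.array([p.peptide_conc if p.peptide_conc is not None
                         else self.peptide_conc for p in self.points])

    @property
    def nmres(self) -> np.ndarray:
        return np.array([p.nmre for p in self.points])


@dataclass
class BindingParameters:
    """Modified-Langmuir parameters of the peptide–membrane equilibrium."""

    kd: float          # mol/L dissociation constant
    n_lipids: float    # lipids occluded per bound peptide
    nmre_max: float    # saturation nMRE (dimensionless, > 1)

    def __post_init__(self) -> None:
        _require(self.kd >= 0, f"kd must be >= 0, got {self.kd}")
        _require(self.n_lipids > 0, f"n_lipids must be > 0, got {self.n_lipids}")
        _require(self.nmre_max > 1, f"nmre_max must be > 1, got {self.nmre_max}")


@dataclass
class Posterior:
    """MCMC posterior summary for the binding fit.

    ``samples`` has one column per parameter in ``param_names``; rows are
    post-burn-in draws pooled over walkers.
    """

    param_names: list[str]
    samples: np.ndarray
    medians: dict[str, float]
    ci68: dict[str, tuple[float, float]]
    diagnostics: dict[str, float]
    converged: bool = True
    no_binding: bool = False

    def __post_init__(self) -> None:
        for name in self.param_names:
            lo, hi = self.ci68[name]
            m = self.medians[name]
            _require(lo <= m <= hi, f"ci68 must bracket the median for {name}")

    def summary(self) -> dict:
        """JSON-serializable summary (no raw samples)."""
        return {
            "medians": self.medians,
            "ci68": {k: list(v) for k, v in self.ci68.items()},
            "diagnostics": self.diagnostics,
            "converged": bool(self.converged),
            "no_binding": bool(self.no_binding),
        }


# ---------------------------------------------------------------------------
# Diffraction
# ---------------------------------------------------------------------------

@dataclass
class DiffractionPattern:
    """A 1-D specular diffraction trace, abscissa in Q (1/Å)."""

    q: np.ndarray               # strictly increasing, 1/Å
    counts: np.ndarray          # >= 0
    wavelength: float           # Å
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        _require(self.q.ndim == 1 and self.q.shape == self.counts.shape,
                 "q and counts must be matching 1-D arrays")
        _require(bool(np.all(np.diff(self.q) > 0)), "abscissa must be strictly increasing")
        _require(bool(np.all(self.counts >= 0)), "counts must be nonnegative")
        _require(self.wavelength > 0, "wavelength must be positive")


@dataclass
class BraggPeak:
    center_q: float
    height: float
    fwhm_q: float
    area: float
    order: Optional[int] = None
    center_sd: float = np.nan
    fwhm_sd: float = np.nan
    area_sd: float = np.nan

    def __post_init__(self) -> None:
        _require(self.center_q > 0, "center_q must be > 0")
        _require(self.fwhm_q > 0, "fwhm_q must be > 0")
        _require(self.area > 0, "area must be > 0")


@dataclass
class LatticeFit:
    """Repeat spacing from the weighted regression of Q_h on order h."""

    d: float                    # Å
    d_sd: float                 # Å
    orders_used: list[int]
    residuals: np.ndarray       # ΔQ per peak, 1/Å
    flagged_multilattice: bool = False

    def __post_init__(self) -> None:
        _require(self.d > 0, "repeat spacing must be positive")


@dataclass
class StructureFactorSet:
    """Bragg amplitudes F(h) with uncertainties and contrast metadata."""

    d: float                                    # Å repeat spacing
    orders: np.ndarray                          # h values, unique
    amplitudes: np.ndarray                      # |F| or signed F
    sds: np.ndarray
    d2o_fraction: float = 0.0                   # x, mole fraction 2H2O
    d7_fraction: float = 0.0                    # labeled-lipid mole fraction
    signed: bool = False
    label: str = ""
    ambiguous_phasing: bool = False

    def __post_init__(self) -> None:
        self.orders = np.asarray(self.orders, dtype=int)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        _require(self.d > 0, "d must be positive")
        _require(len(set(self.orders.tolist())) == len(self.orders),
                 "diffraction orders must be unique")
        _require(self.orders.shape == self.amplitudes.shape == self.sds.shape,
                 "orders, amplitudes and sds must align")
        _require(bool(np.all(self.sds > 0)), "sds must be positive")
        _require(0.0 <= self.d2o_fraction <= 1.0, "d2o_fraction must lie in [0, 1]")
        _require(0.0 <= self.d7_fraction <= 1.0, "d7_fraction must lie in [0, 1]")

    def copy_with(self, **kw) -> "StructureFactorSet":
        data = {
            "d": self.d, "orders": self.orders.copy(),
            "amplitudes": self.amplitudes.copy(), "sds": self.sds.copy(),
            "d2o_fraction": self.d2o_fraction, "d7_fraction": self.d7_fraction,
            "signed": self.signed, "label": self.label,
            "ambiguous_phasing": self.ambiguous_phasing,
        }
        data.update(kw)
        return StructureFactorSet(**data)


@dataclass
class ContrastSeries:
    """Structure-factor sets sharing d and h coverage across contrasts."""

    sets: list[StructureFactorSet]
    peptide_per_lipid: float = 0.0       # r, e.g. 1/25
    composition: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        _require(len(self.sets) >= 1, "a contrast series needs at least one set")
        d0 = self.sets[0].d
        h0 = self.sets[0].orders.tolist()
        for s in self.sets[1:]:
            _require(abs(s.d - d0) <= 1e-6 * d0, "all sets must share the repeat spacing d")
            _require(s.orders.tolist() == h0, "all sets must share the same order list")

    @property
    def d(self) -> float:
        return self.sets[0].d

    @property
    def orders(self) -> np.ndarray:
        return self.sets[0].orders


# ---------------------------------------------------------------------------
# SLD profiles
# ---------------------------------------------------------------------------

@dataclass
class SLDProfile:
    """Relative or calibrated scattering-length density along z on one period."""

    z: np.ndarray               # Å grid on [-d/2, d/2]
    rho: np.ndarray
    d: float
    hmax: int
    sd_band: Optional[np.ndarray] = None
    absolute_scale: bool = False
    # per-order Fourier data the profile was synthesized from, when known;
    # fits use these (with their individual sds) rather than the point grid
    orders: Optional[np.ndarray] = None
    amplitudes: Optional[np.ndarray] = None
    order_sds: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.rho = np.asarray(self.rho, dtype=float)
        _require(self.z.shape == self.rho.shape, "z and rho must align")
        if self.sd_band is not None:
            self.sd_band = np.asarray(self.sd_band, dtype=float)
            _require(self.sd_band.shape == self.rho.shape, "sd_band must align with rho")
        for name in ("orders", "amplitudes", "order_sds"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, np.asarray(v, dtype=float))
        if self.amplitudes is not None:
            _require(self.orders is not None
                     and self.orders.shape == self.amplitudes.shape,
                     "per-order amplitudes require matching orders")


@dataclass
class GaussianComponent:
    """One Gaussian component of a bilayer SLD profile.

    ``pair_constraint`` means the density carries mirrored copies at
    ±center, each of the given area (total 2·area); otherwise a single
    Gaussian at ``center`` (wrapped periodically at the cell boundary).
    """

    center: float               # Å, signed
    fwhm: float                 # Å
    area: float                 # SLD·Å (scattering length per lipid, when absolute)
    pair_constraint: bool = False
    center_sd: float = np.nan
    fwhm_sd: float = np.nan
    area_sd: float = np.nan

    def __post_init__(self) -> None:
        _require(self.fwhm > 0, "fwhm must be positive")

    @property
    def sigma(self) -> float:
        return self.fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))

    def total_area(self) -> float:
        return 2.0 * self.area if self.pair_constraint else self.area


@dataclass
class WaterQuantification:
    """Per-peptide water accounting from a calibrated exchange-difference profile."""

    waters_per_lipid_baseline: float = 9.4      # w_L, POPC at 93% RH
    exchangeable_protons_per_peptide: float = 57.0
    peptide_per_lipid: float = 1.0 / 25.0       # r
    delta_b: float = DELTA_B
    waters_per_peptide: float = np.nan          # w_P, result
    waters_per_peptide_sd: float = np.nan
    flagged_negative: bool = False
    inputs: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# Hydration shells
# ---------------------------------------------------------------------------

@dataclass
class CoordinateFrame:
    """Solute and water point positions for one analysis frame (Å)."""

    solute_positions: np.ndarray    # (Ns, 3)
    water_positions: np.ndarray     # (Nw, 3)
    frame_id: int = 0
    box: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.solute_positions = np.atleast_2d(np.asarray(self.solute_positions, dtype=float))
        self.water_positions = np.atleast_2d(np.asarray(self.water_positions, dtype=float))
        _require(self.solute_positions.shape[0] >= 1, "need at least one solute point")
        _require(self.water_positions.shape[0] >= 1, "need at least one water point")
        _require(bool(np.all(np.isfinite(self.solute_positions)))
                 and bool(np.all(np.isfinite(self.water_positions))),
                 "positions must be finite")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)


@dataclass
class ShellSummary:
    shell_index: int
    boundary_radius: float
    boundary_radius_sd: float
    water_count: float
    water_count_sd: float


# ---------------------------------------------------------------------------
# Synthetic ground truth
# ---------------------------------------------------------------------------

@dataclass
class BilayerModel:
    """Gaussian-component model of one centrosymmetric repeat unit.

    Component areas may respond linearly to the water-deuteration fraction x
    and the labeled-lipid fraction; see :mod:`lamella.synthetic`.
    """

    d: float
    components: list                  # of synthetic.ContrastComponent
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        _require(self.d > 0, "d must be positive")


@dataclass
class GroundTruth:
    """Audit record of every planted value behind a synthetic data set."""

    seed: Optional[int] = None
    binding: Optional[dict] = None
    lattices: Optional[list] = None
    structure_factors: Optional[dict] = None
    water_per_peptide: Optional[float] = None
    shells: Optional[dict] = None
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {k: v for k, v in asdict(self).items() if v not in (None, {})}
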