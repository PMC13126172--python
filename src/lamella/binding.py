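"""Modified-Langmuir CD binding isotherm and its MCMC posterior inference.

The model ties the fraction of peptide bound, ``f_b``, to the total lipid
concentration through

    C_Lt = n * f_b * [1 + K_D / (C_pt * (1 - f_b))] * C_pt

where ``C_pt`` is the total peptide concentration, ``K_D`` the dissociation
constant and ``n`` the number of lipids occluded per bound peptide.  The
measured observable is the normalized mean residue ellipticity at 222 nm,
linear in ``f_b``:  nMRE = 1 + f_b * (nMRE_max - 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import emcee
import numpy as np

from .types import (
    BindingParameters,
    Posterior,
    TitrationCurve,
    TitrationPoint,
    ValidationError,
    _require,
)

__all__ = [
    "fraction_bound",
    "predict_nmre",
    "mre_from_millidegrees",
    "normalize_curve",
    "fit_binding",
    "percent_helicity",
    "BindingPriors",
    "SamplerSettings",
    "HelicityBaselines",
]


def fraction_bound(c_lt, c_pt, params: BindingParameters):
    """Fraction of peptide bound at total lipid ``c_lt`` and peptide ``c_pt``.

    Multiplying the implicit relation through by (1 - f) gives the quadratic

        n*C_pt * f^2 - (n*C_pt + n*K_D + C_Lt) * f + C_Lt = 0.

    Its two roots multiply to C_Lt/(n*C_pt) > 0 and sum to
    1 + (n*K_D + C_Lt*(1 - 1/(n*C_pt)))... — more directly, evaluating the
    quadratic at f = 1 gives n*K_D >= 0 while its minimum lies below zero
    whenever C_Lt > 0, so the smaller root is the one in [0, 1]; the larger
    root exceeds 1 (or equals it only when K_D = 0 and lipid is saturating).
    We therefore always take the smaller root, in a numerically stable form.

    Accepts scalars or arrays for ``c_lt`` (and ``c_pt``).
    """
    c_lt = np.asarray(c_lt, dtype=float)
    c_pt = np.asarray(c_pt, dtype=float)
    if np.any(c_lt < 0):
        raise ValidationError(f"lipid_conc must be >= 0, got {c_lt}")
    if np.any(c_pt <= 0):
        raise ValidationError(f"peptide_conc must be > 0, got {c_pt}")

    a = params.n_lipids * c_pt
    b = params.n_lipids * c_pt + params.n_lipids * params.kd + c_lt
    c = c_lt
    disc = np.maximum(b * b - 4.0 * a * c, 0.0)
    # smaller root via the stable form 2c / (b + sqrt(disc))
    f = 2.0 * c / (b + np.sqrt(disc))
    f = np.clip(f, 0.0, 1.0)
    return float(f) if f.ndim == 0 else f


def predict_nmre(f_b, params: BindingParameters):
    """Normalized MRE from the bound fraction: nmre = 1 + f_b*(nmre_max - 1)."""
    f_b = np.asarray(f_b, dtype=float)
    if np.any((f_b < 0) | (f_b > 1)):
        raise ValidationError(f"f_b must lie in [0, 1], got {f_b}")
    out = 1.0 + f_b * (params.nmre_max - 1.0)
    return float(out) if out.ndim == 0 else out


def mre_from_millidegrees(theta_mdeg: float, path_length: float,
                          conc: float, n_residues: int) -> float:
    """Mean residue ellipticity (deg·cm²/dmol) from raw millidegrees.

    MRE = θ_mdeg / (10 · l[cm] · c[mol/L] · N_residues).
    """
    if path_length <= 0:
        raise ValidationError(f"path_length must be > 0, got {path_length}")
    if conc <= 0:
        raise ValidationError(f"conc must be > 0, got {conc}")
    if n_residues <= 0:
        raise ValidationError(f"n_residues must be > 0, got {n_residues}")
    return theta_mdeg / (10.0 * path_length * conc * n_residues)


@dataclass
class DilutionSchedule:
    """Cumulative-volume dilution bookkeeping for an automated titration."""

    initial_volume: float               # L (or any consistent volume unit)
    step_volumes: Sequence[float]       # titrant volume added at each step
    titrant_lipid_conc: float = 0.0     # mol/L lipid in the titrant

    def cumulative_volumes(self) -> np.ndarray:
        return self.initial_volume + np.cumsum(np.concatenate([[0.0], np.asarray(self.step_volumes, float)]))

    def peptide_dilution_factors(self) -> np.ndarray:
        """Peptide concentration scale per point (first point = 1)."""
        return self.initial_volume / self.cumulative_volumes()

    def lipid_concs(self) -> np.ndarray:
        """Total lipid concentration at each point (index 0 = before titrant)."""
        vols = self.cumulative_volumes()
        added = np.concatenate([[0.0], np.cumsum(np.asarray(self.step_volumes, float))])
        return self.titrant_lipid_conc * added / vols


def normalize_curve(raw_points: Sequence[tuple], buffer_mre222: float,
                    dilution_schedule: DilutionSchedule,
                    peptide_conc: float,
                    composition_label: str = "") -> TitrationCurve:
    """Build a TitrationCurve from raw per-step MRE values.

    ``raw_points`` is a sequence of mre222 values, one per point including the
    zero-lipid point.  Peptide and lipid concentrations are rescaled by the
    cumulative dilution factor; nmre = mre222 / buffer_mre222.
    """
    if buffer_mre222 == 0:
        raise ValidationError("buffer_mre222 must be nonzero")
    mres = np.asarray(raw_points, dtype=float)
    factors = dilution_schedule.peptide_dilution_factors()
    lipids = dilution_schedule.lipid_concs()
    _require(len(mres) == len(factors),
             "raw_points must have one value per schedule point (incl. zero-lipid)")
    sign_warning = bool(np.sign(np.nanmedian(mres)) * np.sign(buffer_mre222) < 0)
    points = [
        TitrationPoint(lipid_conc=float(cl), mre222=float(m),
                       nmre=float(m / buffer_mre222),
                       peptide_conc=float(peptide_conc * f))
        for cl, m, f in zip(lipids, mres, factors)
    ]
    curve = TitrationCurve(peptide_conc=peptide_conc, points=points,
                           composition_label=composition_label)
    curve.sign_warning = sign_warning
    return curve


# ---------------------------------------------------------------------------
# MCMC fit
# ---------------------------------------------------------------------------

@dataclass
class BindingPriors:
    """Prior bounds; K_D is sampled in log10 space (log-uniform)."""

    log10_kd: tuple[float, float] = (-9.0, -2.0)    # mol/L
    n_lipids: tuple[float, float] = (1.0, 200.0)
    nmre_max: tuple[float, float] = (1.0, 50.0)
    noise_sd_scale: float = 1.0                     # half-normal scale on noise SD


@dataclass
class SamplerSettings:
    n_walkers: int = 24
    n_steps: int = 2500
    burn_in: Optional[int] = None       # None -> autocorrelation heuristic
    seed: int = 0
    moves: str = "de"                   # differential-evolution ensemble moves
    rhat_threshold: float = 1.1
    min_signal: float = 0.5             # nMRE excursion below which "no binding"
    init: str = "auto"                  # "auto": least-squares-seeded walkers


_PARAM_NAMES = ["kd", "n_lipids", "nmre_max", "noise_sd"]


def _log_prob(theta: np.ndarray, c_lt: np.ndarray, c_pt: np.ndarray,
              nmre: np.ndarray, priors: BindingPriors) -> float:
    log10_kd, n_lip, nmre_max, log_noise = theta
    if not (priors.log10_kd[0] <= log10_kd <= priors.log10_kd[1]):
        return -np.inf
    if not (priors.n_lipids[0] <= n_lip <= priors.n_lipids[1]):
        return -np.inf
    if not (priors.nmre_max[0] < nmre_max <= priors.nmre_max[1]):
        return -np.inf
    noise = np.exp(log_noise)
    if not (1e-6 < noise < 100.0):
        return -np.inf
    params = BindingParameters.__new__(BindingParameters)
    params.kd = 10.0 ** log10_kd
    params.n_lipids = n_lip
    params.nmre_max = nmre_max
    f = fraction_bound(c_lt, c_pt, params)
    model = 1.0 + f * (nmre_max - 1.0)
    resid = nmre - model
    # Gaussian likelihood; half-normal prior on noise SD (flat in log + Jacobian)
    loglike = -0.5 * np.sum(resid ** 2) / noise ** 2 - len(resid) * np.log(noise)
    logprior = -0.5 * (noise / priors.noise_sd_scale) ** 2 + log_noise
    return loglike + logprior


def _ls_start(c_lt: np.ndarray, c_pt: np.ndarray, nmre: np.ndarray,
              priors: BindingPriors) -> Optional[np.ndarray]:
    """Cheap least-squares point estimate used only to seed the walkers."""
    from scipy.optimize import least_squares

    def resid(th):
        params = BindingParameters.__new__(BindingParameters)
        params.kd = 10.0 ** th[0]
        params.n_lipids = th[1]
        params.nmre_max = th[2]
        f = fraction_bound(c_lt, c_pt, params)
        return 1.0 + f * (th[2] - 1.0) - nmre

    lo = [priors.log10_kd[0], priors.n_lipids[0], priors.nmre_max[0] + 1e-6]
    hi = [priors.log10_kd[1], priors.n_lipids[1], priors.nmre_max[1]]
    try:
        res = least_squares(resid, [-5.3, 30.0, max(2.0, 0.8 * nmre.max())],
                            bounds=(lo, hi))
        noise = max(float(np.std(res.fun)), 1e-3)
        return np.array([res.x[0], res.x[1], res.x[2], np.log(noise)])
    except Exception:
        return None


def fit_binding(curve: TitrationCurve | Sequence[TitrationCurve],
                priors: Optional[BindingPriors] = None,
                sampler_settings: Optional[SamplerSettings] = None) -> Posterior:
    """Posterior over (K_D, n, nMRE_max, noise SD) by ensemble MCMC.

    Uses differential-evolution ensemble moves (an adaptive Metropolis scheme
    in the DREAM family) with a Gaussian likelihood on nMRE residuals of the
    quadratic-root forward model.  Deterministic for a fixed seed.

    ``curve`` may be a single TitrationCurve or a sequence of replicate
    curves sharing the same underlying parameters; replicates are pooled
    into one likelihood.
    """
    priors = priors or BindingPriors()
    st = sampler_settings or SamplerSettings()

    curves = [curve] if isinstance(curve, TitrationCurve) else list(curve)
    _require(len(curves) >= 1, "need at least one curve")
    for c in curves:
        _require(len(c.points) >= 6, "need at least 6 titration points")
        nz = c.lipid_concs[c.lipid_concs > 0]
        _require(nz.max() / nz.min() >= 4.0,
                 "titration must span at least a 4-fold lipid range")
    c_lt = np.concatenate([c.lipid_concs for c in curves])
    c_pt = np.concatenate([c.peptide_concs for c in curves])
    nmre = np.concatenate([c.nmres for c in curves])

    excursion = float(np.nanmax(np.abs(nmre - 1.0)))
    rng = np.random.default_rng(st.seed)

    ndim = 4
    nwalk = max(st.n_walkers, 3 * ndim)
    start = _ls_start(c_lt, c_pt, nmre, priors) if st.init == "auto" else None
    if start is not None and np.isfinite(_log_prob(start, c_lt, c_pt, nmre, priors)):
        # tight ball around the point estimate; burn-in erases the choice
        p0 = start + np.column_stack([
            rng.normal(0, 0.05, nwalk), rng.normal(0, 0.5, nwalk),
            rng.normal(0, 0.05, nwalk), rng.normal(0, 0.05, nwalk)])
        p0[:, 0] = np.clip(p0[:, 0], *priors.log10_kd)
        p0[:, 1] = np.clip(p0[:, 1], *priors.n_lipids)
        p0[:, 2] = np.clip(p0[:, 2], priors.nmre_max[0] + 1e-6, priors.nmre_max[1])
    else:
        # spread over the prior bulk
        p0 = np.column_stack([
            rng.uniform(priors.log10_kd[0] + 1, priors.log10_kd[1] - 0.5, nwalk),
            rng.uniform(5, 60, nwalk),
            rng.uniform(max(1.05, 0.5 * max(nmre.max(), 2.0)),
                        min(priors.nmre_max[1], 2.0 * max(nmre.max(), 2.0)), nwalk),
            np.log(rng.uniform(0.05, 1.0, nwalk)),
        ])

    moves = [(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)] \
        if st.moves == "de" else None
    sampler = emcee.EnsembleSampler(
        nwalk, ndim, _log_prob, args=(c_lt, c_pt, nmre, priors), moves=moves)
    sampler.random_state = np.random.RandomState(st.seed).get_state()
    sampler.run_mcmc(p0, st.n_steps, progress=False)

    if st.burn_in is None:
        try:
            tau = sampler.get_autocorr_time(quiet=True)
            burn = int(min(st.n_steps // 2, 5 * np.nanmax(tau)))
        except Exception:
            burn = st.n_steps // 3
    else:
        burn = st.burn_in
    chain = sampler.get_chain(discard=burn)          # (steps, walkers, ndim)
    flat = chain.reshape(-1, ndim)

    # split-chain potential scale reduction (Gelman–Rubin) on each parameter
    rhat = _split_rhat(chain)
    acc = float(np.mean(sampler.acceptance_fraction))

    # back-transform: kd from log10, noise from log
    samples = np.column_stack([
        10.0 ** flat[:, 0], flat[:, 1], flat[:, 2], np.exp(flat[:, 3])])
    medians = {n: float(np.median(samples[:, i])) for i, n in enumerate(_PARAM_NAMES)}
    ci68 = {n: (float(np.percentile(samples[:, i], 16)),
                float(np.percentile(samples[:, i], 84)))
            for i, n in enumerate(_PARAM_NAMES)}

    converged = bool(np.nanmax(rhat) < st.rhat_threshold)
    no_binding = excursion < st.min_signal
    return Posterior(
        param_names=list(_PARAM_NAMES), samples=samples, medians=medians,
        ci68=ci68,
        diagnostics={"acceptance_fraction": acc, "n_walkers": nwalk,
                     "burn_in": burn, "rhat_max": float(np.nanmax(rhat))},
        converged=converged, no_binding=no_binding)


def _split_rhat(chain: np.ndarray) -> np.ndarray:
    """Split-half Gelman–Rubin statistic per parameter; chain is (S, W, D)."""
    s = chain.shape[0] // 2
    halves = np.concatenate([chain[:s], chain[s:2 * s]], axis=1)  # (s, 2W, D)
    m = halves.shape[1]
    means = halves.mean(axis=0)                     # (2W, D)
    variances = halves.var(axis=0, ddof=1)
    w = variances.mean(axis=0)
    b = s * means.var(axis=0, ddof=1)
    var_hat = (s - 1) / s * w + b / s
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.sqrt(var_hat / w)


# ---------------------------------------------------------------------------
# Helicity
# ---------------------------------------------------------------------------

@dataclass
class HelicityBaselines:
    """Coil and full-helix MRE references at 222 nm.

    Defaults follow the chain-length-corrected helix limit
    ``-40000*(1 - 2.5/N) + 100*T`` and temperature-dependent coil value
    ``640 - 45*T`` (T in °C); both are configuration, not physics built into
    the code.
    """

    temperature_c: float = 25.0
    mre_coil: Optional[float] = None
    mre_helix: Optional[float] = None

    def resolve(self, n_residues: int) -> tuple[float, float]:
        coil = self.mre_coil if self.mre_coil is not None \
            else 640.0 - 45.0 * self.temperature_c
        helix = self.mre_helix if self.mre_helix is not None \
            else -40000.0 * (1.0 - 2.5 / n_residues) + 100.0 * self.temperature_c
        return coil, helix


def percent_helicity(mre222: float, n_residues: int,
                     baselines: Optional[HelicityBaselines] = None) -> float:
    """Percent α-helix from MRE at 222 nm, linear between coil and helix limits."""
    baselines = baselines or HelicityBaselines()
    coil, helix = baselines.resolve(n_residues)
    if helix == coil:
        raise ValidationError("degenerate baselines: mre_helix == mre_coil")
    frac = 100.0 * (mre222 - coil) / (helix - coil)
    return float(np.clip(frac, 0.0, 100.0))
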