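"""Reduction of 1-D lamellar diffraction traces.

Bragg peaks from a stack of bilayers with repeat spacing d appear at
Q_h = 2*pi*h/d; in theta–2theta reflection geometry Q = 4*pi*sin(theta)/lambda.
The stages here pick and refine peaks, index them, regress the repeat
spacing, decompose superposed lattices, and integrate structure factors.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from lmfit.models import GaussianModel, LinearModel
from scipy import signal

from .types import (
    BraggPeak,
    DiffractionPattern,
    LatticeFit,
    StructureFactorSet,
    ValidationError,
    _require,
)

__all__ = [
    "q_from_theta",
    "detect_peaks",
    "index_and_fit_lattice",
    "deconvolve_two_lattices",
    "integrate_structure_factors",
    "PeakSettings",
]

_FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))


def q_from_theta(theta, wavelength: float):
    """Momentum transfer Q = 4*pi*sin(theta)/lambda; theta in degrees."""
    theta = np.asarray(theta, dtype=float)
    if np.any(theta < 0) or np.any(theta >= 90):
        raise ValidationError(f"theta must lie in [0, 90), got {theta}")
    if wavelength <= 0:
        raise ValidationError("wavelength must be positive")
    q = 4.0 * np.pi * np.sin(np.deg2rad(theta)) / wavelength
    return float(q) if q.ndim == 0 else q


@dataclass
class PeakSettings:
    prominence: Optional[float] = None   # None -> 5x robust noise estimate
    min_height: Optional[float] = None
    window_fwhm: float = 4.0             # fit window half-width, in estimated FWHMs
    max_peaks: int = 20
    min_area_significance: float = 5.0   # reject peaks with area < k * area_sd


def _robust_noise(counts: np.ndarray) -> float:
    """Noise floor from the median absolute successive difference."""
    diffs = np.diff(counts)
    return float(np.median(np.abs(diffs - np.median(diffs))) / 0.6745 / np.sqrt(2)) or 1.0


def detect_peaks(pattern: DiffractionPattern,
                 settings: Optional[PeakSettings] = None) -> list[BraggPeak]:
    """Locate Bragg peaks and refine them by local Gaussian + linear fits.

    Candidates come from a prominence filter on the raw trace.  Candidates
    whose fit windows overlap (partially resolved doublets) are refined
    jointly as a sum of Gaussians over a shared linear background; isolated
    candidates get single-Gaussian fits.  Refined peaks closer than one
    FWHM are merged (the larger-area one is kept).
    """
    st = settings or PeakSettings()
    q, counts = pattern.q, pattern.counts
    _require(len(q) >= 50, "pattern must have at least 50 bins")

    noise = _robust_noise(counts)
    prom = st.prominence if st.prominence is not None else 5.0 * noise
    idx, props = signal.find_peaks(counts, prominence=prom, height=st.min_height)
    if len(idx) == 0:
        return []
    # strongest first, cap the number considered
    keep = np.argsort(props["prominences"])[::-1][: st.max_peaks]
    proms = props["prominences"][np.sort(keep)]
    idx = idx[np.sort(keep)]

    dq = float(np.median(np.diff(q)))
    # collapse duplicate candidates riding the noisy top of one reflection
    # (closer than ~a peak width) onto the more prominent one, so a single
    # peak is never fit as a degenerate two-Gaussian cluster
    if len(idx) > 1:
        min_sep = max(5.0 * dq, 0.0)
        merged_idx, merged_prom = [idx[0]], [proms[0]]
        for k in range(1, len(idx)):
            if q[idx[k]] - q[merged_idx[-1]] < min_sep:
                if proms[k] > merged_prom[-1]:
                    merged_idx[-1], merged_prom[-1] = idx[k], proms[k]
            else:
                merged_idx.append(idx[k])
                merged_prom.append(proms[k])
        idx = np.array(merged_idx)
    # crude per-candidate width from the half-prominence crossing, bounded so
    # an unresolved doublet cannot inflate its neighbour's window
    try:
        widths = signal.peak_widths(counts, idx, rel_height=0.5)[0] * dq
    except Exception:
        widths = np.full(len(idx), 5.0 * dq)
    widths = np.clip(widths, 3.0 * dq, None)
    if len(idx) > 1:
        gaps = np.diff(q[idx])
        caps = np.full(len(idx), np.inf)
        caps[:-1] = np.minimum(caps[:-1], gaps)
        caps[1:] = np.minimum(caps[1:], gaps)
        widths = np.minimum(widths, np.maximum(caps, 3.0 * dq))

    # cluster candidates with overlapping windows
    half = st.window_fwhm * widths
    clusters: list[list[int]] = [[0]]
    for k in range(1, len(idx)):
        prev = clusters[-1][-1]
        if q[idx[k]] - half[k] <= q[idx[prev]] + half[prev]:
            clusters[-1].append(k)
        else:
            clusters.append([k])

    peaks: list[BraggPeak] = []
    for cluster in clusters:
        lo = q[idx[cluster[0]]] - half[cluster[0]]
        hi = q[idx[cluster[-1]]] + half[cluster[-1]]
        sel = (q >= lo) & (q <= hi)
        if sel.sum() < 5 + 3 * len(cluster):
            continue
        qx, cy = q[sel], counts[sel]
        model = LinearModel(prefix="bg_")
        for j, k in enumerate(cluster):
            model = model + GaussianModel(prefix=f"g{j}_")
        pars = model.make_params()
        pars["bg_slope"].set(value=0.0)
        pars["bg_intercept"].set(value=float(np.median(cy)))
        for j, k in enumerate(cluster):
            qc = q[idx[k]]
            pars[f"g{j}_center"].set(value=qc, min=qc - widths[k], max=qc + widths[k])
            pars[f"g{j}_sigma"].set(value=widths[k] / _FWHM, min=dq / 4,
                                    max=(hi - lo))
            amp0 = max(counts[idx[k]] - np.median(cy), noise) \
                * widths[k] / _FWHM * np.sqrt(2 * np.pi)
            pars[f"g{j}_amplitude"].set(value=amp0, min=0)
        weights = 1.0 / np.sqrt(np.maximum(cy, 1.0))
        try:
            res = model.fit(cy, pars, x=qx, weights=weights)
        except Exception:
            continue

        def _err(name):
            e = res.params[name].stderr
            return float(e) if e is not None else np.nan

        for j, k in enumerate(cluster):
            center = res.params[f"g{j}_center"].value
            sigma = res.params[f"g{j}_sigma"].value
            area = res.params[f"g{j}_amplitude"].value
            if area <= 0 or sigma <= 0 or center <= 0:
                continue
            if sigma * _FWHM < 2.0 * dq:
                continue        # single-bin spike, not a resolvable reflection
            height = area / (sigma * np.sqrt(2 * np.pi))
            if height < 3.0 * noise:
                continue
            area_err = _err(f"g{j}_amplitude")
            # integrated significance separates reflections from the
            # background bumps that pass a pointwise prominence gate on a
            # long trace
            if np.isfinite(area_err) and area < st.min_area_significance * area_err:
                continue
            fwhm_err = _err(f"g{j}_sigma")
            peaks.append(BraggPeak(
                center_q=float(center), height=float(height),
                fwhm_q=float(sigma * _FWHM), area=float(area),
                center_sd=_err(f"g{j}_center"),
                fwhm_sd=fwhm_err * _FWHM if np.isfinite(fwhm_err) else np.nan,
                area_sd=_err(f"g{j}_amplitude")))

    peaks.sort(key=lambda p: p.center_q)
    # merge refined peaks closer than one FWHM
    merged: list[BraggPeak] = []
    for p in peaks:
        if merged and (p.center_q - merged[-1].center_q) < max(p.fwhm_q, merged[-1].fwhm_q):
            if p.area > merged[-1].area:
                merged[-1] = p
        else:
            merged.append(p)
    return merged


# ---------------------------------------------------------------------------
# Lattice indexing
# ---------------------------------------------------------------------------

def _assign_orders(centers: np.ndarray) -> np.ndarray:
    """Assign integer orders by nearest-integer ratio to the lowest peak.

    When a ratio falls near the midpoint between two integers, both are tried
    and the assignment minimizing total squared residual wins.
    """
    base = centers[0]
    ratios = centers / base
    cands_per_peak = []
    for r in ratios:
        lo = int(np.floor(r))
        near = [h for h in (lo, lo + 1) if h >= 1]
        # keep only candidates within 0.5 of the ratio
        near = [h for h in near if abs(r - h) <= 0.5 + 1e-9] or [max(1, round(r))]
        cands_per_peak.append(near)
    best, best_sse = None, np.inf
    for combo in itertools.product(*cands_per_peak):
        h = np.array(combo, dtype=float)
        if len(set(combo)) < len(combo):
            continue
        slope = np.sum(h * centers) / np.sum(h * h)
        sse = np.sum((centers - slope * h) ** 2)
        if sse < best_sse:
            best, best_sse = combo, sse
    return np.array(best if best is not None else np.rint(ratios), dtype=int)


def _fit_lattice(centers: np.ndarray, orders: np.ndarray,
                 center_sds: Optional[np.ndarray] = None) -> tuple[float, float, np.ndarray]:
    """Weighted LS of Q_h on h through the origin: slope = 2*pi/d."""
    if center_sds is None:
        w = np.ones_like(centers)
    else:
        sds = np.asarray(center_sds, dtype=float).copy()
        bad = ~np.isfinite(sds) | (sds <= 0)
        if bad.all():
            w = np.ones_like(centers)
        else:
            # peaks whose center uncertainty could not be estimated carry no
            # usable metrology; excluding them from the slope beats guessing
            # a weight for a point with h-squared leverage
            w = np.where(bad, 0.0, 1.0 / np.where(bad, 1.0, sds) ** 2)
    h = orders.astype(float)
    slope = np.sum(w * h * centers) / np.sum(w * h * h)
    resid = centers - slope * h
    n = len(centers)
    n_eff = int(np.sum(w > 0))
    if n_eff > 1:
        s2 = np.sum(w * resid ** 2) / (n_eff - 1)
        slope_var = s2 / np.sum(w * h * h)
    else:
        slope_var = (center_sds[0] / h[0]) ** 2 if center_sds is not None and np.isfinite(center_sds[0]) else 0.0
    d = 2.0 * np.pi / slope
    d_sd = 2.0 * np.pi * np.sqrt(max(slope_var, 0.0)) / slope ** 2
    return float(d), float(d_sd), resid


def index_and_fit_lattice(peaks: Sequence[BraggPeak],
                          residual_threshold: float = 0.01) -> LatticeFit:
    """Index peaks against one lamellar lattice and regress the repeat spacing.

    ``residual_threshold`` is the |ΔQ| (1/Å) above which a peak is considered
    inconsistent with a single lattice and the fit is flagged for two-lattice
    treatment.
    """
    _require(len(peaks) >= 1, "need at least one peak")
    peaks = sorted(peaks, key=lambda p: p.center_q)
    centers = np.array([p.center_q for p in peaks])
    sds = np.array([p.center_sd for p in peaks])
    orders = _assign_orders(centers)
    d, d_sd, resid = _fit_lattice(centers, orders, sds)
    for p, h in zip(peaks, orders):
        p.order = int(h)
    return LatticeFit(d=d, d_sd=d_sd, orders_used=[int(h) for h in orders],
                      residuals=resid,
                      flagged_multilattice=bool(np.any(np.abs(resid) > residual_threshold)))


def deconvolve_two_lattices(peaks: Sequence[BraggPeak],
                            bic_margin: float = 10.0,
                            residual_threshold: float = 0.01
                            ) -> tuple[LatticeFit, Optional[LatticeFit], dict]:
    """Exact two-lattice decomposition by exhaustive peak assignment.

    Every bipartition of the peaks (each part >= 2, exact for <= 12 peaks) is
    indexed and fitted; the assignment minimizing the total squared residual
    wins.  The split is only accepted if its Bayesian information criterion
    beats the single-lattice fit by ``bic_margin``; otherwise the single fit
    is returned with a "no split detected" flag.

    Returns ``(fit_a, fit_b, info)``; ``fit_b`` is None when no split is
    detected.  ``info`` carries memberships, BICs and flags.
    """
    _require(len(peaks) >= 4, "need at least 4 peaks for two-lattice deconvolution")
    if len(peaks) > 12:
        # exact search is exponential; keep the strongest peaks
        peaks = sorted(peaks, key=lambda p: p.area, reverse=True)[:12]
    peaks = sorted(peaks, key=lambda p: p.center_q)
    centers = np.array([p.center_q for p in peaks])
    n = len(peaks)

    single = index_and_fit_lattice(peaks, residual_threshold)
    sse_1 = float(np.sum(single.residuals ** 2))
    bic_1 = n * np.log(max(sse_1, 1e-30) / n) + 1 * np.log(n)

    best = None
    for bits in range(1, 2 ** (n - 1)):           # peak 0 fixed to lattice A
        mask = np.array([(bits >> k) & 1 == 0 for k in range(n)], dtype=bool)
        if mask.sum() < 2 or (~mask).sum() < 2:
            continue
        ca, cb = centers[mask], centers[~mask]
        ha, hb = _assign_orders(ca), _assign_orders(cb)
        da, _, ra = _fit_lattice(ca, ha)
        db, _, rb = _fit_lattice(cb, hb)
        sse = float(np.sum(ra ** 2) + np.sum(rb ** 2))
        if best is None or sse < best[0]:
            best = (sse, mask, ha, hb)

    info: dict = {"bic_single": float(bic_1)}
    if best is None:
        info["no_split"] = True
        return single, None, info

    sse_2, mask, ha, hb = best
    bic_2 = n * np.log(max(sse_2, 1e-30) / n) + 2 * np.log(n)
    info["bic_two"] = float(bic_2)
    if bic_1 - bic_2 < bic_margin:
        info["no_split"] = True
        return single, None, info

    pa = [p for p, m in zip(peaks, mask) if m]
    pb = [p for p, m in zip(peaks, mask) if not m]
    sds_a = np.array([p.center_sd for p in pa])
    sds_b = np.array([p.center_sd for p in pb])
    da, da_sd, ra = _fit_lattice(centers[mask], ha, sds_a)
    db, db_sd, rb = _fit_lattice(centers[~mask], hb, sds_b)
    for p, h in zip(pa, ha):
        p.order = int(h)
    for p, h in zip(pb, hb):
        p.order = int(h)
    fit_a = LatticeFit(d=da, d_sd=da_sd, orders_used=[int(h) for h in ha], residuals=ra)
    fit_b = LatticeFit(d=db, d_sd=db_sd, orders_used=[int(h) for h in hb], residuals=rb)
    if fit_a.d < fit_b.d:
        fit_a, fit_b, mask = fit_b, fit_a, ~mask
    info["no_split"] = False
    info["membership_a"] = mask.tolist()
    if abs(fit_a.d - fit_b.d) < 3.0 * max(fit_a.d_sd, fit_b.d_sd, 1e-6):
        info["degenerate"] = True
    return fit_a, fit_b, info


# ---------------------------------------------------------------------------
# Structure factors
# ---------------------------------------------------------------------------

def integrate_structure_factors(pattern: DiffractionPattern, lattice: LatticeFit,
                                corrections: Optional[dict[str, Callable[[int], float]]] = None,
                                window_fwhm: float = 3.0,
                                default_fwhm_q: float = 0.005,
                                hmax: Optional[int] = None,
                                ) -> StructureFactorSet:
    """Unsigned structure factors |F(h)| = sqrt(corrected integrated intensity).

    Each order's peak is integrated over a window of ``window_fwhm`` FWHMs
    around Q_h = 2*pi*h/d after subtracting a linear background anchored at
    the window edges; multiplicative corrections (absorption, extinction) are
    applied per order before the square root.  The SD comes from Poisson
    counting statistics on the integrated counts, delta-method-propagated
    through the square root: sd(|F|) = sd(area)*C/(2*|F|).
    """
    corrections = corrections or {}
    c_abs = corrections.get("absorption", lambda h: 1.0)
    c_ext = corrections.get("extinction", lambda h: 1.0)
    q, counts = pattern.q, pattern.counts
    dq = np.gradient(q)
    hs = sorted(set(lattice.orders_used)) if hmax is None else list(range(1, hmax + 1))

    orders, amps, sds = [], [], []
    for h in hs:
        q_h = 2.0 * np.pi * h / lattice.d
        half = window_fwhm * default_fwhm_q
        sel = (q >= q_h - half) & (q <= q_h + half)
        if sel.sum() < 5:
            continue
        # linear background through the mean of a few edge bins
        edge = max(2, sel.sum() // 10)
        i0 = np.where(sel)[0][0]
        i1 = np.where(sel)[0][-1]
        y0 = counts[max(0, i0 - edge):i0 + 1].mean()
        y1 = counts[i1:i1 + edge + 1].mean()
        bg = np.interp(q[sel], [q[i0], q[i1]], [y0, y1])
        net = counts[sel] - bg
        area = float(np.sum(net * dq[sel]))
        # Poisson: var(sum counts) = sum counts (raw, incl. background)
        dq_bar = float(np.mean(dq[sel]))
        area_sd = float(np.sqrt(np.sum(counts[sel]))) * dq_bar
        corr = c_abs(h) * c_ext(h)
        corrected = area * corr
        if corrected <= 0:
            orders.append(h)
            amps.append(0.0)
            sds.append(max(np.sqrt(abs(corrected)) if corrected else area_sd, area_sd))
            continue
        amp = np.sqrt(corrected)
        orders.append(h)
        amps.append(float(amp))
        sds.append(float(area_sd * corr / (2.0 * amp)))

    return StructureFactorSet(
        d=lattice.d, orders=np.array(orders), amplitudes=np.array(amps),
        sds=np.array(sds), signed=False,
        label=str(pattern.metadata.get("label", "")))
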