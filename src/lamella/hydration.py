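"""Radial distribution of water around a solute and shell-wise water counts.

Distances use the nearest-solute-point convention (a surface-proximity
measure, appropriate for hydration shells around an extended peptide).
Normalization of g(r) uses the ideal-gas density of the water points in the
analysis volume; because the nearest-distance "shell" around a multi-point
solute is not a spherical annulus, shell volumes are estimated by seeded
Monte-Carlo integration over the analysis volume.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.signal import find_peaks
from scipy.spatial.distance import cdist

from .types import CoordinateFrame, ShellSummary, ValidationError, _require

__all__ = ["radial_distribution", "shell_boundaries", "count_waters_in_shells", "GofR"]


def _nearest_distances(frame: CoordinateFrame) -> np.ndarray:
    if frame.box is not None:
        # minimum-image convention per axis
        diff = frame.water_positions[:, None, :] - frame.solute_positions[None, :, :]
        diff -= frame.box * np.round(diff / frame.box)
        return np.sqrt((diff ** 2).sum(axis=2)).min(axis=1)
    return cdist(frame.water_positions, frame.solute_positions).min(axis=1)


@dataclass
class GofR:
    r: np.ndarray           # bin centers, Å
    g: np.ndarray
    g_sd: np.ndarray        # over-frame SD
    bin_width: float
    density: float          # mean water number density used for normalization
    shell_volumes: np.ndarray
    n_frames: int = 1


def _analysis_bounds(frames: Sequence[CoordinateFrame]) -> tuple[np.ndarray, np.ndarray]:
    pts = np.vstack([f.water_positions for f in frames])
    return pts.min(axis=0), pts.max(axis=0)


def radial_distribution(frames: Sequence[CoordinateFrame], r_max: float,
                        bin_width: float, mc_samples: int = 200_000,
                        seed: int = 0) -> GofR:
    """g(r) of water around the solute under the nearest-solute convention."""
    frames = list(frames)
    _require(len(frames) >= 1, "need at least one frame")
    _require(bin_width > 0, "bin_width must be positive")
    _require(r_max > 3 * bin_width, "r_max must exceed 3 bin widths")

    edges = np.arange(0.0, r_max + bin_width, bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    rng = np.random.default_rng(seed)

    # Monte-Carlo shell volumes in the analysis volume (box if given, else
    # the waters' bounding box padded by r_max)
    f0 = frames[0]
    if f0.box is not None:
        lo = np.zeros(3)
        hi = np.asarray(f0.box, float)
    else:
        lo, hi = _analysis_bounds(frames)
        lo, hi = lo - 0.0, hi + 0.0
    vol_total = float(np.prod(hi - lo))
    sample = lo + rng.random((mc_samples, 3)) * (hi - lo)
    probe = CoordinateFrame(solute_positions=f0.solute_positions,
                            water_positions=sample, box=f0.box)
    d_probe = _nearest_distances(probe)
    counts_probe, _ = np.histogram(d_probe, bins=edges)
    shell_volumes = counts_probe / mc_samples * vol_total

    g_frames = []
    for f in frames:
        dists = _nearest_distances(f)
        counts, _ = np.histogram(dists, bins=edges)
        density = len(dists) / vol_total
        with np.errstate(divide="ignore", invalid="ignore"):
            g = counts / (density * shell_volumes)
        g[shell_volumes == 0] = 0.0
        g_frames.append(g)
    G = np.array(g_frames)
    return GofR(r=centers, g=G.mean(axis=0),
                g_sd=G.std(axis=0, ddof=1) if len(frames) > 1 else np.zeros_like(centers),
                bin_width=bin_width,
                density=float(np.mean([len(f.water_positions) for f in frames])) / vol_total,
                shell_volumes=shell_volumes, n_frames=len(frames))


def shell_boundaries(g_curve: GofR, n_shells: int = 3,
                     smooth_window: int = 3, n_boot: int = 50, seed: int = 0,
                     ) -> tuple[list[float], list[float], bool]:
    """Boundary radii at the local minima following successive g(r) maxima.

    Returns ``(radii, radii_sd, flagged)``; flagged is True when fewer minima
    than requested exist.  SDs come from re-localizing the minima on curves
    resampled within the over-frame SD.
    """
    def locate(g: np.ndarray) -> list[float]:
        if smooth_window > 1:
            k = np.ones(smooth_window)
            g = np.convolve(g, k, mode="same") / np.convolve(np.ones_like(g), k, mode="same")
        span = float(g.max() - g.min())
        if span <= 0:
            return []
        # hydration-shell peaks, not noise bumps: require real prominence
        peaks, _ = find_peaks(g, prominence=0.1 * span)
        if len(peaks) == 0:
            return []
        # and statistical significance against the over-frame scatter
        sem = g_curve.g_sd / np.sqrt(max(g_curve.n_frames, 1))
        peaks = np.array([p for p in peaks if g[p] - 1.0 >= 2.0 * sem[p]],
                         dtype=int)
        if len(peaks) == 0:
            return []
        bounds = []
        for i, p in enumerate(peaks):
            if len(bounds) >= n_shells:
                break
            stop = peaks[i + 1] if i + 1 < len(peaks) else len(g)
            seg = g[p:stop]
            if len(seg) < 2:
                continue
            m = p + int(np.argmin(seg))
            if m > p:
                bounds.append(float(g_curve.r[m]))
        return bounds[:n_shells]

    base = locate(g_curve.g)
    if len(base) == 0:
        return [], [], True
    rng = np.random.default_rng(seed)
    boot = []
    for _ in range(n_boot):
        pert = g_curve.g + rng.normal(0.0, np.maximum(g_curve.g_sd, 0.0))
        b = locate(pert)
        if len(b) == len(base):
            boot.append(b)
    if len(boot) >= 2:
        sds = np.std(np.array(boot), axis=0, ddof=1).tolist()
    else:
        sds = [0.0] * len(base)
    flagged = len(base) < n_shells
    return base, sds, flagged


def count_waters_in_shells(frames: Sequence[CoordinateFrame],
                           boundaries: Sequence[float]) -> list[ShellSummary]:
    """Cumulative water counts below each boundary, mean ± SD over frames."""
    frames = list(frames)
    _require(len(frames) >= 1, "need at least one frame")
    bounds = list(boundaries)
    _require(all(b > a for a, b in zip(bounds, bounds[1:])),
             "boundaries must be strictly increasing")
    counts = np.zeros((len(frames), len(bounds)))
    for i, f in enumerate(frames):
        dists = _nearest_distances(f)
        for j, b in enumerate(bounds):
            counts[i, j] = np.sum(dists < b)
    means = counts.mean(axis=0)
    sds = counts.std(axis=0, ddof=1) if len(frames) > 1 else np.zeros(len(bounds))
    return [ShellSummary(shell_index=j + 1, boundary_radius=float(b),
                         boundary_radius_sd=0.0, water_count=float(means[j]),
                         water_count_sd=float(sds[j]))
            for j, b in enumerate(bounds)]
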