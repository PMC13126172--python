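"""Plain-text readers and writers for the pipeline's interchange formats.

All formats are line-oriented text: two-column diffraction traces with
``# key = value`` header comments, structure-factor CSV with contrast
metadata headers, (z, rho, sd) profile tables, XYZ coordinate frames, and
wide-format CD titration CSV.
"""

from __future__ import annotations

import io as _io
import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .diffraction import q_from_theta
from .types import (
    CoordinateFrame,
    DiffractionPattern,
    SLDProfile,
    StructureFactorSet,
    TitrationCurve,
    TitrationPoint,
    ValidationError,
)

__all__ = [
    "read_pattern", "write_pattern",
    "read_structure_factors", "write_structure_factors",
    "read_profile", "write_profile",
    "read_xyz_frames", "write_xyz_frames",
    "read_cd_csv",
    "read_titration_csv", "write_titration_csv",
]


def _parse_header_comments(path) -> dict:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if "=" in body:
                k, v = body.split("=", 1)
                meta[k.strip()] = v.strip()
    return meta


def read_pattern(path, wavelength: Optional[float] = None) -> DiffractionPattern:
    """Two-column (abscissa, counts) trace; header comments may declare
    ``# units = q|two_theta`` and ``# wavelength = <Å>``.  2θ abscissae are
    converted to Q on load using θ = 2θ/2 (symmetric reflection geometry)."""
    meta = _parse_header_comments(path)
    arr = np.loadtxt(path, comments="#", delimiter=None)
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise ValidationError(f"{path}: expected two columns (abscissa, counts)")
    wl = wavelength or float(meta.get("wavelength", 0) or 0)
    units = meta.get("units", "q").lower()
    x, counts = arr[:, 0], arr[:, 1]
    if units in ("two_theta", "2theta", "twotheta"):
        if wl <= 0:
            raise ValidationError("2theta input requires a declared wavelength")
        x = q_from_theta(x / 2.0, wl)
    elif wl <= 0:
        wl = 1.54
    return DiffractionPattern(q=x, counts=counts, wavelength=wl, metadata=meta)


def write_pattern(pattern: DiffractionPattern, path) -> None:
    with open(path, "w") as fh:
        fh.write("# units = q\n")
        fh.write(f"# wavelength = {pattern.wavelength}\n")
        for k, v in pattern.metadata.items():
            if k not in ("units", "wavelength"):
                fh.write(f"# {k} = {v}\n")
        np.savetxt(fh, np.column_stack([pattern.q, pattern.counts]),
                   fmt="%.8g", header="q_invA counts")


def read_structure_factors(path) -> StructureFactorSet:
    """CSV (h, F, sd) with ``# d_spacing=``, ``# d2o_fraction=``,
    ``# d7_fraction=`` and optional ``# signed=`` header lines."""
    meta = _parse_header_comments(path)
    df = pd.read_csv(path, comment="#")
    cols = {c.strip().lower(): c for c in df.columns}
    h_col = cols.get("h")
    f_col = cols.get("f") or cols.get("f_or_absf") or cols.get("amplitude")
    sd_col = cols.get("sd")
    if not (h_col and f_col and sd_col):
        raise ValidationError(f"{path}: need columns h, F, sd")
    return StructureFactorSet(
        d=float(meta.get("d_spacing", 0) or 0) or float(meta.get("d", 0)),
        orders=df[h_col].to_numpy(),
        amplitudes=df[f_col].to_numpy(dtype=float),
        sds=df[sd_col].to_numpy(dtype=float),
        d2o_fraction=float(meta.get("d2o_fraction", 0) or 0),
        d7_fraction=float(meta.get("d7_fraction", 0) or 0),
        signed=str(meta.get("signed", "false")).lower() in ("1", "true", "yes"),
        label=meta.get("label", ""))


def write_structure_factors(sf: StructureFactorSet, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# d_spacing = {sf.d}\n")
        fh.write(f"# d2o_fraction = {sf.d2o_fraction}\n")
        fh.write(f"# d7_fraction = {sf.d7_fraction}\n")
        fh.write(f"# signed = {str(sf.signed).lower()}\n")
        if sf.label:
            fh.write(f"# label = {sf.label}\n")
        pd.DataFrame({"h": sf.orders, "F": sf.amplitudes, "sd": sf.sds}) \
            .to_csv(fh, index=False)


def read_profile(path) -> SLDProfile:
    meta = _parse_header_comments(path)
    arr = np.loadtxt(path, comments="#")
    sd = arr[:, 2] if arr.shape[1] > 2 else None
    return SLDProfile(z=arr[:, 0], rho=arr[:, 1], sd_band=sd,
                      d=float(meta.get("d_spacing", 0) or (arr[-1, 0] - arr[0, 0])),
                      hmax=int(float(meta.get("hmax", 5))),
                      absolute_scale=str(meta.get("absolute_scale", "false")).lower()
                      in ("1", "true", "yes"))


def write_profile(profile: SLDProfile, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# d_spacing = {profile.d}\n")
        fh.write(f"# hmax = {profile.hmax}\n")
        fh.write(f"# absolute_scale = {str(profile.absolute_scale).lower()}\n")
        cols = [profile.z, profile.rho]
        header = "z_A rho"
        if profile.sd_band is not None:
            cols.append(profile.sd_band)
            header += " sd"
        np.savetxt(fh, np.column_stack(cols), fmt="%.8g", header=header)


# ---------------------------------------------------------------------------
# XYZ frames
# ---------------------------------------------------------------------------

def read_xyz_frames(path, solute_labels: Sequence[str],
                    water_labels: Sequence[str]) -> list[CoordinateFrame]:
    """Multi-frame XYZ (count line, comment line, then `label x y z` rows);
    the label sets route atoms to the solute or water point clouds."""
    solute_labels = set(solute_labels)
    water_labels = set(water_labels)
    frames = []
    lines = Path(path).read_text().splitlines()
    i, fid = 0, 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i].split()[0])
        rows = lines[i + 2:i + 2 + n]
        sol, wat = [], []
        for row in rows:
            parts = row.split()
            label, xyz = parts[0], [float(v) for v in parts[1:4]]
            if label in solute_labels:
                sol.append(xyz)
            elif label in water_labels:
                wat.append(xyz)
        frames.append(CoordinateFrame(solute_positions=np.array(sol),
                                      water_positions=np.array(wat),
                                      frame_id=fid))
        fid += 1
        i += 2 + n
    return frames


def write_xyz_frames(frames: Sequence[CoordinateFrame], path,
                     solute_label: str = "P", water_label: str = "O") -> None:
    with open(path, "w") as fh:
        for f in frames:
            n = len(f.solute_positions) + len(f.water_positions)
            fh.write(f"{n}\nframe {f.frame_id}\n")
            for p in f.solute_positions:
                fh.write(f"{solute_label} {p[0]:.4f} {p[1]:.4f} {p[2]:.4f}\n")
            for p in f.water_positions:
                fh.write(f"{water_label} {p[0]:.4f} {p[1]:.4f} {p[2]:.4f}\n")


def read_cd_csv(path) -> pd.DataFrame:
    """Wide CD table: first column wavelength_nm, one column per titration
    step in millidegrees."""
    df = pd.read_csv(path, comment="#")
    first = df.columns[0]
    if "wavelength" not in first.lower():
        raise ValidationError("first column must be the wavelength (nm)")
    return df.rename(columns={first: "wavelength_nm"})


def write_titration_csv(curve: TitrationCurve, path) -> None:
    """Long-form titration table: lipid_conc_M, peptide_conc_M, nmre."""
    with open(path, "w") as fh:
        fh.write("lipid_conc_M,peptide_conc_M,nmre\n")
        for p in curve.points:
            fh.write(f"{p.lipid_conc:.10e},{p.peptide_conc:.10e},{p.nmre:.8f}\n")


def read_titration_csv(path) -> TitrationCurve:
    """Read the long-form titration table written by ``write_titration_csv``."""
    df = pd.read_csv(path, comment="#")
    required = {"lipid_conc_M", "peptide_conc_M", "nmre"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"titration CSV must have columns {sorted(required)}")
    points = [TitrationPoint(lipid_conc=float(r.lipid_conc_M),
                             nmre=float(r.nmre),
                             peptide_conc=float(r.peptide_conc_M))
              for r in df.itertuples()]
    return TitrationCurve(peptide_conc=float(df.peptide_conc_M.iloc[0]),
                          points=points)
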