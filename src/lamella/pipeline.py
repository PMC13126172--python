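"""Pipeline orchestration: config, logging, staged execution, reports.

Stages run in dependency order (simulate → fit-binding | reduce-diffraction
→ phase → profile → water | shells); every run writes a resolved-config
snapshot, a timestamped log, and per-stage JSON reports that ``report``
aggregates.  Physical quantities in the config carry explicit unit suffixes
(``_umol_per_L``, ``_angstrom``, ...).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from . import __version__
from .binding import DilutionSchedule, SamplerSettings, fit_binding
from .diffraction import (PeakSettings, deconvolve_two_lattices, detect_peaks,
                          index_and_fit_lattice, integrate_structure_factors)
from .hydration import count_waters_in_shells, radial_distribution, shell_boundaries
from .io import (read_pattern, read_structure_factors, read_titration_csv,
                 read_xyz_frames, write_pattern, write_profile,
                 write_structure_factors, write_titration_csv,
                 write_xyz_frames)
from .profiles import (ComponentSpec, calibrate_amplitude, deuterium_difference,
                       fit_gaussian_components, fourier_synthesis, mc_resample,
                       phase_by_contrast, waters_per_peptide)
from .synthetic import (BINDING_PRESETS, default_bilayer_model,
                        forward_structure_factors, generate_contrast_series,
                        generate_hydration_frames, generate_titration,
                        generate_two_phase_pattern, render_pattern, write_audit)
from .types import (ContrastSeries, GroundTruth, ValidationError,
                    WaterQuantification)

STAGES = ("simulate", "fit-binding", "reduce-diffraction", "phase",
          "profile", "water", "shells", "report")

# published schema: allowed keys per stage section
_SCHEMA: dict[str, set] = {
    "run": {"stages", "seed", "outdir", "log_level"},
    "simulate": {"kind", "composition", "noise_sd_nmre", "d_angstrom",
                 "d_a_angstrom", "d_b_angstrom", "weight", "total_counts",
                 "x_fractions", "d7_fractions", "noise_level",
                 "noise_floor_frac",
                 "shell_radii_angstrom", "shell_counts", "n_frames",
                 "n_background", "background_extent_angstrom",
                 "peptide_conc_umol_per_L", "volume_uL",
                 "aliquot_uL", "n_aliquots", "lipid_stock_mmol_per_L"},
    "fit-binding": {"input_csvs", "n_walkers", "n_steps", "seed"},
    "reduce-diffraction": {"input", "wavelength_angstrom", "min_prominence",
                           "try_two_lattices", "hmax"},
    "phase": {"inputs", "axis", "labeled_inputs"},
    "profile": {"inputs", "components", "n_grid"},
    "water": {"base", "high", "labeled", "label_fraction", "n_deuterons",
              "waters_per_lipid", "exchangeable_protons",
              "peptide_per_lipid", "d2o_fraction"},
    "shells": {"frames_xyz", "r_max_angstrom", "bin_width_angstrom",
               "n_shells", "solute_labels", "water_labels"},
    "report": set(),
}


@dataclasses.dataclass
class RunConfig:
    """Validated run configuration with a resolved snapshot."""

    stages: list
    seed: int = 0
    outdir: Path = Path("runs/out")
    log_level: str = "INFO"
    sections: dict = dataclasses.field(default_factory=dict)
    source_path: Optional[Path] = None

    @classmethod
    def from_yaml(cls, path, seed: Optional[int] = None,
                  outdir: Optional[str] = None,
                  log_level: Optional[str] = None,
                  stages: Optional[Sequence[str]] = None) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValidationError(f"{path}: config must be a mapping")
        validate_config(raw, str(path))
        run = raw.get("run", {})
        cfg = cls(
            stages=list(stages if stages is not None else run.get("stages", [])),
            seed=int(seed if seed is not None else run.get("seed", 0)),
            outdir=Path(outdir if outdir is not None else run.get("outdir", "runs/out")),
            log_level=str(log_level if log_level is not None else run.get("log_level", "INFO")),
            sections={k: v for k, v in raw.items() if k != "run"},
            source_path=path,
        )
        if not cfg.stages:
            raise ValidationError(f"{path}: run.stages must name at least one stage")
        return cfg

    def resolved(self) -> dict:
        out = {"run": {"stages": list(self.stages), "seed": self.seed,
                       "outdir": str(self.outdir), "log_level": self.log_level,
                       "version": __version__}}
        out.update(self.sections)
        return out


def validate_config(raw: dict, source: str = "<config>") -> None:
    """Schema validation with key-addressed errors."""
    for section, body in raw.items():
        if section not in _SCHEMA:
            raise ValidationError(f"{source}: unknown section '{section}'")
        if body is None:
            continue
        if not isinstance(body, dict):
            raise ValidationError(f"{source}: section '{section}' must be a mapping")
        for key in body:
            if key not in _SCHEMA[section]:
                raise ValidationError(
                    f"{source}: unknown key '{section}.{key}'")
    stages = (raw.get("run") or {}).get("stages", [])
    for s in stages:
        if s not in STAGES:
            raise ValidationError(f"{source}: run.stages: unknown stage '{s}'")


def _setup_logging(outdir: Path, level: str) -> logging.Logger:
    logger = logging.getLogger("lamella")
    logger.setLevel(getattr(logging, level.upper(), logging.INFO))
    logger.handlers.clear()
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
    fh = logging.FileHandler(outdir / "run.log")
    fh.setFormatter(fmt)
    sh = logging.StreamHandler(sys.stderr)
    sh.setFormatter(fmt)
    logger.addHandler(fh)
    logger.addHandler(sh)
    return logger


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _dump(obj, path: Path) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, Path):
            return str(o)
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        raise TypeError(f"not serializable: {type(o)}")
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=default)
        fh.write("\n")


def _resolve(base: Optional[Path], p, outdir: Optional[Path] = None) -> Path:
    """Resolve a relative input against the config directory, then against
    the run's output directory (where earlier stages write)."""
    p = Path(p)
    if not p.is_absolute():
        for root in (base, outdir):
            if root is not None and (Path(root) / p).exists():
                return Path(root) / p
    return p


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: dict, seed: int, outdir: Path, log) -> dict:
    kind = cfg.get("kind", "titration")
    rep: dict = {"kind": kind, "flagged": False, "outputs": []}
    if kind == "titration":
        comp = cfg.get("composition", "POPC")
        if comp not in BINDING_PRESETS:
            raise ValidationError(f"simulate.composition: unknown '{comp}'")
        schedule = DilutionSchedule(
            initial_volume=float(cfg.get("volume_uL", 300.0)) * 1e-6,
            step_volumes=[float(cfg.get("aliquot_uL", 10.0)) * 1e-6]
            * int(cfg.get("n_aliquots", 20)),
            titrant_lipid_conc=float(cfg.get("lipid_stock_mmol_per_L", 3.0)) * 1e-3)
        curve, gt = generate_titration(
            BINDING_PRESETS[comp],
            c_pt=float(cfg.get("peptide_conc_umol_per_L", 20.0)) * 1e-6,
            lipid_schedule=schedule,
            noise_sd=float(cfg.get("noise_sd_nmre", 0.3)), seed=seed,
            composition_label=comp,
            audit_path=outdir / "titration_audit.json")
        out = outdir / "titration.csv"
        write_titration_csv(curve, out)
        rep["outputs"] = [str(out), str(outdir / "titration_audit.json")]
    elif kind == "pattern":
        d = float(cfg.get("d_angstrom", 54.9))
        model = default_bilayer_model(d=d)
        sf = forward_structure_factors(model, hmax=5, scale=1.0)
        pattern = render_pattern(sf, total_counts=float(cfg.get("total_counts", 2e6)),
                                 seed=seed)
        write_audit(GroundTruth(seed=seed,
                                structure_factors={"d": d,
                                                   "F": sf.amplitudes.tolist()}),
                    outdir / "pattern_audit.json")
        out = outdir / "pattern.txt"
        write_pattern(pattern, out)
        rep["outputs"] = [str(out), str(outdir / "pattern_audit.json")]
    elif kind == "two_phase":
        pattern, gt = generate_two_phase_pattern(
            d1=float(cfg.get("d_a_angstrom", 58.6)),
            d2=float(cfg.get("d_b_angstrom", 55.3)),
            weight=float(cfg.get("weight", 0.5)),
            total_counts=float(cfg.get("total_counts", 2e6)),
            seed=seed, audit_path=outdir / "pattern_audit.json")
        out = outdir / "pattern.txt"
        write_pattern(pattern, out)
        rep["outputs"] = [str(out), str(outdir / "pattern_audit.json")]
    elif kind == "contrast":
        model = default_bilayer_model(d=float(cfg.get("d_angstrom", 54.9)))
        series, gt = generate_contrast_series(
            model,
            x_list=tuple(cfg.get("x_fractions", (0.0, 0.5, 1.0))),
            d7_list=tuple(cfg.get("d7_fractions", (0.0, 0.4, 5.0 / 6.0))),
            noise_level=float(cfg.get("noise_level", 0.02)),
            noise_floor_frac=float(cfg.get("noise_floor_frac", 0.002)),
            seed=seed, audit_path=outdir / "contrast_audit.json")
        outs = []
        for s in series.sets:
            p = outdir / f"sf_x{s.d2o_fraction:g}_d7{s.d7_fraction:g}.csv"
            write_structure_factors(s, p)
            outs.append(str(p))
        rep["outputs"] = outs + [str(outdir / "contrast_audit.json")]
    elif kind == "hydration":
        frames, gt = generate_hydration_frames(
            shell_radii=tuple(cfg.get("shell_radii_angstrom", (2.8, 4.5, 6.5))),
            shell_counts=tuple(cfg.get("shell_counts", (6, 14, 28))),
            n_frames=int(cfg.get("n_frames", 8)), seed=seed,
            n_background=int(cfg.get("n_background", 0)),
            background_extent=float(cfg.get("background_extent_angstrom", 15.0)),
            audit_path=outdir / "hydration_audit.json")
        out = outdir / "frames.xyz"
        write_xyz_frames(frames, out)
        rep["outputs"] = [str(out), str(outdir / "hydration_audit.json")]
    else:
        raise ValidationError(f"simulate.kind: unknown '{kind}'")
    log.info("simulate(%s) wrote %d file(s)", kind, len(rep["outputs"]))
    return rep


def stage_fit_binding(cfg: dict, seed: int, outdir: Path, log,
                      base: Optional[Path] = None) -> dict:
    paths = [_resolve(base, p, outdir) for p in cfg.get("input_csvs", [outdir / "titration.csv"])]
    for p in paths:
        if not Path(p).exists():
            raise ValidationError(f"fit-binding: missing input file '{p}'")
    curves = [read_titration_csv(p) for p in paths]
    settings = SamplerSettings(
        n_walkers=int(cfg.get("n_walkers", 24)),
        n_steps=int(cfg.get("n_steps", 2500)),
        seed=int(cfg.get("seed", seed)))
    post = fit_binding(curves if len(curves) > 1 else curves[0],
                       sampler_settings=settings)
    rep = {"flagged": not post.converged, "inputs": [str(p) for p in paths],
           "input_sha256": {str(p): _sha256(Path(p)) for p in paths},
           "posterior": post.summary()}
    log.info("fit-binding: n median %.2f, converged %s",
             post.medians.get("n_lipids", float("nan")), post.converged)
    return rep


def stage_reduce(cfg: dict, seed: int, outdir: Path, log,
                 base: Optional[Path] = None) -> dict:
    path = _resolve(base, cfg.get("input", outdir / "pattern.txt"), outdir)
    if not Path(path).exists():
        raise ValidationError(f"reduce-diffraction: missing input file '{path}'")
    pattern = read_pattern(path)
    settings = PeakSettings()
    if "min_prominence" in cfg:
        settings = dataclasses.replace(settings, prominence=float(cfg["min_prominence"]))
    peaks = detect_peaks(pattern, settings=settings)
    fit = index_and_fit_lattice(peaks)
    resid = float(np.max(np.abs(fit.residuals))) if len(fit.residuals) else 0.0
    rep = {"flagged": False, "input": str(path), "input_sha256": _sha256(Path(path)),
           "n_peaks": len(peaks),
           "peaks": [{"center_q": p.center_q, "fwhm_q": p.fwhm_q, "area": p.area,
                      "order": p.order} for p in peaks],
           "lattice": {"d": fit.d, "d_sd": fit.d_sd,
                       "max_abs_residual": resid,
                       "flagged_multilattice": fit.flagged_multilattice}}
    if cfg.get("try_two_lattices", False) or fit.flagged_multilattice:
        fa, fb, info = deconvolve_two_lattices(peaks)
        split = fb is not None and not info.get("no_split", False)
        rep["two_lattices"] = {
            "split": split,
            "d_a": fa.d, "d_a_sd": fa.d_sd,
            "d_b": fb.d if fb is not None else None,
            "d_b_sd": fb.d_sd if fb is not None else None,
            "degenerate": bool(info.get("degenerate", False))}
        if fb is not None:
            fit = fa if fa.d >= fb.d else fb
        # a multilattice signature that cannot be separated leaves the
        # integrated amplitudes unreliable
        rep["flagged"] = bool(fit.flagged_multilattice and not split)
    sf = integrate_structure_factors(pattern, fit,
                                     hmax=int(cfg.get("hmax", 5)))
    sf_path = outdir / "structure_factors.csv"
    write_structure_factors(sf, sf_path)
    rep["structure_factors"] = str(sf_path)
    log.info("reduce-diffraction: %d peaks, d = %.3f Å", len(peaks), fit.d)
    return rep


def stage_phase(cfg: dict, seed: int, outdir: Path, log,
                base: Optional[Path] = None) -> dict:
    paths = [_resolve(base, p, outdir) for p in cfg.get("inputs", [])]
    if not paths:
        raise ValidationError("phase: 'inputs' must list structure-factor CSVs")
    for p in paths:
        if not Path(p).exists():
            raise ValidationError(f"phase: missing input file '{p}'")
    sets = [read_structure_factors(p) for p in paths]
    series = ContrastSeries(sets=sets)
    result = phase_by_contrast(series, axis=cfg.get("axis", "d2o"))
    outs = []
    for s in result.sets:
        p = outdir / f"signed_x{s.d2o_fraction:g}_d7{s.d7_fraction:g}.csv"
        write_structure_factors(s, p)
        outs.append(str(p))
    labeled = [_resolve(base, p, outdir) for p in cfg.get("labeled_inputs", [])]
    lab_outs = []
    if labeled:
        lab_sets = [read_structure_factors(p) for p in labeled]
        base_set = min(result.sets, key=lambda s: s.d2o_fraction)
        res2 = phase_by_contrast(ContrastSeries(sets=[base_set] + lab_sets),
                                 axis="d7")
        for s in res2.sets[1:]:
            p = outdir / f"signed_x{s.d2o_fraction:g}_d7{s.d7_fraction:g}.csv"
            write_structure_factors(s, p)
            lab_outs.append(str(p))
    rep = {"flagged": bool(result.ambiguous),
           "inputs": [str(p) for p in paths + labeled],
           "input_sha256": {str(p): _sha256(Path(p)) for p in paths + labeled},
           "signs": np.asarray(result.signs).tolist(),
           "ambiguous": bool(result.ambiguous),
           "diagnostics": result.diagnostics,
           "outputs": outs + lab_outs}
    log.info("phase: %d sets, ambiguous=%s", len(paths) + len(labeled), result.ambiguous)
    return rep


def stage_profile(cfg: dict, seed: int, outdir: Path, log,
                  base: Optional[Path] = None) -> dict:
    paths = [_resolve(base, p, outdir) for p in cfg.get("inputs", [])]
    if not paths:
        raise ValidationError("profile: 'inputs' must list signed structure-factor CSVs")
    outs, fits = [], {}
    for p in paths:
        if not Path(p).exists():
            raise ValidationError(f"profile: missing input file '{p}'")
        s = read_structure_factors(p)
        prof = fourier_synthesis(s, n_grid=int(cfg.get("n_grid", 512)))
        out = outdir / (Path(p).stem + "_profile.txt")
        write_profile(prof, out)
        outs.append(str(out))
        model_cfg = cfg.get("components")
        if model_cfg:
            model = [ComponentSpec(center=float(c["center_angstrom"]),
                                   fwhm=float(c["fwhm_angstrom"]),
                                   area=float(c.get("area", 0.01)),
                                   pair_constraint=bool(c.get("pair", False)),
                                   vary_center=bool(c.get("vary_center", True)))
                     for c in model_cfg]
            comps, info = fit_gaussian_components(prof, model)
            fits[str(p)] = {"components": [dataclasses.asdict(c) for c in comps],
                            "info": {k: v for k, v in info.items()
                                     if isinstance(v, (int, float, bool, str))}}
    rep = {"flagged": False, "outputs": outs, "fits": fits,
           "input_sha256": {str(p): _sha256(Path(p)) for p in paths}}
    log.info("profile: synthesized %d profile(s)", len(outs))
    return rep


def stage_water(cfg: dict, seed: int, outdir: Path, log,
                base: Optional[Path] = None) -> dict:
    for key in ("base", "high", "labeled"):
        if key not in cfg:
            raise ValidationError(f"water: missing required key '{key}'")
    p_base = _resolve(base, cfg["base"], outdir)
    p_high = _resolve(base, cfg["high"], outdir)
    p_lab = _resolve(base, cfg["labeled"], outdir)
    for p in (p_base, p_high, p_lab):
        if not Path(p).exists():
            raise ValidationError(f"water: missing input file '{p}'")
    s_base = read_structure_factors(p_base)
    s_high = read_structure_factors(p_high)
    s_lab = read_structure_factors(p_lab)
    for s in (s_base, s_high, s_lab):
        if not s.signed:
            raise ValidationError("water: inputs must be signed (run phase first)")
    lab_diff = deuterium_difference(fourier_synthesis(s_lab), fourier_synthesis(s_base))
    scale, cal_info = calibrate_amplitude(
        lab_diff, label_fraction=float(cfg.get("label_fraction", s_lab.d7_fraction)),
        n_deuterons=int(cfg.get("n_deuterons", 7)))
    wdiff = deuterium_difference(fourier_synthesis(s_high), fourier_synthesis(s_base))
    d = s_base.d
    model = [ComponentSpec(center=d / 2.0, fwhm=14.0,
                           area=float(np.max(wdiff.rho)) * 14.0, vary_center=False),
             ComponentSpec(center=0.0, fwhm=12.0,
                           area=float(wdiff.rho[np.argmin(np.abs(wdiff.z))]) * 12.0,
                           vary_center=False)]
    comps, fit_info = fit_gaussian_components(wdiff, model)
    B = scale * float(sum(c.total_area() for c in comps))
    quant_in = WaterQuantification(
        waters_per_lipid_baseline=float(cfg.get("waters_per_lipid", 9.4)),
        exchangeable_protons_per_peptide=float(cfg.get("exchangeable_protons", 57.0)),
        peptide_per_lipid=float(cfg.get("peptide_per_lipid", 1.0 / 25.0)))
    quant = waters_per_peptide(
        B, x=float(cfg.get("d2o_fraction", s_high.d2o_fraction)),
        quant=quant_in)
    rep = {"flagged": bool(quant.flagged_negative or fit_info["flagged"]),
           "scale": scale, "exchanged_sl_per_lipid": B,
           "waters_per_peptide": quant.waters_per_peptide,
           "waters_per_peptide_sd": quant.waters_per_peptide_sd,
           "calibration": {"measured_integral": cal_info["measured_integral"],
                           "expected_integral": cal_info["expected_integral"]},
           "input_sha256": {str(p): _sha256(Path(p))
                            for p in (p_base, p_high, p_lab)}}
    log.info("water: %.1f waters/peptide (sd %.1f)",
             quant.waters_per_peptide, quant.waters_per_peptide_sd)
    return rep


def stage_shells(cfg: dict, seed: int, outdir: Path, log,
                 base: Optional[Path] = None) -> dict:
    path = _resolve(base, cfg.get("frames_xyz", outdir / "frames.xyz"), outdir)
    if not Path(path).exists():
        raise ValidationError(f"shells: missing input file '{path}'")
    frames = read_xyz_frames(
        path,
        solute_labels=tuple(cfg.get("solute_labels", ("P",))),
        water_labels=tuple(cfg.get("water_labels", ("O",))))
    g = radial_distribution(frames,
                            r_max=float(cfg.get("r_max_angstrom", 9.0)),
                            bin_width=float(cfg.get("bin_width_angstrom", 0.1)),
                            seed=seed)
    radii, radii_sd, flagged = shell_boundaries(g, n_shells=int(cfg.get("n_shells", 3)))
    summaries = count_waters_in_shells(frames, radii) if radii else []
    gpath = outdir / "gofr.txt"
    with open(gpath, "w") as fh:
        fh.write("# r_angstrom g g_sd\n")
        for r, gg, sd in zip(g.r, g.g, g.g_sd):
            fh.write(f"{r:.4f} {gg:.6f} {sd:.6f}\n")
    rep = {"flagged": bool(flagged), "gofr": str(gpath),
           "boundaries_angstrom": list(map(float, radii)),
           "boundaries_sd": list(map(float, radii_sd)),
           "shells": [dataclasses.asdict(s) for s in summaries],
           "input_sha256": {str(path): _sha256(Path(path))}}
    log.info("shells: boundaries %s", np.round(radii, 2).tolist())
    return rep


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "fit-binding": stage_fit_binding,
    "reduce-diffraction": stage_reduce,
    "phase": stage_phase,
    "profile": stage_profile,
    "water": stage_water,
    "shells": stage_shells,
}


def write_report(outdir: Path) -> dict:
    """Aggregate every per-stage JSON in ``outdir`` into report.json."""
    bundle: dict = {"version": __version__, "stages": {}}
    fatal = False
    for p in sorted(Path(outdir).glob("stage_*.json")):
        name = p.stem.replace("stage_", "", 1)
        with open(p) as fh:
            rep = json.load(fh)
        bundle["stages"][name] = rep
        fatal = fatal or bool(rep.get("flagged"))
    bundle["any_flagged"] = fatal
    _dump(bundle, Path(outdir) / "report.json")
    return bundle


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in dependency order; return the bundle."""
    order = [s for s in STAGES if s in config.stages]
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log = _setup_logging(outdir, config.log_level)
    with open(outdir / "resolved_config.yaml", "w") as fh:
        yaml.safe_dump(config.resolved(), fh, sort_keys=True)
    log.info("lamella %s seed=%d stages=%s", __version__, config.seed, order)
    base = config.source_path.parent if config.source_path else None
    for name in order:
        if name == "report":
            continue
        cfg = config.sections.get(name) or {}
        func = _STAGE_FUNCS[name]
        if name == "simulate":
            rep = func(cfg, config.seed, outdir, log)
        else:
            rep = func(cfg, config.seed, outdir, log, base=base)
        _dump(rep, outdir / f"stage_{name}.json")
    bundle = write_report(outdir)
    return bundle
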