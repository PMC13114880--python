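"""End-to-end analysis runs: manifest-driven chains and report assembly.

Every report is a plain dict with ``"schema": 1`` and explicit units, so
it serializes directly to JSON and regenerates bit-identically from the
same config + inputs + seed.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

from . import binding, fret, spectra, thermo, wham
from .errors import InputError, ValidationError

SCHEMA_VERSION = 1


def load_config(path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise InputError(f"{path}: config must be a key/value mapping")
    return cfg


def _file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _provenance(paths) -> dict:
    return {str(p): _file_sha256(p) for p in paths}


def _read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"file", "q_conc_M", "temperature_K", "a_ex", "a_em"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: manifest missing columns {sorted(missing)}")
    if df.empty:
        raise ValidationError(f"{path}: manifest is empty")
    return df


def _series_from_manifest(df: pd.DataFrame, base_dir: Path) -> dict:
    """Per-temperature inner-filter-corrected titration series."""
    out = {}
    for temp, group in df.groupby("temperature_K"):
        group = group.sort_values("q_conc_M")
        points = []
        for row in group.itertuples():
            spec = spectra.read_spectrum(base_dir / row.file, kind="emission")
            corrected = binding.correct_inner_filter(spec.intensity, row.a_ex, row.a_em)
            points.append(
                (row.q_conc_M, spectra.Spectrum(spec.axis, corrected, "emission"))
            )
        out[float(temp)] = binding.TitrationSeries(points=tuple(points), temperature=float(temp))
    return out


def run_binding_chain(config: dict) -> dict:
    """Stern-Volmer + double-log fits per temperature, mechanism call, and
    (given >= 2 temperatures) the van't Hoff thermodynamics."""
    manifest_path = Path(config["manifest"])
    base_dir = Path(config.get("base_dir", manifest_path.parent))
    qcfg = binding.QuenchConfig(**config.get("quench", {}))
    em_window = tuple(config["em_window"]) if "em_window" in config else None

    df = _read_manifest(manifest_path)
    series_by_T = _series_from_manifest(df, base_dir)
    temps = sorted(series_by_T)

    quench_fits, binding_fits = [], []
    for t in temps:
        quench_fits.append(binding.stern_volmer_fit(series_by_T[t], qcfg, em_window))
        binding_fits.append(binding.double_log_fit(series_by_T[t], em_window))

    report = {
        "schema": SCHEMA_VERSION,
        "inputs": _provenance([manifest_path]),
        "temperatures_K": temps,
        "stern_volmer": [
            {
                "temperature_K": f.temperature,
                "ksv_L_per_mol": f.ksv,
                "kq_L_per_mol_s": f.kq,
                "intercept": f.intercept,
                "r_squared": f.r_squared,
                "no_quenching": f.no_quenching,
            }
            for f in quench_fits
        ],
        "double_log": [
            {
                "temperature_K": f.temperature,
                "ka_L_per_mol": f.ka,
                "n_sites": f.n,
                "r_squared": f.r_squared,
            }
            for f in binding_fits
        ],
    }
    if len(temps) >= 2:
        mech = binding.classify_mechanism(quench_fits, qcfg)
        report["mechanism"] = {"label": mech.label.value, "evidence": mech.evidence}
        tres = thermo.vant_hoff_fit({f.temperature: f.ka for f in binding_fits})
        report["thermodynamics"] = thermo_report(tres)
    else:
        report["notice"] = (
            "single temperature: mechanism call and van't Hoff analysis require >= 2"
        )
    return report


def thermo_report(tres: thermo.ThermoResult) -> dict:
    return {
        "delta_h_kJ_per_mol": tres.delta_h,
        "delta_s_J_per_mol_K": tres.delta_s,
        "delta_h_stderr_kJ_per_mol": tres.delta_h_stderr,
        "delta_s_stderr_J_per_mol_K": tres.delta_s_stderr,
        "delta_g_kJ_per_mol_by_T": {str(k): v for k, v in tres.delta_g_by_T.items()},
        "delta_g_from_ka_kJ_per_mol_by_T": {
            str(k): v for k, v in tres.delta_g_from_ka.items()
        },
        "r_squared": tres.r_squared,
        "force_label": tres.force_label.value,
    }


def run_thermo(config: dict) -> dict:
    """Van't Hoff analysis from a (temperature_K, ka) table (TSV/CSV/JSON)."""
    path = Path(config["ka_table"])
    if path.suffix == ".json":
        with open(path) as fh:
            ka_by_T = {float(k): float(v) for k, v in json.load(fh).items()}
    else:
        df = pd.read_csv(path, sep=None, engine="python")
        ka_by_T = dict(zip(df["temperature_K"].astype(float), df["ka"].astype(float)))
    tres = thermo.vant_hoff_fit(ka_by_T)
    return {"schema": SCHEMA_VERSION, "inputs": _provenance([path]), **thermo_report(tres)}


def run_fret(config: dict) -> dict:
    """Overlap integral -> Förster radius -> efficiency -> distance."""
    donor_path = Path(config["donor"])
    acceptor_path = Path(config["acceptor"])
    donor = spectra.read_spectrum(donor_path, kind="emission")
    acceptor = spectra.read_spectrum(acceptor_path, kind="absorbance")
    warn = None
    if float(acceptor.intensity.max()) < 10.0:
        warn = (
            "acceptor maximum < 10: values look like absorbance, not molar "
            "absorptivity (L/mol/cm); J will be off by the concentration factor"
        )
    constants = fret.FretConstants(**config.get("constants", {}))
    res = fret.fret_analysis(donor, acceptor, config["f0"], config["f"], constants)
    report = {
        "schema": SCHEMA_VERSION,
        "inputs": _provenance([donor_path, acceptor_path]),
        "j_cm3_L_per_mol": res.j,
        "efficiency": res.e,
        "r0_nm": res.r0,
        "r_nm": res.r,
        "constants": {"k2": constants.k2, "n_refr": constants.n_refr, "phi": constants.phi},
    }
    if warn:
        report["warning"] = warn
    return report


def run_sites(config: dict) -> dict:
    """Site assignment from displacement curves (CSV: probe, probe_conc_M,
    displacement_pct)."""
    path = Path(config["displacement_table"])
    df = pd.read_csv(path)
    curves = []
    for probe, group in df.groupby("probe", sort=False):
        group = group.sort_values("probe_conc_M")
        curves.append(
            binding.DisplacementCurve(
                probe=probe,
                points=tuple(zip(group["probe_conc_M"], group["displacement_pct"])),
            )
        )
    result = binding.assign_site(
        curves,
        drop_threshold_pct=config.get("drop_threshold_pct", 15.0),
        trend_min_points=config.get("trend_min_points", 3),
    )
    return {
        "schema": SCHEMA_VERSION,
        "inputs": _provenance([path]),
        "site": result.site,
        "verdicts": result.verdicts,
    }


def run_wham(config: dict) -> dict:
    """WHAM PMF from window files, with overlap warnings and the barrier."""
    paths = [Path(p) for p in config["windows"]]
    windows = [wham.read_window(p) for p in paths]
    grid = None
    if "grid" in config:
        g = config["grid"]
        grid = wham.GridSpec(g["lo"], g["hi"], g.get("n_bins", 200))
    temperature = config.get("temperature_K", 300.0)
    profile = wham.wham_solve(
        windows,
        grid,
        temperature_K=temperature,
        tol=config.get("tol", 1e-6),
        max_iter=config.get("max_iter", 100000),
    )
    if config.get("n_boot", 0):
        profile = wham.bootstrap_pmf(
            windows, grid, temperature_K=temperature,
            n_boot=config["n_boot"], seed=config.get("seed"),
        )
    _, overlap_notes = wham.histogram_overlap(windows, grid)
    barrier_kj, barrier_kcal = wham.pmf_barrier(profile)
    return {
        "schema": SCHEMA_VERSION,
        "inputs": _provenance(paths),
        "temperature_K": temperature,
        "bin_width_nm": profile.bin_width,
        "n_iterations": profile.n_iterations,
        "grid_nm": profile.grid.tolist(),
        "pmf_kJ_per_mol": profile.free_energy.tolist(),
        "error_band_kJ_per_mol": (
            None if profile.error_band is None else profile.error_band.tolist()
        ),
        "window_free_energies_kJ_per_mol": profile.window_free_energies.tolist(),
        "adjacent_overlap": profile.overlap_matrix.tolist(),
        "overlap_warnings": overlap_notes,
        "barrier_kJ_per_mol": barrier_kj,
        "barrier_kcal_per_mol": barrier_kcal,
    }


def write_report(report: dict, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")


def binding_tables(report: dict) -> str:
    """Human-readable per-temperature tables (quenching / binding / thermo)."""
    lines = ["T_K\tKsv_L_mol\tkq_L_mol_s\tR2"]
    for row in report["stern_volmer"]:
        lines.append(
            f"{row['temperature_K']:.0f}\t{row['ksv_L_per_mol']:.4g}"
            f"\t{row['kq_L_per_mol_s']:.4g}\t{row['r_squared']:.4f}"
        )
    lines.append("")
    lines.append("T_K\tKa_L_mol\tn\tR2")
    for row in report["double_log"]:
        lines.append(
            f"{row['temperature_K']:.0f}\t{row['ka_L_per_mol']:.4g}"
            f"\t{row['n_sites']:.3f}\t{row['r_squared']:.4f}"
        )
    if "thermodynamics" in report:
        th = report["thermodynamics"]
        lines.append("")
        lines.append("T_K\tdH_kJ_mol\tdS_J_mol_K\tdG_kJ_mol")
        for t, dg in th["delta_g_kJ_per_mol_by_T"].items():
            lines.append(
                f"{float(t):.0f}\t{th['delta_h_kJ_per_mol']:.2f}"
                f"\t{th['delta_s_J_per_mol_K']:.1f}\t{dg:.2f}"
            )
    return "\n".join(lines) + "\n"
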