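"""End-to-end characterization of one compound.

``run_characterization`` composes the analysis stages the way a full
photophysical workup proceeds: ground-state pKa from a titration (or given
directly), 0-0 transition energies from absorption/emission maxima (or given
directly), Forster-cycle pKa*, optional Lippert-Mataga dipole analysis, and
lifetime/quantum-yield rate decomposition with the H2O/D2O ESPT bound.

The configuration is a plain dict (typically loaded from YAML) with known
top-level sections only; every physical quantity can be supplied either as a
measured file to be fitted or as a literal value.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .errors import ConfigError
from .forster import ForsterInput, excited_pKa, nu00_estimate
from .io import read_decay, read_solvent_table, read_spectrum, read_titration_manifest
from .kinetics import espt_rate_lower_bound, fit_monoexponential, rate_decomposition
from .solvatochromism import analyze_solvent_series
from .spectra import nm_to_wavenumber
from .titration import fit_single_equilibrium

_KNOWN_SECTIONS = {"titration", "forster", "lippert", "kinetics", "label"}


def _forster_stage(cfg: dict, pka: float | None, temperature: float) -> dict:
    if "nu00_base" in cfg and "nu00_acid" in cfg:
        nu_b, nu_bh = float(cfg["nu00_base"]), float(cfg["nu00_acid"])
    elif {"abs_max_nm_base", "em_max_nm_base",
          "abs_max_nm_acid", "em_max_nm_acid"} <= cfg.keys():
        nu_b = nu00_estimate(nm_to_wavenumber(cfg["abs_max_nm_base"]),
                             nm_to_wavenumber(cfg["em_max_nm_base"]))
        nu_bh = nu00_estimate(nm_to_wavenumber(cfg["abs_max_nm_acid"]),
                              nm_to_wavenumber(cfg["em_max_nm_acid"]))
    else:
        raise ConfigError("forster section needs nu00_base/nu00_acid or the "
                          "four abs/em maxima in nm")
    if pka is None:
        raise ConfigError("forster stage needs a ground-state pKa (titration "
                          "section or forster.pka)")
    res = excited_pKa(ForsterInput(pka, nu_b, nu_bh, temperature))
    return {"nu00_base_cm": nu_b, "nu00_acid_cm": nu_bh,
            "pKa_excited": res.pKa_excited, "delta_pKa": res.delta_pKa}


def _kinetics_stage(cfg: dict, base: Path) -> dict:
    out: dict = {}

    def tau_phi(block: dict) -> tuple[float, float]:
        if "decay_file" in block:
            fit = fit_monoexponential(read_decay(base / block["decay_file"]),
                                      fit_window=tuple(block["fit_window"])
                                      if "fit_window" in block else None)
            tau = fit.tau
            out.setdefault("decay_fits", {})[block.get("name", "decay")] = {
                "tau_ns": fit.tau, "tau_se_ns": fit.tau_se,
                "chi2_reduced": fit.chi2_reduced}
        else:
            tau = float(block["tau_ns"])
        return tau, float(block["phi"])

    h2o = cfg.get("h2o") or cfg
    tau, phi = tau_phi(h2o)
    rates = rate_decomposition(phi, tau)
    out["h2o"] = {"tau_ns": tau, "phi": phi, "k_r": rates.k_r,
                  "k_nr": rates.k_nr}
    if "d2o" in cfg:
        tau_d, phi_d = tau_phi(cfg["d2o"])
        rates_d = rate_decomposition(phi_d, tau_d)
        out["d2o"] = {"tau_ns": tau_d, "phi": phi_d, "k_r": rates_d.k_r,
                      "k_nr": rates_d.k_nr}
        bound = espt_rate_lower_bound(rates, rates_d)
        out["espt"] = {"k_espt_lower_s": bound.k_espt_lower,
                       "no_isotope_effect": bound.no_isotope_effect}
    return out


def run_characterization(config: dict, base_dir=".", out_path=None) -> dict:
    """Run the configured stages and return (optionally write) the report.

    The report carries full-precision values in machine-readable form plus a
    ``display`` block with table-style rounding (pKa to 2 decimals, rates
    scaled by 1e8 s^-1 with 2 decimals).
    """
    if not isinstance(config, dict) or not config:
        raise ConfigError("empty or invalid characterization config")
    unknown = set(config) - _KNOWN_SECTIONS
    if unknown:
        raise ConfigError(f"unknown config sections: {sorted(unknown)}")
    base = Path(base_dir)
    report: dict = {"label": config.get("label", "compound")}
    pka = None
    if "titration" in config:
        tcfg = config["titration"]
        if "manifest" in tcfg:
            series = read_titration_manifest(base / tcfg["manifest"])
            fit = fit_single_equilibrium(
                series,
                pKa_bounds=tuple(tcfg["pka_bounds"]) if "pka_bounds" in tcfg else None,
                assume_isosbestic_excitation=tcfg.get(
                    "assume_isosbestic_excitation", False))
            pka = float(fit.pKa_estimates[0])
            report["titration"] = {"pKa": pka,
                                   "pKa_se": float(fit.pKa_se[0]),
                                   "residual_rms": float(fit.residual_rms)}
        elif "pka" in tcfg:
            pka = float(tcfg["pka"])
            report["titration"] = {"pKa": pka}
        else:
            raise ConfigError("titration section needs 'manifest' or 'pka'")
    if "forster" in config:
        fcfg = config["forster"]
        report["forster"] = _forster_stage(
            fcfg, pka if pka is not None else fcfg.get("pka"),
            float(fcfg.get("temperature", 298.0)))
    if "lippert" in config:
        lcfg = config["lippert"]
        table = (read_solvent_table(base / lcfg["solvent_table"])
                 if "solvent_table" in lcfg else None)
        pairs = {}
        for name, files in lcfg["pairs"].items():
            pairs[name] = (read_spectrum(base / files["absorption"]),
                           read_spectrum(base / files["emission"]))
        lfit = analyze_solvent_series(pairs, float(lcfg["a0_angstrom"]), table)
        report["lippert"] = {"slope_cm": lfit.slope, "slope_se_cm": lfit.slope_se,
                             "intercept_cm": lfit.intercept, "r": lfit.r,
                             "delta_mu_debye": lfit.delta_mu,
                             "delta_mu_se_debye": lfit.delta_mu_se}
    if "kinetics" in config:
        report["kinetics"] = _kinetics_stage(config["kinetics"], base)
    report["display"] = _display_block(report)
    if out_path is not None:
        with open(out_path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(report, fh, sort_keys=False)
    return report


def _display_block(report: dict) -> dict:
    """Table-style rounding: pKa 2 decimals, rates in 1e8 s^-1 with 2 decimals."""
    disp: dict = {}
    if "titration" in report:
        disp["pKa"] = round(report["titration"]["pKa"], 2)
    if "forster" in report:
        disp["pKa_excited"] = round(report["forster"]["pKa_excited"], 2)
        disp["delta_pKa"] = round(report["forster"]["delta_pKa"], 2)
    if "lippert" in report:
        disp["slope_cm"] = round(report["lippert"]["slope_cm"], 0)
        disp["delta_mu_debye"] = round(report["lippert"]["delta_mu_debye"], 1)
    if "kinetics" in report:
        for sol in ("h2o", "d2o"):
            if sol in report["kinetics"]:
                blk = report["kinetics"][sol]
                disp[f"{sol}_tau_ns"] = round(blk["tau_ns"], 2)
                disp[f"{sol}_k_r_1e8"] = round(blk["k_r"] / 1e8, 2)
                disp[f"{sol}_k_nr_1e8"] = round(blk["k_nr"] / 1e8, 2)
        if "espt" in report["kinetics"]:
            disp["k_espt_lower_1e8"] = round(
                report["kinetics"]["espt"]["k_espt_lower_s"] / 1e8, 2)
    return disp
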