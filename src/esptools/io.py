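"""Readers and writers for the package's plain-text formats.

Formats
-------
Spectrum CSV
    header ``wavelength_nm,value`` (or ``wavenumber_cm-1,value``); optional
    ``#``-prefixed metadata lines before the header, ``# key: value``.
Decay CSV
    header ``time_ns,counts``.
Solvent table CSV
    header ``name,epsilon_r,n``.
Titration manifest (YAML)
    ``path_length_cm``, ``total_conc_M``, ``response_kind`` and a
    ``spectra:`` list of ``{ph: <float>, file: <spectrum csv>}`` entries,
    file paths relative to the manifest.

All round-trips are lossless to the printed precision (full ``repr``
precision is written).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from .errors import ParseError
from .kinetics import DecayHistogram
from .solvatochromism import SolventRecord
from .spectra import (ABSORBANCE, Spectrum, WAVELENGTH_NM,
                      WAVENUMBER_CM, resample_to_common_axis)
from .titration import SpeciationFit, TitrationSeries

_SPECTRUM_HEADERS = {"wavelength_nm": WAVELENGTH_NM,
                     "wavenumber_cm-1": WAVENUMBER_CM}


def _read_table(path, expected_first: list[str], expected_second: str):
    """Parse a two-column numeric CSV with optional # metadata lines."""
    path = Path(path)
    meta: dict[str, str] = {}
    rows: list[tuple[float, float]] = []
    header = None
    first_kind = None
    with open(path, "r", encoding="utf-8") as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if ":" in body:
                    k, v = body.split(":", 1)
                    meta[k.strip()] = v.strip()
                continue
            if header is None:
                header = [c.strip() for c in line.split(",")]
                if len(header) != 2 or header[0] not in expected_first \
                        or header[1] != expected_second:
                    raise ParseError(
                        f"{path.name}:{ln}: expected header "
                        f"'<{'|'.join(expected_first)}>,{expected_second}', "
                        f"got {line!r}")
                first_kind = header[0]
                continue
            cells = line.split(",")
            if len(cells) != 2:
                raise ParseError(f"{path.name}:{ln}: expected 2 columns")
            try:
                rows.append((float(cells[0]), float(cells[1])))
            except ValueError:
                raise ParseError(f"{path.name}:{ln}: non-numeric cell in "
                                 f"{line!r}") from None
    if header is None or not rows:
        raise ParseError(f"{path.name}: no data rows found")
    arr = np.array(rows)
    return arr[:, 0], arr[:, 1], first_kind, meta


def read_spectrum(path) -> Spectrum:
    """Read a Spectrum CSV; ``# signal_kind: emission_intensity`` switches kind."""
    axis, signal, axis_header, meta = _read_table(
        path, list(_SPECTRUM_HEADERS), "value")
    signal_kind = meta.pop("signal_kind", ABSORBANCE)
    label = meta.pop("label", Path(path).stem)
    return Spectrum(axis, signal, _SPECTRUM_HEADERS[axis_header], signal_kind,
                    label=label, meta=meta)


def write_spectrum(spec: Spectrum, path) -> None:
    header = {v: k for k, v in _SPECTRUM_HEADERS.items()}[spec.axis_kind]
    with open(path, "w", encoding="utf-8") as fh:
        if spec.label:
            fh.write(f"# label: {spec.label}\n")
        fh.write(f"# signal_kind: {spec.signal_kind}\n")
        for k, v in spec.meta.items():
            fh.write(f"# {k}: {v}\n")
        fh.write(f"{header},value\n")
        for a, s in zip(spec.axis, spec.signal):
            fh.write(f"{float(a)!r},{float(s)!r}\n")


def read_decay(path) -> DecayHistogram:
    t, c, _, meta = _read_table(path, ["time_ns"], "counts")
    return DecayHistogram(t, c, meta=meta)


def write_decay(decay: DecayHistogram, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for k, v in decay.meta.items():
            fh.write(f"# {k}: {v}\n")
        fh.write("time_ns,counts\n")
        for t, c in zip(decay.time_bins, decay.counts):
            fh.write(f"{float(t)!r},{float(c)!r}\n")


def read_solvent_table(path) -> dict[str, SolventRecord]:
    path = Path(path)
    table: dict[str, SolventRecord] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            cells = [c.strip() for c in line.split(",")]
            if ln == 1 or cells[0] == "name":
                if cells != ["name", "epsilon_r", "n"]:
                    raise ParseError(f"{path.name}:{ln}: expected header "
                                     "'name,epsilon_r,n'")
                continue
            if len(cells) != 3:
                raise ParseError(f"{path.name}:{ln}: expected 3 columns")
            try:
                table[cells[0]] = SolventRecord(cells[0], float(cells[1]),
                                                float(cells[2]))
            except ValueError:
                raise ParseError(f"{path.name}:{ln}: non-numeric cell") from None
    if not table:
        raise ParseError(f"{path.name}: no solvent rows found")
    return table


def write_solvent_table(table: dict[str, SolventRecord], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("name,epsilon_r,n\n")
        for rec in table.values():
            fh.write(f"{rec.name},{float(rec.epsilon_r)!r},{float(rec.n)!r}\n")


def read_titration_manifest(path) -> TitrationSeries:
    """Load a titration manifest and assemble the series on a common axis."""
    path = Path(path)
    try:
        with open(path, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        raise ParseError(f"{path.name}: invalid YAML: {exc}") from None
    if not isinstance(doc, dict) or "spectra" not in doc or not doc["spectra"]:
        raise ParseError(f"{path.name}: manifest needs a non-empty 'spectra' list")
    ph, spectra = [], []
    for i, entry in enumerate(doc["spectra"]):
        if "ph" not in entry or "file" not in entry:
            raise ParseError(f"{path.name}: spectra[{i}] needs 'ph' and 'file'")
        fpath = path.parent / entry["file"]
        if not fpath.exists():
            raise ParseError(f"{path.name}: file for pH {entry['ph']} not "
                             f"found: {entry['file']}")
        ph.append(float(entry["ph"]))
        spectra.append(read_spectrum(fpath))
    if len(set(ph)) != len(ph):
        raise ParseError(f"{path.name}: duplicate pH values in manifest")
    axis, matrix = resample_to_common_axis(spectra)
    return TitrationSeries(
        np.array(ph), matrix, axis,
        path_length=float(doc.get("path_length_cm", 1.0)),
        total_conc=float(doc.get("total_conc_M", 1e-5)),
        response_kind=doc.get("response_kind", ABSORBANCE))


def write_titration(series: TitrationSeries, out_dir, stem: str = "spectrum") -> Path:
    """Write a series as per-pH Spectrum CSVs plus a manifest; returns manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, ph in enumerate(series.pH_values):
        fname = f"{stem}_{i:02d}.csv"
        write_spectrum(Spectrum(series.axis, series.response_matrix[i],
                                WAVELENGTH_NM, series.response_kind,
                                label=f"pH {ph:g}"),
                       out_dir / fname)
        entries.append({"ph": float(ph), "file": fname})
    manifest = {"path_length_cm": series.path_length,
                "total_conc_M": series.total_conc,
                "response_kind": series.response_kind,
                "spectra": entries}
    mpath = out_dir / "manifest.yaml"
    with open(mpath, "w", encoding="utf-8") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return mpath


def write_fit_report(fit: SpeciationFit, out_dir, ph_grid=None) -> Path:
    """Write a speciation-fit report: YAML summary, component-spectra CSV and
    a species-distribution CSV; returns the YAML path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary = {"pKa": [float(x) for x in fit.pKa_estimates],
               "pKa_se": [float(x) for x in fit.pKa_se],
               "residual_rms": float(fit.residual_rms),
               "n_species": int(fit.component_spectra.shape[0])}
    ypath = out_dir / "fit.yaml"
    with open(ypath, "w", encoding="utf-8") as fh:
        yaml.safe_dump(summary, fh, sort_keys=False)
    with open(out_dir / "component_spectra.csv", "w", encoding="utf-8") as fh:
        names = [f"species_{j}" for j in range(fit.component_spectra.shape[0])]
        fh.write("wavelength_nm," + ",".join(names) + "\n")
        for i, lam in enumerate(fit.axis):
            vals = ",".join(f"{v:.8g}" for v in fit.component_spectra[:, i])
            fh.write(f"{lam:g},{vals}\n")
    if ph_grid is None:
        lo = float(fit.pKa_estimates.min()) - 2.5
        hi = float(fit.pKa_estimates.max()) + 2.5
        ph_grid = np.linspace(lo, hi, 101)
    frac = fit.species_distribution(np.asarray(ph_grid, dtype=float))
    with open(out_dir / "species_distribution.csv", "w", encoding="utf-8") as fh:
        names = [f"fraction_{j}" for j in range(frac.shape[1])]
        fh.write("pH," + ",".join(names) + "\n")
        for ph, row in zip(ph_grid, frac):
            fh.write(f"{ph:.4f}," + ",".join(f"{v:.6f}" for v in row) + "\n")
    return ypath
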