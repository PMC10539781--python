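"""Readers and writers for the package's plain-text formats.

Formats
-------
species table
    Tab-separated, header ``species\tnucleus\tAiso_MHz``, one row per
    nucleus; ``#`` comment lines allowed.  A companion YAML file carries
    per-species metadata: ``g_iso``, ``role`` and an optional
    ``protonation_label``.
peak list
    Tab-separated, header
    ``species\tnucleus\tshift_ppm\trel_intensity\tsignificant``.
spectrum
    Two columns (ppm, amplitude), whitespace-separated, ``#`` header lines
    carrying metadata as ``key=value``.

All round-trip at the stored precision; malformed lines are reported with
their line number.
"""

from __future__ import annotations

import io as _io
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .species import (
    HyperfineTable,
    RadicalSpecies,
    ResonanceObservation,
    canonical_nucleus,
)
from .spectrum import Spectrum

__all__ = [
    "fixture_paths",
    "read_species_table",
    "write_species_table",
    "read_peak_list",
    "write_peak_list",
    "read_spectrum",
    "write_spectrum",
    "write_report",
]

_SPECIES_COLUMNS = ["species", "nucleus", "Aiso_MHz"]
_PEAK_COLUMNS = ["species", "nucleus", "shift_ppm", "rel_intensity", "significant"]


class FormatError(ValueError):
    """Malformed input file; message carries the path and line context."""


def fixture_paths() -> dict[str, Path]:
    """Paths of the packaged TML species table, metadata and peak list."""
    root = Path(__file__).parent / "data"
    return {
        "species_table": root / "tml_species.tsv",
        "species_meta": root / "tml_species_meta.yaml",
        "peak_list": root / "tml_peaks.tsv",
    }


def _read_table(path, columns) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"{path}: cannot parse: {exc}") from exc
    if list(df.columns) != columns:
        raise FormatError(
            f"{path}: expected header {columns}, found {list(df.columns)}"
        )
    return df


def read_species_table(
    table_path, meta_path
) -> list[RadicalSpecies]:
    """Load radical species from a couplings table plus a metadata YAML."""
    df = _read_table(table_path, _SPECIES_COLUMNS)
    with open(meta_path) as fh:
        meta = yaml.safe_load(fh) or {}
    couplings: dict[str, dict[str, float]] = {}
    for i, row in df.iterrows():
        name = str(row["species"]).strip()
        nucleus = canonical_nucleus(str(row["nucleus"]))
        try:
            aiso = float(row["Aiso_MHz"])
        except ValueError as exc:
            raise FormatError(
                f"{table_path}: line {i + 2}: non-numeric Aiso {row['Aiso_MHz']!r}"
            ) from exc
        if nucleus in couplings.get(name, {}):
            raise FormatError(
                f"{table_path}: line {i + 2}: duplicate nucleus {nucleus!r} "
                f"for species {name!r}"
            )
        couplings.setdefault(name, {})[nucleus] = aiso
    species = []
    for name, table in couplings.items():
        if name not in meta:
            raise FormatError(f"{meta_path}: missing metadata for species {name!r}")
        m = meta[name]
        species.append(
            RadicalSpecies(
                name=name,
                g_iso=float(m["g_iso"]),
                hyperfine=HyperfineTable(table),
                role=str(m["role"]),
                protonation_label=str(m.get("protonation_label", "")),
            )
        )
    return species


def write_species_table(species: list[RadicalSpecies], table_path, meta_path) -> None:
    rows = [
        {"species": sp.name, "nucleus": n, "Aiso_MHz": _fmt(a)}
        for sp in species
        for n, a in sp.hyperfine.items()
    ]
    pd.DataFrame(rows, columns=_SPECIES_COLUMNS).to_csv(table_path, sep="\t", index=False)
    meta = {
        sp.name: {
            "g_iso": sp.g_iso,
            "role": sp.role,
            "protonation_label": sp.protonation_label,
        }
        for sp in species
    }
    with open(meta_path, "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)


def read_peak_list(path) -> list[ResonanceObservation]:
    df = _read_table(path, _PEAK_COLUMNS)
    seen: set[tuple[str, str]] = set()
    observations = []
    for i, row in df.iterrows():
        key = (str(row["species"]).strip(), canonical_nucleus(str(row["nucleus"])))
        if key in seen:
            raise FormatError(
                f"{path}: line {i + 2}: duplicate (species, nucleus) {key}"
            )
        seen.add(key)
        sig_raw = str(row["significant"]).strip().lower()
        if sig_raw not in ("true", "false"):
            raise FormatError(
                f"{path}: line {i + 2}: significant must be true/false, "
                f"got {row['significant']!r}"
            )
        try:
            shift = float(row["shift_ppm"])
            intensity = float(row["rel_intensity"])
        except ValueError as exc:
            raise FormatError(f"{path}: line {i + 2}: non-numeric field") from exc
        observations.append(
            ResonanceObservation(
                species_name=key[0],
                nucleus=key[1],
                shift=shift,
                rel_intensity=intensity,
                significant=sig_raw == "true",
            )
        )
    return observations


def write_peak_list(observations: list[ResonanceObservation], path) -> None:
    rows = [
        {
            "species": o.species_name,
            "nucleus": o.nucleus,
            "shift_ppm": _fmt(o.shift),
            "rel_intensity": _fmt(o.rel_intensity),
            "significant": "true" if o.significant else "false",
        }
        for o in observations
    ]
    pd.DataFrame(rows, columns=_PEAK_COLUMNS).to_csv(path, sep="\t", index=False)


def read_spectrum(path) -> Spectrum:
    path = Path(path)
    meta: dict = {}
    data_lines = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    k, v = body.split("=", 1)
                    meta[k.strip()] = _parse_scalar(v.strip())
                continue
            parts = line.split()
            if len(parts) != 2:
                raise FormatError(f"{path}: line {lineno}: expected 2 columns")
            try:
                data_lines.append((float(parts[0]), float(parts[1])))
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: non-numeric field") from exc
    if len(data_lines) < 2:
        raise FormatError(f"{path}: fewer than 2 data points")
    arr = np.array(data_lines)
    return Spectrum(ppm_axis=arr[:, 0], amplitude=arr[:, 1], meta=meta)


def write_spectrum(spectrum: Spectrum, path) -> None:
    with open(path, "w") as fh:
        for k, v in spectrum.meta.items():
            fh.write(f"# {k} = {v}\n")
        for x, a in zip(spectrum.ppm_axis, spectrum.amplitude):
            fh.write(f"{x:.8f}\t{a:.10e}\n")


def write_report(report: dict, json_path, text_path=None) -> None:
    """Serialize an analysis report as JSON plus an optional text summary."""
    with open(json_path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")
    if text_path is not None:
        with open(text_path, "w") as fh:
            fh.write(_render_text_report(report))


def _render_text_report(report: dict, indent: int = 0) -> str:
    out = _io.StringIO()
    pad = "  " * indent
    for key in sorted(report):
        value = report[key]
        if isinstance(value, dict):
            out.write(f"{pad}{key}:\n")
            out.write(_render_text_report(value, indent + 1))
        else:
            out.write(f"{pad}{key} = {value}\n")
    return out.getvalue()


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def _parse_scalar(text: str):
    for cast in (int, float):
        try:
            return cast(text)
        except ValueError:
            continue
    return text


def _fmt(x: float) -> str:
    """Shortest decimal text that round-trips the stored float."""
    if isinstance(x, float) and math.isnan(x):
        return "nan"
    return repr(float(x))
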