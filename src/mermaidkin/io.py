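"""Tab-delimited text I/O for traces, spectral matrices, series and solutions.

All formats are plain text with '#' metadata header lines of the form
``# key: value``, tab delimiters, '.' decimal separators and scientific
notation where needed; round trips are lossless to better than 1e-12
relative.  Malformed input raises :class:`FormatError` carrying the line
number.
"""

from __future__ import annotations

import ast
from pathlib import Path

import numpy as np
import yaml

from .ephys import IVSeries, RecoverySeries
from .globalfit import TimeResolvedSpectra
from .kinetics import KineticScheme, LightProtocol, PhotocurrentTrace
from .solutions import SolutionComposition
from .spectra import Spectrum, TitrationSeries

__all__ = [
    "FormatError",
    "read_trace",
    "write_trace",
    "read_matrix",
    "write_matrix",
    "read_series",
    "write_series",
    "read_spectrum",
    "write_spectrum",
    "read_iv",
    "read_recovery",
    "read_titration",
    "read_solution",
    "read_config",
    "scheme_from_config",
    "protocol_from_config",
]

_FMT = "%.17g"


class FormatError(ValueError):
    """A malformed input file; carries the offending path and line number."""

    def __init__(self, path, line_no, message):
        super().__init__(f"{path}:{line_no}: {message}")
        self.path = str(path)
        self.line_no = line_no


def _parse_meta_value(raw: str):
    raw = raw.strip()
    try:
        return ast.literal_eval(raw)
    except (ValueError, SyntaxError):
        return raw


def _read_lines(path):
    text = Path(path).read_text()
    meta = {}
    rows = []
    for n, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, val = body.partition(":")
                meta[key.strip()] = _parse_meta_value(val)
            continue
        rows.append((n, line.rstrip("\n").split("\t")))
    if not rows:
        raise FormatError(path, 1, "no data rows found")
    return meta, rows


def _floats(path, n, fields, start=0):
    out = []
    for f in fields[start:]:
        try:
            out.append(float(f))
        except ValueError:
            raise FormatError(path, n, f"not a number: {f!r}") from None
    return out


def _meta_lines(meta: dict) -> str:
    items = {k: (v.item() if isinstance(v, np.generic) else v) for k, v in meta.items()}
    return "".join(f"# {k}: {v!r}\n" for k, v in items.items())


def write_trace(path, trace: PhotocurrentTrace) -> None:
    meta = {
        "voltage_mV": trace.voltage,
        "e_rev_mV": trace.e_rev,
        "conductance_scale_pA_per_mV": trace.conductance_scale,
        "light_on_s": trace.light_window[0],
        "light_off_s": trace.light_window[1],
    }
    body = "\n".join(
        f"{t:.17g}\t{i:.17g}" for t, i in zip(trace.times, trace.current)
    )
    Path(path).write_text(_meta_lines(meta) + "time_s\tcurrent_pA\n" + body + "\n")


def read_trace(path) -> PhotocurrentTrace:
    meta, rows = _read_lines(path)
    required = ("voltage_mV", "e_rev_mV", "light_on_s", "light_off_s")
    for key in required:
        if key not in meta:
            raise FormatError(path, 1, f"missing metadata key {key!r}")
    data = []
    for n, fields in rows:
        if fields[0].startswith("time"):
            continue
        if len(fields) != 2:
            raise FormatError(path, n, f"expected 2 columns, got {len(fields)}")
        data.append(_floats(path, n, fields))
    arr = np.asarray(data)
    return PhotocurrentTrace(
        times=arr[:, 0],
        current=arr[:, 1],
        voltage=float(meta["voltage_mV"]),
        e_rev=float(meta["e_rev_mV"]),
        light_window=(float(meta["light_on_s"]), float(meta["light_off_s"])),
        conductance_scale=float(meta.get("conductance_scale_pA_per_mV", 1.0)),
        metadata=meta,
    )


def write_matrix(path, data: TimeResolvedSpectra) -> None:
    meta = dict(data.metadata)
    meta.pop("ground_truth", None)
    if data.excluded_ranges:
        meta["excluded_ranges"] = ";".join(f"{a:.17g}-{b:.17g}" for a, b in data.excluded_ranges)
    header = data.axis_kind + "\t" + "\t".join(f"{t:.17g}" for t in data.times)
    lines = [header]
    for x, row in zip(data.axis_values, data.delta_a):
        lines.append(f"{x:.17g}\t" + "\t".join(f"{v:.17g}" for v in row))
    Path(path).write_text(_meta_lines(meta) + "\n".join(lines) + "\n")


def read_matrix(path) -> TimeResolvedSpectra:
    meta, rows = _read_lines(path)
    n0, header = rows[0]
    axis_kind = header[0].strip()
    if axis_kind not in ("wavelength", "wavenumber"):
        raise FormatError(path, n0, f"unknown axis kind tag {axis_kind!r}")
    times = np.asarray(_floats(path, n0, header, start=1))
    axis = []
    matrix = []
    for n, fields in rows[1:]:
        if len(fields) != times.size + 1:
            raise FormatError(path, n, f"expected {times.size + 1} columns, got {len(fields)}")
        vals = _floats(path, n, fields)
        axis.append(vals[0])
        matrix.append(vals[1:])
    excluded = ()
    if "excluded_ranges" in meta and meta["excluded_ranges"]:
        try:
            excluded = tuple(
                tuple(float(x) for x in part.split("-", 1))
                for part in str(meta["excluded_ranges"]).split(";")
            )
        except ValueError:
            raise FormatError(path, 1, "malformed excluded_ranges metadata") from None
    meta.pop("excluded_ranges", None)
    return TimeResolvedSpectra(
        axis_values=np.asarray(axis),
        times=times,
        delta_a=np.asarray(matrix),
        axis_kind=axis_kind,
        excluded_ranges=excluded,
        metadata=meta,
    )


def write_series(path, x, y, columns=("x", "y"), meta=None) -> None:
    lines = _meta_lines(meta or {}) + "\t".join(columns) + "\n"
    lines += "\n".join(f"{a:.17g}\t{b:.17g}" for a, b in zip(x, y))
    Path(path).write_text(lines + "\n")


def read_series(path):
    """Two-column series -> (x, y, metadata)."""
    meta, rows = _read_lines(path)
    data = []
    for n, fields in rows:
        try:
            float(fields[0])
        except ValueError:
            continue  # column-header line
        if len(fields) != 2:
            raise FormatError(path, n, f"expected 2 columns, got {len(fields)}")
        data.append(_floats(path, n, fields))
    if not data:
        raise FormatError(path, 1, "no numeric rows found")
    arr = np.asarray(data)
    return arr[:, 0], arr[:, 1], meta


def write_spectrum(path, spec: Spectrum) -> None:
    meta = {"label": spec.label, **spec.metadata}
    write_series(path, spec.wavelengths, spec.absorbance, ("wavelength_nm", "absorbance_AU"), meta)


def read_spectrum(path) -> Spectrum:
    wl, ab, meta = read_series(path)
    return Spectrum(wavelengths=wl, absorbance=ab, label=str(meta.pop("label", "")), metadata=meta)


def read_iv(path) -> IVSeries:
    v, i, meta = read_series(path)
    return IVSeries(voltages=v, currents=i, condition_label=str(meta.get("condition", "")))


def read_recovery(path) -> RecoverySeries:
    dt, r, _ = read_series(path)
    return RecoverySeries(intervals=dt, peak_ratios=r)


def read_titration(path) -> TitrationSeries:
    ph, amp, meta = read_series(path)
    return TitrationSeries(ph_values=ph, amplitudes=amp, wavelength=float(meta.get("wavelength_nm", "nan")))


def read_solution(path) -> SolutionComposition:
    """Solution file: '# key: value' metadata plus 'species<TAB>mM' lines."""
    meta, rows = _read_lines(path)
    comps = []
    for n, fields in rows:
        if len(fields) != 2:
            raise FormatError(path, n, f"expected 'species<TAB>mM', got {len(fields)} fields")
        try:
            conc = float(fields[1])
        except ValueError:
            raise FormatError(path, n, f"not a concentration: {fields[1]!r}") from None
        comps.append((fields[0].strip(), conc))
    return SolutionComposition(
        components=tuple(comps),
        ph=float(meta.get("pH", 7.4)),
        temperature_c=float(meta.get("temperature_C", 25.0)),
        label=str(meta.get("label", "")),
    )


def read_config(path) -> dict:
    """Structured (YAML) configuration with nested sections."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise FormatError(path, 1, "config must be a mapping")
    return cfg


def scheme_from_config(cfg: dict) -> KineticScheme:
    """Build a KineticScheme from a config mapping.

    Expected keys: ``states`` (list), ``conducting`` (list of state names),
    ``ground_state``, ``photo_rates`` and ``thermal_rates`` (mappings with
    'A->B' keys).
    """
    states = tuple(cfg["states"])
    conducting = set(cfg.get("conducting", ()))

    def parse_rates(section):
        out = {}
        for key, val in (cfg.get(section) or {}).items():
            a, _, b = key.partition("->")
            out[(a.strip(), b.strip())] = float(val)
        return out

    return KineticScheme(
        state_names=states,
        conducting_mask=tuple(s in conducting for s in states),
        ground_state=cfg["ground_state"],
        photo_rates=parse_rates("photo_rates"),
        thermal_rates=parse_rates("thermal_rates"),
    )


def protocol_from_config(cfg: dict) -> LightProtocol:
    """Build a LightProtocol from ``segments`` / ``delta_flash`` config keys."""
    segments = tuple(tuple(float(x) for x in seg) for seg in cfg.get("segments", ()))
    flash = cfg.get("delta_flash")
    if flash is not None:
        flash = (float(flash[0]), float(flash[1]))
    return LightProtocol(segments=segments, delta_flash=flash)
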