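"""Plain-text file formats shared by all stages.

One CSV dialect everywhere: optional ``#``-prefixed metadata lines
(``# key: value``, values JSON-decoded when possible), a header row, then
numeric rows with dot decimals.  Temperatures are Celsius at user-facing
boundaries; the populations and curves tables carry kelvin with explicit
``_K`` column suffixes.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np

from ._constants import celsius_to_kelvin
from .dsc import Thermogram
from .esr import EsrSpectrum, PopulationSeries
from .vanthoff import VantHoffModel

__all__ = [
    "read_xy_table",
    "write_thermogram",
    "write_spectrum",
    "write_populations",
    "write_model_json",
    "read_model_json",
    "write_curves",
]

_COLUMNS = {
    "thermogram": ("temperature_C", "cp_kcal_mol_K"),
    "spectrum": ("field_G", "intensity"),
    "populations": ("temperature_K", "P_ordered", "P_disordered",
                    "residual_rms"),
}


def _format_meta(metadata: dict) -> list[str]:
    lines = []
    for k, v in metadata.items():
        if isinstance(v, (dict, list)):
            v = json.dumps(v)
        lines.append(f"# {k}: {v}")
    return lines


def _parse_meta_value(text: str):
    try:
        return json.loads(text)
    except (json.JSONDecodeError, ValueError):
        return text


def _write_table(path, metadata, header, rows):
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for line in _format_meta(metadata):
            fh.write(line + "\n")
        fh.write(",".join(header) + "\n")
        for row in rows:
            fh.write(",".join(repr(float(v)) for v in row) + "\n")


def write_thermogram(path, tg: Thermogram) -> None:
    meta = {"kind": "thermogram", **tg.metadata}
    _write_table(path, meta, _COLUMNS["thermogram"],
                 zip(tg.temperature_C, tg.cp))


def write_spectrum(path, spec: EsrSpectrum) -> None:
    meta = {"kind": "spectrum", **spec.metadata}
    if spec.temperature_C is not None:
        meta.setdefault("temperature_C", spec.temperature_C)
    if spec.label:
        meta.setdefault("label", spec.label)
    _write_table(path, meta, _COLUMNS["spectrum"],
                 zip(spec.field_G, spec.intensity))


def write_populations(path, series: PopulationSeries, metadata=None) -> None:
    meta = {"kind": "populations", **(metadata or {})}
    _write_table(path, meta, _COLUMNS["populations"],
                 zip(series.temperature_K, series.P_ordered,
                     series.P_disordered, series.residual_rms))


def _read_raw(path):
    """Parse metadata, header and the numeric body with line numbers."""
    path = Path(path)
    metadata, header, body = {}, None, []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                text = line.lstrip("#").strip()
                if ":" in text:
                    k, v = text.split(":", 1)
                    metadata[k.strip()] = _parse_meta_value(v.strip())
                continue
            cells = [c.strip() for c in line.split(",")]
            if header is None:
                header = cells
                continue
            try:
                body.append([float(c) for c in cells])
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: malformed numeric cell ({exc})"
                ) from None
    if header is None or not body:
        raise ValueError(f"{path}: empty table body")
    widths = {len(r) for r in body}
    if widths != {len(header)}:
        raise ValueError(f"{path}: ragged rows (header has {len(header)} "
                         f"columns)")
    return metadata, header, np.asarray(body, dtype=float)


def read_xy_table(path, kind: str):
    """Read a thermogram, spectrum or populations CSV into its typed
    container.  A non-monotonic axis is re-sorted ascending with a warning;
    malformed cells are hard errors naming the line."""
    if kind not in _COLUMNS:
        raise ValueError(f"unknown kind {kind!r}")
    metadata, header, data = _read_raw(path)
    required = _COLUMNS[kind]
    missing = [c for c in required if c not in header]
    # residual_rms is optional on input
    if kind == "populations" and missing == ["residual_rms"]:
        missing = []
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    cols = {c: data[:, header.index(c)] for c in header}
    axis = cols[required[0]]
    if not np.all(np.diff(axis) > 0):
        warnings.warn(f"{path}: axis not strictly increasing; re-sorting",
                      stacklevel=2)
        idx = np.argsort(axis, kind="stable")
        cols = {c: v[idx] for c, v in cols.items()}
    if kind == "thermogram":
        return Thermogram(celsius_to_kelvin(cols["temperature_C"]),
                          cols["cp_kcal_mol_K"], metadata)
    if kind == "spectrum":
        return EsrSpectrum(cols["field_G"], cols["intensity"],
                           temperature_C=metadata.get("temperature_C"),
                           label=str(metadata.get("label", "")),
                           metadata=metadata)
    rms = cols.get("residual_rms", np.zeros_like(cols["temperature_K"]))
    return PopulationSeries(cols["temperature_K"], cols["P_ordered"],
                            cols["P_disordered"], rms)


# ---------------------------------------------------------------------------
# model / curves artifacts


def write_model_json(path, model: VantHoffModel, metadata=None) -> None:
    payload = {
        "kind": "vanthoff_model",
        "Kp": model.Kp,
        "degree": model.degree,
        "coeffs": {k: v for k, v in zip("abcd", model.coeffs)},
        "covariance": np.asarray(model.covariance).tolist(),
        "T_range_K": list(model.T_range),
        "n_points": model.n_points,
        "rss": model.rss,
        "adj_r2": model.adj_r2,
    }
    if metadata:
        payload["metadata"] = metadata
    Path(path).write_text(json.dumps(payload, indent=2) + "\n",
                          encoding="utf-8")


def read_model_json(path) -> VantHoffModel:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    if payload.get("kind") != "vanthoff_model":
        raise ValueError(f"{path}: not a van't Hoff model file")
    co = payload["coeffs"]
    return VantHoffModel(
        Kp=payload["Kp"], degree=payload["degree"],
        coeffs=(co["a"], co["b"], co["c"], co["d"]),
        covariance=np.asarray(payload["covariance"], dtype=float),
        T_range=tuple(payload["T_range_K"]),
        n_points=payload["n_points"], rss=payload["rss"],
        adj_r2=payload["adj_r2"])


def write_curves(path, curves, metadata=None) -> None:
    meta = {"kind": "curves", **(metadata or {})}
    header = ("T_K", "dG_cal_mol", "dH_cal_mol", "dS_cal_mol_K",
              "dC_cal_mol_K")
    _write_table(path, meta, header,
                 zip(curves.T_grid, curves.dG, curves.dH, curves.dS,
                     curves.dC))


def write_special_temperatures(path, curves, metadata=None) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for line in _format_meta({"kind": "special_temperatures",
                                  **(metadata or {})}):
            fh.write(line + "\n")
        fh.write("kind,T_K\n")
        for kind, T in curves.special:
            fh.write(f"{kind},{T!r}\n")
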