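"""File formats: experiment JSON, reflection tables, distortion maps, frames.

All formats are versioned and validated on read. The experiment description
is a single JSON document (schema_version "1"); its canonical serialization
(sorted keys, 2-space indent) round-trips byte-identically. Reflection tables
are written as CSV with a commented header naming units and flag-bit meanings
(lossless, full float repr) or as Parquet; distortion maps and multi-panel
frames as NumPy ``.npz`` archives with a JSON sidecar; single-panel frames as
TIFF.
"""

from __future__ import annotations

import io
import json
import os
from typing import Optional

import numpy as np
import pandas as pd

from .geometry import (
    BeamModel,
    CrystalModel,
    DetectorModel,
    ExperimentModel,
    GoniometerModel,
    PanelModel,
    ScanModel,
    ScanVaryingStates,
    SchemaError,
)
from .image_prep import DistortionMapPair, RawFrame
from .prediction import COLUMNS, Flags, ReflectionTable

__all__ = [
    "SCHEMA_VERSION",
    "experiment_to_json",
    "experiment_from_json",
    "write_experiment",
    "read_experiment",
    "write_reflections_csv",
    "read_reflections_csv",
    "write_reflections_parquet",
    "read_reflections_parquet",
    "write_distortion_maps",
    "read_distortion_maps",
    "write_frame",
    "read_frame",
    "parse_config",
]

SCHEMA_VERSION = "1"


def _arr(a) -> list:
    return np.asarray(a, dtype=float).tolist()


def experiment_to_json(exp: ExperimentModel) -> str:
    """Canonical JSON serialization of an experiment (distortion maps are
    stored separately, see :func:`write_distortion_maps`)."""
    sv = None
    if exp.scan_varying is not None:
        sv = {
            "U": None if exp.scan_varying.U is None else _arr(exp.scan_varying.U),
            "g_star": None if exp.scan_varying.g_star is None else _arr(exp.scan_varying.g_star),
            "beam_direction": None
            if exp.scan_varying.beam_direction is None
            else _arr(exp.scan_varying.beam_direction),
        }
    doc = {
        "schema_version": SCHEMA_VERSION,
        "beam": {"direction": _arr(exp.beam.direction), "wavelength": exp.beam.wavelength},
        "detector": {
            "panels": [
                {
                    "origin": _arr(p.origin),
                    "fast_axis": _arr(p.fast_axis),
                    "slow_axis": _arr(p.slow_axis),
                    "pixel_size": list(p.pixel_size),
                    "n_pixels": list(p.n_pixels),
                    "gain": p.gain,
                }
                for p in exp.detector.panels
            ]
        },
        "goniometer": {"rotation_axis": _arr(exp.goniometer.rotation_axis)},
        "scan": {"image_range": list(exp.scan.image_range), "oscillation": list(exp.scan.oscillation)},
        "crystal": {
            "U": _arr(exp.crystal.U),
            "g_star": _arr(exp.crystal.g_star),
            "lattice_constraint": exp.crystal.lattice_constraint.value,
        },
        "scan_varying": sv,
    }
    return json.dumps(doc, sort_keys=True, indent=2) + "\n"


def experiment_from_json(text: str) -> ExperimentModel:
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise SchemaError(f"not valid JSON: {exc}") from exc
    if not isinstance(doc, dict) or "schema_version" not in doc:
        raise SchemaError("missing schema_version")
    if doc["schema_version"] != SCHEMA_VERSION:
        raise SchemaError(
            f"unsupported schema_version {doc['schema_version']!r} (supported: {SCHEMA_VERSION!r})"
        )
    for key in ("beam", "detector", "goniometer", "scan", "crystal"):
        if key not in doc:
            raise SchemaError(f"missing required key {key!r}")
    try:
        sv = None
        if doc.get("scan_varying") is not None:
            d = doc["scan_varying"]
            sv = ScanVaryingStates(
                U=None if d.get("U") is None else np.asarray(d["U"], dtype=float),
                g_star=None if d.get("g_star") is None else np.asarray(d["g_star"], dtype=float),
                beam_direction=None
                if d.get("beam_direction") is None
                else np.asarray(d["beam_direction"], dtype=float),
            )
        return ExperimentModel(
            beam=BeamModel(**doc["beam"]),
            detector=DetectorModel(
                [PanelModel(**{k: v for k, v in p.items()}) for p in doc["detector"]["panels"]]
            ),
            goniometer=GoniometerModel(**doc["goniometer"]),
            scan=ScanModel(**doc["scan"]),
            crystal=CrystalModel(**doc["crystal"]),
            scan_varying=sv,
        )
    except (KeyError, TypeError) as exc:
        raise SchemaError(f"malformed experiment document: {exc}") from exc


def write_experiment(exp: ExperimentModel, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(experiment_to_json(exp))


def read_experiment(path: str) -> ExperimentModel:
    with open(path) as fh:
        return experiment_from_json(fh.read())


# --------------------------------------------------------------------------
# Reflection tables
# --------------------------------------------------------------------------
_CSV_HEADER = (
    "# edgeom reflection table v1\n"
    "# columns: h,k,l (Miller indices); panel (panel id); X_o,Y_o (observed centroid, px);\n"
    "#   phi_o (observed rotation angle, deg); var_X,var_Y (px^2); var_phi (deg^2);\n"
    "#   X_c,Y_c (predicted centroid, px); phi_c (deg); flags (bitset)\n"
    "# flags: 1=observed 2=predicted 4=indexed 8=outlier 16=used_in_refinement\n"
)


def write_reflections_csv(table: ReflectionTable, path: str) -> None:
    buf = io.StringIO()
    # default float formatting is the shortest round-trip repr
    table.df.to_csv(buf, index=False)
    with open(path, "w") as fh:
        fh.write(_CSV_HEADER)
        fh.write(buf.getvalue())


def read_reflections_csv(path: str) -> ReflectionTable:
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"reflection table missing columns: {missing}")
    return ReflectionTable(df)


def write_reflections_parquet(table: ReflectionTable, path: str) -> None:
    table.df.to_parquet(path, index=False)


def read_reflections_parquet(path: str) -> ReflectionTable:
    return ReflectionTable(pd.read_parquet(path))


# --------------------------------------------------------------------------
# Distortion maps
# --------------------------------------------------------------------------
def write_distortion_maps(maps: DistortionMapPair, path: str, panel: int = 0) -> None:
    """Paired 32-bit float offset arrays (.npz) plus a JSON sidecar naming the
    panel, shape and sign convention."""
    np.savez(
        path,
        offset_fast=maps.offset_fast.astype(np.float32),
        offset_slow=maps.offset_slow.astype(np.float32),
    )
    sidecar = {
        "format": "edgeom distortion maps v1",
        "panel": panel,
        "shape": list(maps.offset_fast.shape),
        "units": "pixels",
        "sign_convention": "offset = corrected - raw, evaluated at raw pixel positions",
    }
    base = path if path.endswith(".npz") else path + ".npz"
    with open(base + ".json", "w") as fh:
        json.dump(sidecar, fh, sort_keys=True, indent=2)


def read_distortion_maps(path: str) -> DistortionMapPair:
    base = path if path.endswith(".npz") else path + ".npz"
    with np.load(base) as data:
        return DistortionMapPair(
            offset_fast=data["offset_fast"].astype(float),
            offset_slow=data["offset_slow"].astype(float),
        )


# --------------------------------------------------------------------------
# Raw frames
# --------------------------------------------------------------------------
def write_frame(frame: RawFrame, path: str) -> None:
    """Single-panel frames as TIFF; multi-panel frames as .npz + JSON sidecar."""
    if len(frame.panels) == 1 and (path.endswith(".tif") or path.endswith(".tiff")):
        import tifffile

        tifffile.imwrite(path, frame.panels[0])
        return
    arrays = {f"panel_{i}": p for i, p in enumerate(frame.panels)}
    if frame.masks is not None:
        arrays.update({f"mask_{i}": m for i, m in enumerate(frame.masks)})
    np.savez(path, **arrays)
    base = path if path.endswith(".npz") else path + ".npz"
    with open(base + ".json", "w") as fh:
        json.dump(
            {
                "format": "edgeom raw frame v1",
                "image_number": frame.image_number,
                "n_panels": len(frame.panels),
                "has_masks": frame.masks is not None,
            },
            fh,
            sort_keys=True,
            indent=2,
        )


def read_frame(path: str) -> RawFrame:
    if path.endswith(".tif") or path.endswith(".tiff"):
        import tifffile

        return RawFrame(panels=[tifffile.imread(path)])
    base = path if path.endswith(".npz") else path + ".npz"
    with open(base + ".json") as fh:
        meta = json.load(fh)
    with np.load(base) as data:
        panels = [data[f"panel_{i}"] for i in range(meta["n_panels"])]
        masks = (
            [data[f"mask_{i}"] for i in range(meta["n_panels"])] if meta.get("has_masks") else None
        )
    return RawFrame(panels=panels, image_number=meta.get("image_number", 1), masks=masks)


# --------------------------------------------------------------------------
# Flat key=value configuration
# --------------------------------------------------------------------------
def parse_config(text: str) -> dict:
    """Parse a flat ``key=value`` configuration (``#`` comments allowed).

    Values are coerced to int, float or bool where possible; comma-separated
    values become lists. Example keys: ``fix=dist,tau2,tau3``,
    ``restraints.sigma=0.1``, ``scan_varying.beam=2``, ``max_iterations=100``.
    """

    def coerce(v: str):
        v = v.strip()
        if "," in v:
            return [coerce(x) for x in v.split(",") if x.strip()]
        low = v.lower()
        if low in ("true", "yes", "on"):
            return True
        if low in ("false", "no", "off"):
            return False
        for cast in (int, float):
            try:
                return cast(v)
            except ValueError:
                pass
        return v

    out: dict = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise SchemaError(f"config line {lineno}: expected key=value, got {raw!r}")
        key, val = line.split("=", 1)
        out[key.strip()] = coerce(val)
    return out
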