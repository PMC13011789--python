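"""Readers and writers: NIfTI volumes, CSV measurement tables, JSON
calibration artefacts and atlas export/import.

Formats are deliberately language-neutral: NIfTI-1 for volumes, CSV with a
fixed documented header for tables, versioned JSON for calibration files.
Values are stored at full float precision; rounding happens only at
presentation.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .atlas import GridSpec, RegionAtlas, RegionInfo, Volume
from .calibrate import (
    Level1Anchors,
    PipelineCalibration,
    RegionAnchor,
    RegionMapping,
    TracerMapping,
)
from .endpoints import AgeSexModel, RegionAgeSex
from .tables import COLUMNS, CmTable, MeasurementTable, SbrTable

__all__ = [
    "read_volume",
    "write_volume",
    "read_table",
    "write_table",
    "write_atlas",
    "read_atlas",
    "CalibrationFile",
    "write_calibration",
    "read_calibration",
]

SCHEMA_VERSION = 1


class FormatError(ValueError):
    pass


# ---------------------------------------------------------------- volumes


def write_volume(v: Volume, path) -> None:
    img = nib.Nifti1Image(np.asarray(v.data, dtype=np.float64), v.grid.affine)
    img.header.set_zooms(v.grid.voxel_size_mm)
    nib.save(img, str(path))


def read_volume(path, frame: int | None = None,
                grid: GridSpec | None = None) -> Volume:
    """Read a 3-D NIfTI volume (4-D accepted only with a frame selection).

    If ``grid`` is given, the image grid must match it exactly; otherwise the
    grid is reconstructed from the header zooms.
    """
    try:
        img = nib.load(str(path))
    except Exception as exc:  # corrupt header / not NIfTI
        raise FormatError(f"cannot read {path} as NIfTI: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4:
        if frame is None:
            raise FormatError(
                f"{path} is 4-D ({data.shape[3]} frames); select a frame"
            )
        if not (0 <= frame < data.shape[3]):
            raise FormatError(f"frame {frame} out of range for {path}")
        data = data[..., frame]
    if data.ndim != 3:
        raise FormatError(f"{path} is {data.ndim}-D; expected a 3-D volume")
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    file_grid = GridSpec(tuple(int(s) for s in data.shape), zooms)
    if grid is not None and (
        file_grid.shape != grid.shape or file_grid.voxel_size_mm != grid.voxel_size_mm
    ):
        raise FormatError(
            f"{path}: grid {file_grid.shape} @ {file_grid.voxel_size_mm} mm does "
            f"not match the expected {grid.shape} @ {grid.voxel_size_mm} mm; "
            "resample the image onto the canonical grid first"
        )
    return Volume(np.asarray(data, dtype=np.float64), file_grid)


# ----------------------------------------------------------------- tables


def write_table(table: MeasurementTable, path) -> None:
    table.df.to_csv(path, index=False)


def read_table(path, kind: str = "sbr") -> MeasurementTable:
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path} is empty") from exc
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    sex_raw = df["sex"].astype(str).str.strip()
    non_numeric = ~sex_raw.str.fullmatch(r"[01](\.0)?")
    if non_numeric.any():
        row = int(df.index[non_numeric][0])
        raise FormatError(
            f"{path}: sex must be coded numerically, 0 = female / 1 = male "
            f"(row {row} has {df.loc[row, 'sex']!r}); letter codes are not accepted"
        )
    cls = {"sbr": SbrTable, "cm": CmTable}.get(kind)
    if cls is None:
        raise ValueError(f"kind must be 'sbr' or 'cm', got {kind!r}")
    try:
        return cls(df)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


# ------------------------------------------------------------------ atlas


def write_atlas(atlas: RegionAtlas, directory) -> None:
    """Write the label image (NIfTI) and the region table (JSON)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(atlas.labels.astype(np.int16), atlas.grid.affine)
    nib.save(img, str(directory / "labels.nii.gz"))
    meta = {
        "schema_version": SCHEMA_VERSION,
        "grid": {"shape": list(atlas.grid.shape),
                 "voxel_size_mm": list(atlas.grid.voxel_size_mm)},
        "regions": [
            {"code": i.code, "name": i.name, "side": i.side,
             "class": i.region_class}
            for i in atlas.region_table.values()
        ],
        "composites": {
            name: {side: sorted(codes) for side, codes in sides.items()}
            for name, sides in atlas.composites.items()
        },
    }
    (directory / "regions.json").write_text(json.dumps(meta, indent=1))


def read_atlas(directory) -> RegionAtlas:
    directory = Path(directory)
    meta = json.loads((directory / "regions.json").read_text())
    img = nib.load(str(directory / "labels.nii.gz"))
    grid = GridSpec(tuple(meta["grid"]["shape"]),
                    tuple(meta["grid"]["voxel_size_mm"]))
    labels = np.asarray(img.dataobj).astype(np.int16)
    table = {
        r["code"]: RegionInfo(r["code"], r["name"], r["side"], r["class"])
        for r in meta["regions"]
    }
    composites = {
        name: {side: frozenset(codes) for side, codes in sides.items()}
        for name, sides in meta["composites"].items()
    }
    return RegionAtlas(labels, grid, table, composites)


# ------------------------------------------------------ calibration files


class CalibrationFile:
    """Bundle of calibration artefacts with lossless JSON round-tripping."""

    def __init__(
        self,
        anchors: Level1Anchors | None = None,
        mappings: list[TracerMapping] | None = None,
        agesex: AgeSexModel | None = None,
        pipeline: PipelineCalibration | None = None,
        provenance: dict | None = None,
    ):
        self.anchors = anchors
        self.mappings = mappings or []
        self.agesex = agesex
        self.pipeline = pipeline
        self.provenance = provenance or {}

    def mapping_for(self, tracer: str) -> TracerMapping:
        for m in self.mappings:
            if m.tracer == tracer:
                return m
        raise KeyError(f"no mapping for tracer {tracer!r} in calibration file")

    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "anchors": None
            if self.anchors is None
            else {
                "tracer": self.anchors.tracer,
                "regions": {r: asdict(a) for r, a in self.anchors.regions.items()},
            },
            "mappings": [
                {
                    "tracer": m.tracer,
                    "upstream": m.upstream,
                    "level": m.level,
                    "regions": {r: asdict(rm) for r, rm in m.regions.items()},
                }
                for m in self.mappings
            ],
            "agesex": None
            if self.agesex is None
            else {r: asdict(rm) for r, rm in self.agesex.regions.items()},
            "pipeline": None if self.pipeline is None else asdict(self.pipeline),
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationFile":
        anchors = None
        if d.get("anchors"):
            anchors = Level1Anchors(
                tracer=d["anchors"]["tracer"],
                regions={
                    r: RegionAnchor(**a) for r, a in d["anchors"]["regions"].items()
                },
            )
        mappings = [
            TracerMapping(
                tracer=m["tracer"],
                upstream=m["upstream"],
                level=m["level"],
                regions={
                    r: RegionMapping(
                        **{
                            **rm,
                            "slope_ci": tuple(rm["slope_ci"]),
                            "intercept_ci": tuple(rm["intercept_ci"]),
                        }
                    )
                    for r, rm in m["regions"].items()
                },
            )
            for m in d.get("mappings", [])
        ]
        agesex = None
        if d.get("agesex"):
            agesex = AgeSexModel(
                regions={r: RegionAgeSex(**rm) for r, rm in d["agesex"].items()}
            )
        pipeline = None
        if d.get("pipeline"):
            p = dict(d["pipeline"])
            pipeline = PipelineCalibration(**p)
        return cls(anchors, mappings, agesex, pipeline, d.get("provenance", {}))


def write_calibration(calib: CalibrationFile, path) -> None:
    Path(path).write_text(json.dumps(calib.to_dict(), indent=1))


def read_calibration(path) -> CalibrationFile:
    try:
        return CalibrationFile.from_dict(json.loads(Path(path).read_text()))
    except (json.JSONDecodeError, KeyError, TypeError) as exc:
        raise FormatError(f"cannot parse calibration file {path}: {exc}") from exc
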