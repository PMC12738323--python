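"""Serialization: MetaImage (.mhd/.raw) grids, YAML dataset sidecars, CSV
profiles and CSV/JSON sweep results.

Grids are stored as uncompressed little-endian 32-bit float MetaImage pairs
(dose in Gy, LET_d in keV/um, sigmas in the same units as their values); a
YAML sidecar carries the generating specs, seed and a schema version so a
written dataset is fully reproducible and re-readable.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import SimpleITK as sitk
import yaml

from .grids import PhantomDataset, VoxelGrid3D
from .specs import (BeamSpec, CollimatorSpec, GeneratorParams, GeometrySpec,
                    spec_to_dict)
from .sobp import SOBPSpec

SCHEMA_VERSION = 1


class GridIOError(IOError):
    """Raised on malformed or inconsistent MetaImage input."""


def write_grid(path: str | Path, grid: VoxelGrid3D) -> Path:
    """Write a grid as an uncompressed float32 MetaImage (.mhd + .raw)."""
    path = Path(path)
    if path.suffix != ".mhd":
        raise GridIOError(f"expected a .mhd path, got {path}")
    # SimpleITK arrays are indexed [z, y, x]
    arr = np.ascontiguousarray(grid.values.transpose(2, 1, 0),
                               dtype=np.float32)
    img = sitk.GetImageFromArray(arr)
    img.SetSpacing(tuple(float(s) for s in grid.spacing))
    img.SetOrigin(tuple(float(o) for o in grid.origin))
    sitk.WriteImage(img, str(path), useCompression=False)
    return path


def read_grid(path: str | Path, quantity: str = "dose_Gy") -> VoxelGrid3D:
    """Read a float32 MetaImage pair back into a :class:`VoxelGrid3D`.

    A truncated or otherwise malformed payload raises :class:`GridIOError`
    rather than returning silently corrupted data.
    """
    path = Path(path)
    if not path.exists():
        raise GridIOError(f"no such grid file: {path}")
    _check_payload(path)
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:  # ITK reports parse errors as RuntimeError
        raise GridIOError(f"failed to parse MetaImage {path}: {exc}") from exc
    if img.GetDimension() != 3:
        raise GridIOError(f"{path}: expected a 3-D image, got "
                          f"{img.GetDimension()}-D")
    arr = sitk.GetArrayFromImage(img)  # [z, y, x]
    values = np.asarray(arr, dtype=np.float64).transpose(2, 1, 0)
    return VoxelGrid3D(values=values, origin=tuple(img.GetOrigin()),
                       spacing=tuple(img.GetSpacing()), quantity=quantity)


def _check_payload(mhd_path: Path) -> None:
    """Verify the .raw payload size against the declared header geometry."""
    header: dict[str, str] = {}
    with open(mhd_path, "r", encoding="ascii", errors="replace") as fh:
        for line in fh:
            if "=" in line:
                k, v = line.split("=", 1)
                header[k.strip()] = v.strip()
    try:
        dims = [int(x) for x in header["DimSize"].split()]
        etype = header["ElementType"]
        datafile = header["ElementDataFile"]
    except KeyError as exc:
        raise GridIOError(f"{mhd_path}: missing header field {exc}") from exc
    sizes = {"MET_FLOAT": 4, "MET_DOUBLE": 8}
    if etype not in sizes:
        raise GridIOError(f"{mhd_path}: unsupported element type {etype}")
    raw = mhd_path.parent / datafile
    if not raw.exists():
        raise GridIOError(f"{mhd_path}: payload {raw} not found")
    expected = int(np.prod(dims)) * sizes[etype]
    actual = raw.stat().st_size
    if actual != expected:
        raise GridIOError(
            f"{raw}: payload size {actual} B does not match the declared "
            f"{dims} x {etype} = {expected} B")


_GRID_NAMES = ("dose", "dose_sigma", "let", "let_sigma")
_QUANTITIES = {"dose": "dose_Gy", "dose_sigma": "sigma",
               "let": "let_kev_per_um", "let_sigma": "sigma"}


def write_dataset(outdir: str | Path, dataset: PhantomDataset) -> Path:
    """Write the four grids plus a YAML sidecar describing the setup."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name in _GRID_NAMES:
        write_grid(outdir / f"{name}.mhd", getattr(dataset, name))
    sidecar = {
        "schema_version": SCHEMA_VERSION,
        "beam": spec_to_dict(dataset.beam) if dataset.beam else None,
        "collimator": (spec_to_dict(dataset.collimator)
                       if dataset.collimator else None),
        "geometry": (spec_to_dict(dataset.geometry)
                     if dataset.geometry else None),
        "params": spec_to_dict(dataset.params) if dataset.params else None,
        "prescription_Gy": float(dataset.prescription),
        "seed": dataset.seed,
        "meta": {k: v for k, v in dataset.meta.items()
                 if isinstance(v, (str, int, float, bool, list, tuple))},
    }
    with open(outdir / "dataset.yaml", "w") as fh:
        yaml.safe_dump(sidecar, fh, sort_keys=True)
    return outdir


def read_dataset(indir: str | Path) -> PhantomDataset:
    """Read a dataset directory written by :func:`write_dataset`."""
    indir = Path(indir)
    sidecar_path = indir / "dataset.yaml"
    if not sidecar_path.exists():
        raise GridIOError(f"{indir}: missing dataset.yaml sidecar")
    with open(sidecar_path) as fh:
        side = yaml.safe_load(fh)
    if side.get("schema_version") != SCHEMA_VERSION:
        raise GridIOError(f"{indir}: unsupported schema version "
                          f"{side.get('schema_version')!r}")
    grids = {name: read_grid(indir / f"{name}.mhd", _QUANTITIES[name])
             for name in _GRID_NAMES}
    beam = BeamSpec(**side["beam"]) if side.get("beam") else None
    coll = (CollimatorSpec(**side["collimator"])
            if side.get("collimator") else None)
    geom = GeometrySpec(**side["geometry"]) if side.get("geometry") else None
    params = (GeneratorParams(**side["params"])
              if side.get("params") else None)
    return PhantomDataset(beam=beam, collimator=coll, geometry=geom,
                          params=params,
                          prescription=side["prescription_Gy"],
                          seed=side.get("seed"),
                          meta=side.get("meta", {}), **grids)


def profile_to_csv(path: str | Path, profile, pv=None) -> Path:
    """Write a lateral profile with all channels; peak/valley flags if a
    :class:`PeakValleySet` is given."""
    n = len(profile.positions)
    is_peak = np.zeros(n, dtype=bool)
    is_valley = np.zeros(n, dtype=bool)
    if pv is not None:
        is_peak[pv.peak_indices] = True
        is_valley[pv.valley_indices] = True
    rbe_col = (profile.bio_dose / profile.dose
               if profile.bio_dose is not None
               else np.full(n, np.nan))
    df = pd.DataFrame({
        "x_mm": profile.positions,
        "depth_cm": profile.depth,
        "dose_Gy": profile.dose,
        "dose_sigma_Gy": profile.dose_sigma,
        "let_kev_um": profile.let,
        "rbe": rbe_col,
        "bio_dose_Gy": (profile.bio_dose if profile.bio_dose is not None
                        else np.full(n, np.nan)),
        "bio_sigma_Gy": (profile.bio_sigma if profile.bio_sigma is not None
                         else np.full(n, np.nan)),
        "is_peak": is_peak,
        "is_valley": is_valley,
    })
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable configuration object."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def write_results(outdir: str | Path, records: pd.DataFrame,
                  summary: dict) -> tuple[Path, Path]:
    """Write sweep/analysis records as CSV and a JSON summary (records plus
    every input parameter, seed and config hash; no timestamps, so repeated
    runs are byte-identical)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    csv_path = outdir / "pvdr_results.csv"
    records.to_csv(csv_path, index=False)
    json_path = outdir / "summary.json"
    payload = dict(summary)
    payload["schema_version"] = SCHEMA_VERSION
    payload["records"] = records.to_dict(orient="records")
    with open(json_path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True, default=str)
    return csv_path, json_path


def read_sobp_spec(path: str | Path) -> SOBPSpec:
    """Read an SOBP spec from YAML: a list of {energy, weight} plus an
    optional plateau window."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    layers = tuple((float(d["energy"]), float(d["weight"]))
                   for d in data["layers"])
    return SOBPSpec(layers=layers,
                    plateau_lo=float(data.get("plateau_lo", 7.0)),
                    plateau_hi=float(data.get("plateau_hi", 9.0)))
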