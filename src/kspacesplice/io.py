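"""Readers and writers for k-space acquisitions.

Primary on-disk format is HDF5: one complex dataset per (channel, slice) at
``/kspace/ch{c}/sl{s}`` with a ``gain_db`` float attribute and the provenance
map serialized as a JSON string attribute.  A raw-binary dialect
(``<name>.cplx`` row-major interleaved float32 real/imag plus a
``<name>.json`` sidecar) is accepted for interoperability; it is lossy to
float32 precision by construction.
"""

from __future__ import annotations

import json
import os
from pathlib import Path
from typing import Any

import h5py
import numpy as np

from .core import KSpaceAcquisition, validate_kspace_matrix
from .errors import KSpaceError, MetadataError, ShapeError

_DEFAULT_DATASET = "/kspace/ch1/sl1"


def write_kspace(
    acq: KSpaceAcquisition,
    path: str | os.PathLike,
    dataset: str = _DEFAULT_DATASET,
    overwrite: bool = False,
) -> None:
    """Write an acquisition so that :func:`read_kspace` round-trips it exactly.

    ``.cplx`` paths select the raw-binary dialect (float32, lossy for
    double-precision data); anything else is written as HDF5.  Existing files
    are only replaced when ``overwrite`` is true.
    """
    path = Path(path)
    if path.exists() and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True to replace it")
    if path.suffix == ".cplx":
        _write_raw(acq, path)
        return
    # track_times=False keeps rewrites byte-identical (reproducibility contract)
    with h5py.File(path, "w") as f:
        ds = f.create_dataset(dataset, data=acq.data, track_times=False)
        ds.attrs["gain_db"] = float(acq.gain_db)
        if "seed" in acq.meta:
            ds.attrs["seed"] = int(acq.meta["seed"])
        ds.attrs["meta_json"] = json.dumps(acq.meta, sort_keys=True, default=_jsonable)


def read_kspace(path: str | os.PathLike, dataset: str | None = None) -> KSpaceAcquisition:
    """Read an acquisition written by :func:`write_kspace`.

    ``dataset`` defaults to the first dataset under ``/kspace`` (HDF5) and is
    ignored for the raw dialect.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix == ".cplx":
        return _read_raw(path)
    with h5py.File(path, "r") as f:
        ds = _locate_dataset(f, dataset)
        if "gain_db" not in ds.attrs:
            raise MetadataError(f"{path}:{ds.name} lacks the gain_db attribute")
        data = ds[...]
        if data.ndim != 2:
            raise ShapeError(f"{path}:{ds.name} is {data.ndim}-D, expected 2-D k-space")
        meta: dict[str, Any] = {}
        if "meta_json" in ds.attrs:
            meta = json.loads(ds.attrs["meta_json"])
        acq = KSpaceAcquisition(data=data, gain_db=float(ds.attrs["gain_db"]), meta=meta)
    return acq


def _locate_dataset(f: h5py.File, dataset: str | None) -> h5py.Dataset:
    if dataset is not None:
        if dataset not in f:
            raise KSpaceError(f"dataset {dataset!r} not found")
        return f[dataset]
    found: list[h5py.Dataset] = []

    def visit(name: str, obj: object) -> None:
        if isinstance(obj, h5py.Dataset):
            found.append(obj)

    root = f["/kspace"] if "/kspace" in f else f
    root.visititems(visit)
    if not found:
        raise KSpaceError("no dataset found in file")
    return found[0]


def _write_raw(acq: KSpaceAcquisition, path: Path) -> None:
    inter = np.empty(acq.data.shape + (2,), dtype=np.float32)
    inter[..., 0] = acq.data.real
    inter[..., 1] = acq.data.imag
    inter.tofile(path)
    sidecar = {
        "M": acq.M,
        "K": acq.K,
        "gain_db": acq.gain_db,
        "meta": _json_roundtrippable(acq.meta),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, sort_keys=True, indent=1))


def _read_raw(path: Path) -> KSpaceAcquisition:
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise MetadataError(f"raw dialect requires sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    for key in ("M", "K", "gain_db"):
        if key not in sidecar:
            raise MetadataError(f"sidecar {sidecar_path} lacks {key!r}")
    M, K = int(sidecar["M"]), int(sidecar["K"])
    raw = np.fromfile(path, dtype=np.float32)
    if raw.size != 2 * M * K:
        raise ShapeError(f"{path}: expected {2 * M * K} float32 values, found {raw.size}")
    raw = raw.reshape(M, K, 2)
    data = raw[..., 0].astype(np.complex64)
    data += 1j * raw[..., 1].astype(np.complex64)
    validate_kspace_matrix(data)
    return KSpaceAcquisition(
        data=data, gain_db=float(sidecar["gain_db"]), meta=dict(sidecar.get("meta", {}))
    )


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (tuple, set, np.ndarray)):
        return list(obj)
    raise TypeError(f"meta value {obj!r} is not JSON-serializable")


def _json_roundtrippable(meta: dict[str, Any]) -> dict[str, Any]:
    return json.loads(json.dumps(meta, default=_jsonable))
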