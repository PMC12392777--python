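"""HDF5 containers and YAML filter/parameter serialization.

One acquisition per HDF5 file: ``/counts`` (or ``/values``) holding the
``[layer, row, col]`` array, detector spec and provenance as a JSON
attribute, format version mandatory.  The DRF is stored as COO
triplets.  Round trips are lossless.
"""

from __future__ import annotations

import json
from dataclasses import asdict

import h5py
import numpy as np
import yaml
from scipy import sparse

from .blur import BlurFilterSet
from .detector import DetectorSpec
from .drf import DRFMatrix
from .geometry import GeometryParams
from .projection import PrecondProjection, RawProjection
from .recon import SourceGrid

FORMAT_VERSION = "mlprecond-1"

__all__ = [
    "write_projection", "read_projection",
    "write_drf", "read_drf",
    "write_volume", "read_volume",
    "save_filters", "load_filters",
    "save_geometry", "load_geometry",
]


def _spec_to_json(spec: DetectorSpec) -> str:
    d = asdict(spec)
    d["raw_grid"] = list(d["raw_grid"])
    d["precond_grid"] = list(d["precond_grid"])
    return json.dumps(d)


def _spec_from_json(s: str) -> DetectorSpec:
    d = json.loads(s)
    d["raw_grid"] = tuple(d["raw_grid"])
    d["precond_grid"] = tuple(d["precond_grid"])
    return DetectorSpec(**d)


def _sanitize(meta: dict) -> dict:
    def conv(v):
        if isinstance(v, (np.integer,)):
            return int(v)
        if isinstance(v, (np.floating,)):
            return float(v)
        if isinstance(v, np.ndarray):
            return v.tolist()
        if isinstance(v, dict):
            return {k: conv(x) for k, x in v.items()}
        if isinstance(v, (list, tuple)):
            return [conv(x) for x in v]
        return v
    return conv(meta)


def write_projection(path, proj) -> None:
    """Write a raw or preconditioned projection (type round-trips)."""
    with h5py.File(path, "w") as f:
        f.attrs["format"] = FORMAT_VERSION
        f.attrs["spec"] = _spec_to_json(proj.spec)
        f.attrs["meta"] = json.dumps(_sanitize(proj.meta))
        if isinstance(proj, RawProjection):
            f.attrs["kind"] = "raw"
            integral = np.issubdtype(proj.counts.dtype, np.integer)
            f.create_dataset("counts", data=proj.counts,
                             dtype=np.uint32 if integral else np.float64)
            if proj.energy_window is not None:
                f.attrs["energy_window"] = list(proj.energy_window)
        elif isinstance(proj, PrecondProjection):
            f.attrs["kind"] = "precond"
            f.attrs["n_iter"] = proj.n_iter
            f.create_dataset("values", data=proj.values)
            for i, tr in enumerate(proj.loglik):
                f.create_dataset(f"loglik/{i}", data=np.asarray(tr))
        else:
            raise TypeError(f"cannot write {type(proj).__name__}")


def read_projection(path):
    with h5py.File(path, "r") as f:
        if f.attrs.get("format") != FORMAT_VERSION:
            raise ValueError(f"unrecognized file format {f.attrs.get('format')!r}")
        spec = _spec_from_json(f.attrs["spec"])
        meta = json.loads(f.attrs["meta"])
        kind = f.attrs["kind"]
        if kind == "raw":
            ew = f.attrs.get("energy_window")
            return RawProjection(
                counts=f["counts"][...], spec=spec,
                energy_window=tuple(ew) if ew is not None else None, meta=meta)
        if kind == "precond":
            traces = []
            if "loglik" in f:
                for i in sorted(f["loglik"], key=int):
                    traces.append(f["loglik"][i][...])
            return PrecondProjection(values=f["values"][...], spec=spec,
                                     n_iter=int(f.attrs["n_iter"]),
                                     loglik=traces, meta=meta)
        raise ValueError(f"unknown projection kind {kind!r}")


def write_drf(path, drf: DRFMatrix) -> None:
    coo = drf.P.tocoo()
    with h5py.File(path, "w") as f:
        f.attrs["format"] = FORMAT_VERSION
        f.attrs["kind"] = "drf"
        f.attrs["raw_shape"] = list(drf.raw_shape)
        f.attrs["precond_shape"] = list(drf.precond_shape)
        f.attrs["meta"] = json.dumps(_sanitize(drf.meta))
        f.create_dataset("P/row", data=coo.row)
        f.create_dataset("P/col", data=coo.col)
        f.create_dataset("P/value", data=coo.data)
        f.create_dataset("s", data=drf.s)


def read_drf(path) -> DRFMatrix:
    with h5py.File(path, "r") as f:
        if f.attrs.get("format") != FORMAT_VERSION:
            raise ValueError(f"unrecognized file format {f.attrs.get('format')!r}")
        raw_shape = tuple(int(v) for v in f.attrs["raw_shape"])
        precond_shape = tuple(int(v) for v in f.attrs["precond_shape"])
        M = raw_shape[0] * raw_shape[1]
        N = precond_shape[0] * precond_shape[1]
        P = sparse.coo_matrix(
            (f["P/value"][...], (f["P/row"][...], f["P/col"][...])),
            shape=(M, N)).tocsc()
        return DRFMatrix(P=P, s=f["s"][...], raw_shape=raw_shape,
                         precond_shape=precond_shape,
                         meta=json.loads(f.attrs["meta"]))


def write_volume(path, grid: SourceGrid) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["format"] = FORMAT_VERSION
        f.attrs["kind"] = "volume"
        f.attrs["voxel_size"] = grid.voxel_size
        f.attrs["origin"] = list(grid.origin)
        f.attrs["meta"] = json.dumps(_sanitize(grid.meta))
        f.create_dataset("values", data=grid.values)


def read_volume(path) -> SourceGrid:
    with h5py.File(path, "r") as f:
        if f.attrs.get("format") != FORMAT_VERSION:
            raise ValueError(f"unrecognized file format {f.attrs.get('format')!r}")
        return SourceGrid(values=f["values"][...],
                          voxel_size=float(f.attrs["voxel_size"]),
                          origin=tuple(f.attrs["origin"]),
                          meta=json.loads(f.attrs["meta"]))


# -- YAML sidecars ---------------------------------------------------------

def save_filters(path, filters: BlurFilterSet) -> None:
    doc = {
        "format": FORMAT_VERSION,
        "scheme": filters.scheme,
        "band_width": int(filters.band_width),
        "subbins_per_pixel": int(filters.subbins_per_pixel),
        "sigmas_mm": filters.sigmas.tolist(),
        "objective": None if filters.objective is None else list(map(float, filters.objective)),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh)


def load_filters(path) -> BlurFilterSet:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if doc.get("format") != FORMAT_VERSION:
        raise ValueError("unrecognized filter file format")
    return BlurFilterSet(
        sigmas=np.asarray(doc["sigmas_mm"], dtype=float),
        band_width=doc["band_width"],
        subbins_per_pixel=doc["subbins_per_pixel"],
        scheme=doc["scheme"],
        objective=None if doc["objective"] is None else np.asarray(doc["objective"]),
    )


def save_geometry(path, alpha: GeometryParams) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({"format": FORMAT_VERSION,
                        "alpha": alpha.to_vector().tolist()}, fh)


def load_geometry(path) -> GeometryParams:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if doc.get("format") != FORMAT_VERSION:
        raise ValueError("unrecognized geometry file format")
    return GeometryParams.from_vector(np.asarray(doc["alpha"], dtype=float))
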