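"""File I/O for time series, masks and model artifacts.

Orientation convention: on disk as in memory, time x vertex.  GIFTI
functional series store one data array per time point (each of length
v_vertex); HDF5 files use datasets /data, /tr and /run_boundaries; TSV holds
small fixtures with one row per time point.  Model artifacts (template,
sparse transform, stimulus and tuning matrices) are HDF5.
"""

from __future__ import annotations

import os

import h5py
import nibabel as nib
import numpy as np
from scipy import sparse

from .data import RegionMask, SubjectTimeseries
from .template import FunctionalTemplate
from .tuning import StimulusMatrix, TuningMatrix
from .wha import WholeBrainTransform


class FormatError(ValueError):
    """Raised when a file does not match the declared format or geometry."""


def _check_finite(data: np.ndarray, path: str):
    bad = np.nonzero(~np.all(np.isfinite(data), axis=0))[0]
    if bad.size:
        raise FormatError(
            f"{path}: non-finite values at vertices {bad.tolist()[:20]}"
            + ("..." if bad.size > 20 else ""))


def write_timeseries(ts: SubjectTimeseries, path: str, format: str | None = None):
    fmt = _infer_format(path, format)
    if fmt == "hdf5":
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=ts.data)
            f.create_dataset("tr", data=ts.tr_seconds)
            f.create_dataset("run_boundaries", data=np.asarray(ts.run_boundaries))
            f.attrs["subject_id"] = ts.subject_id
    elif fmt == "gifti":
        img = nib.gifti.GiftiImage()
        img.meta["subject_id"] = ts.subject_id
        img.meta["tr_seconds"] = repr(ts.tr_seconds)
        img.meta["run_boundaries"] = ",".join(str(b) for b in ts.run_boundaries)
        for row in ts.data:  # one map per time point
            img.add_gifti_data_array(nib.gifti.GiftiDataArray(
                row.astype(np.float32), intent="NIFTI_INTENT_TIME_SERIES"))
        nib.save(img, path)
    elif fmt == "tsv":
        header = f"# subject_id={ts.subject_id} tr={ts.tr_seconds} " \
                 f"runs={','.join(str(b) for b in ts.run_boundaries)}"
        np.savetxt(path, ts.data, delimiter="\t", header=header, comments="")
    else:
        raise FormatError(f"unknown format {fmt!r}")


def read_timeseries(path: str, format: str | None = None,
                    n_vertices: int | None = None) -> SubjectTimeseries:
    fmt = _infer_format(path, format)
    if fmt == "hdf5":
        with h5py.File(path, "r") as f:
            data = f["data"][()]
            tr = float(f["tr"][()])
            rb = [int(b) for b in f["run_boundaries"][()]]
            sid = f.attrs.get("subject_id", os.path.basename(path))
    elif fmt == "gifti":
        img = nib.load(path)
        data = np.stack([d.data.astype(float) for d in img.darrays])
        meta = dict(img.meta)
        sid = meta.get("subject_id", os.path.basename(path))
        tr = float(meta.get("tr_seconds", "1.0"))
        rb = [int(x) for x in meta.get("run_boundaries", "0").split(",")]
    elif fmt == "tsv":
        sid, tr, rb = os.path.basename(path), 1.0, [0]
        with open(path) as f:
            first = f.readline()
        if first.startswith("#"):
            fields = dict(kv.split("=") for kv in first[1:].split())
            sid = fields.get("subject_id", sid)
            tr = float(fields.get("tr", tr))
            rb = [int(x) for x in fields.get("runs", "0").split(",")]
        data = np.loadtxt(path, delimiter="\t", comments="#", ndmin=2)
    else:
        raise FormatError(f"unknown format {fmt!r}")
    if n_vertices is not None and data.shape[1] != n_vertices:
        raise FormatError(
            f"{path}: {data.shape[1]} vertices, declared geometry has {n_vertices}")
    _check_finite(data, path)
    return SubjectTimeseries(str(sid), data, tr_seconds=tr, run_boundaries=rb)


def _infer_format(path: str, format: str | None) -> str:
    if format is not None:
        return {"gifti": "gifti", "hdf5": "hdf5", "h5": "hdf5",
                "tsv": "tsv", "text": "tsv"}.get(format, format)
    if path.endswith((".gii", ".func.gii")):
        return "gifti"
    if path.endswith((".h5", ".hdf5")):
        return "hdf5"
    if path.endswith((".tsv", ".txt")):
        return "tsv"
    raise FormatError(f"cannot infer format of {path}")


def read_mask(path: str, name: str | None = None) -> RegionMask:
    """Mask as plain index list (one integer per line) or GIFTI label file."""
    if path.endswith(".gii"):
        img = nib.load(path)
        labels = img.darrays[0].data
        members = np.nonzero(labels > 0)[0]
    else:
        members = np.loadtxt(path, dtype=int, ndmin=1)
    return RegionMask(name or os.path.basename(path), members)


def write_mask(mask: RegionMask, path: str):
    np.savetxt(path, mask.members, fmt="%d")


def write_template(tpl: FunctionalTemplate, path: str):
    with h5py.File(path, "w") as f:
        f.create_dataset("M", data=tpl.data)
        f.create_dataset("radius", data=tpl.radius_mm)
        f.create_dataset("n_train", data=tpl.n_train)
        f.attrs["scaling"] = tpl.pc_scale


def read_template(path: str) -> FunctionalTemplate:
    with h5py.File(path, "r") as f:
        return FunctionalTemplate(f["M"][()], n_train=int(f["n_train"][()]),
                                  radius_mm=float(f["radius"][()]),
                                  pc_scale=str(f.attrs.get("scaling", "sqrt_n")))


def write_transform(W: WholeBrainTransform, path: str):
    mat = W.matrix.tocsr()
    with h5py.File(path, "w") as f:
        f.create_dataset("indptr", data=mat.indptr)
        f.create_dataset("indices", data=mat.indices)
        f.create_dataset("data", data=mat.data)
        f.create_dataset("shape", data=np.asarray(mat.shape))
        f.attrs["subject_id"] = W.subject_id
        for k, v in W.metadata.items():
            f.attrs[f"meta_{k}"] = v


def read_transform(path: str) -> WholeBrainTransform:
    with h5py.File(path, "r") as f:
        mat = sparse.csr_matrix(
            (f["data"][()], f["indices"][()], f["indptr"][()]),
            shape=tuple(f["shape"][()]))
        meta = {k[5:]: f.attrs[k] for k in f.attrs if k.startswith("meta_")}
        return WholeBrainTransform(str(f.attrs["subject_id"]), mat, meta)


def write_stimulus_matrix(S: StimulusMatrix, path: str):
    with h5py.File(path, "w") as f:
        f.create_dataset("S", data=S.data)
        f.create_dataset("row_index", data=S.row_index)
        f.attrs["basis_id"] = S.basis_id
        f.attrs["scale"] = S.scale


def read_stimulus_matrix(path: str) -> StimulusMatrix:
    with h5py.File(path, "r") as f:
        return StimulusMatrix(f["S"][()], basis_id=str(f.attrs["basis_id"]),
                              scale=str(f.attrs["scale"]),
                              row_index=f["row_index"][()])


def write_tuning_matrix(T: TuningMatrix, path: str):
    with h5py.File(path, "w") as f:
        f.create_dataset("T", data=T.data)
        f.attrs["subject_id"] = T.subject_id
        f.attrs["basis_id"] = T.basis_id


def read_tuning_matrix(path: str) -> TuningMatrix:
    with h5py.File(path, "r") as f:
        return TuningMatrix(str(f.attrs["subject_id"]), f["T"][()],
                            str(f.attrs["basis_id"]))
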