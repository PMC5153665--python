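"""Stack, mask and metadata I/O.

Volumes travel as multi-page TIFF (one page per z-slice) or HDF5; metadata
(voxel size, bit depth, axis order, provenance, optional intensity
inversion) lives in a JSON sidecar next to TIFF files and in attributes for
HDF5, keeping the pixel container format-dialect independent. Raw EM data
in which stain is dark can be flagged ``invert`` so it enters the label-high
working convention on read. All writers are byte-deterministic for
identical inputs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import h5py
import numpy as np
import tifffile

from .bulk import LabelVolume
from .phantom import ObjectInfo, PhantomTruth
from .volume import IntensityRange, VolumeGrid

__all__ = [
    "StackMetadata",
    "read_stack",
    "write_stack",
    "write_labels",
    "read_labels",
    "write_truth",
    "read_truth",
    "write_trials",
    "slice_count",
    "validate_slice_count",
]


@dataclass
class StackMetadata:
    """Sidecar metadata for an image stack."""

    voxel_size: tuple[float, float, float] | None = None  # (z, y, x) nm
    bit_depth: int = 8
    axis_order: str = "zyx"
    name: str = ""
    provenance: list = field(default_factory=list)
    invert: bool = False

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["voxel_size"] is not None:
            d["voxel_size"] = list(d["voxel_size"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StackMetadata":
        vs = d.get("voxel_size")
        return cls(
            voxel_size=tuple(vs) if vs is not None else None,
            bit_depth=int(d.get("bit_depth", 8)),
            axis_order=d.get("axis_order", "zyx"),
            name=d.get("name", ""),
            provenance=list(d.get("provenance", [])),
            invert=bool(d.get("invert", False)),
        )


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def _detect_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        return "tiff"
    if suffix in (".h5", ".hdf5"):
        return "hdf5"
    raise ValueError(f"cannot infer format from suffix {suffix!r} of {path}")


def _storage_dtype(bit_depth: int) -> np.dtype:
    if bit_depth == 8:
        return np.dtype(np.uint8)
    if bit_depth == 16:
        return np.dtype(np.uint16)
    raise ValueError(f"unsupported bit depth {bit_depth}")


def write_stack(volume: VolumeGrid, path, fmt: str | None = None) -> None:
    """Write a volume plus metadata. TIFF gets a JSON sidecar; HDF5 attributes.

    Values are rounded to the working bit depth's unsigned integer type.
    Output bytes are deterministic for identical input.
    """
    path = Path(path)
    fmt = _detect_format(path, fmt)
    data = np.clip(np.rint(volume.values), 0, volume.domain_max).astype(_storage_dtype(volume.bit_depth))
    meta = StackMetadata(
        voxel_size=volume.voxel_size,
        bit_depth=volume.bit_depth,
        name=volume.name,
        provenance=volume.provenance,
    )
    try:
        if fmt == "tiff":
            tifffile.imwrite(path, data, photometric="minisblack")
            _sidecar_path(path).write_text(
                json.dumps(meta.to_dict(), indent=2, sort_keys=True) + "\n"
            )
        elif fmt == "hdf5":
            with h5py.File(path, "w") as f:
                d = f.create_dataset("volume", data=data, track_times=False)
                _write_meta_attrs(d, meta)
        else:
            raise ValueError(f"unknown format {fmt!r}")
    except OSError as e:
        raise OSError(f"failed writing stack to {path}: {e}") from e


def _write_meta_attrs(dset, meta: StackMetadata) -> None:
    if meta.voxel_size is not None:
        dset.attrs["voxel_size_nm"] = np.asarray(meta.voxel_size, dtype=float)
    dset.attrs["bit_depth"] = meta.bit_depth
    dset.attrs["axis_order"] = meta.axis_order
    dset.attrs["name"] = meta.name
    dset.attrs["provenance"] = json.dumps(meta.provenance, sort_keys=True)
    dset.attrs["invert"] = meta.invert


def _read_meta_attrs(dset) -> StackMetadata:
    vs = dset.attrs.get("voxel_size_nm")
    return StackMetadata(
        voxel_size=tuple(float(v) for v in vs) if vs is not None else None,
        bit_depth=int(dset.attrs.get("bit_depth", 8)),
        axis_order=str(dset.attrs.get("axis_order", "zyx")),
        name=str(dset.attrs.get("name", "")),
        provenance=json.loads(dset.attrs.get("provenance", "[]")),
        invert=bool(dset.attrs.get("invert", False)),
    )


def read_stack(path, fmt: str | None = None, invert: bool | None = None) -> VolumeGrid:
    """Read a stack (z = page index for TIFF) and its metadata.

    ``invert`` overrides the metadata flag; when active, value v maps to
    (domain max − v), bringing stain-dark raw data into the label-high
    convention. The inversion is recorded in provenance.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"stack not found: {path}")
    fmt = _detect_format(path, fmt)
    if fmt == "tiff":
        try:
            data = tifffile.imread(path)
        except Exception as e:  # ragged pages, bad TIFF structure
            raise ValueError(f"cannot read TIFF stack {path}: {e}") from e
        sidecar = _sidecar_path(path)
        meta = (
            StackMetadata.from_dict(json.loads(sidecar.read_text()))
            if sidecar.exists()
            else StackMetadata()
        )
    else:
        with h5py.File(path, "r") as f:
            if "volume" not in f:
                raise ValueError(f"HDF5 file {path} has no 'volume' dataset")
            dset = f["volume"]
            data = dset[()]
            meta = _read_meta_attrs(dset)
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ValueError(f"stack {path} is {data.ndim}D; expected 3D (z, y, x)")
    if data.dtype not in (np.uint8, np.uint16):
        raise ValueError(f"unsupported stack dtype {data.dtype}; expected uint8/uint16")
    bit_depth = 8 if data.dtype == np.uint8 else 16
    if meta.bit_depth != bit_depth:
        warnings.warn(
            f"sidecar bit depth {meta.bit_depth} disagrees with stored dtype "
            f"({bit_depth}-bit); using the stored dtype"
        )
        meta.bit_depth = bit_depth
    values = data.astype(np.float32)
    provenance = list(meta.provenance)
    do_invert = meta.invert if invert is None else invert
    if do_invert:
        values = (2**bit_depth - 1) - values
        provenance.append({"op": "invert"})
    return VolumeGrid(values, voxel_size=meta.voxel_size, bit_depth=bit_depth,
                      provenance=provenance, name=meta.name)


# ---------------------------------------------------------------------------
# Labels, truth, trials
# ---------------------------------------------------------------------------

def write_labels(labelvol: LabelVolume, path, log_dict: dict | None = None) -> None:
    """Store a label volume as an HDF5 integer dataset with its metadata."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        d = f.create_dataset("labels", data=labelvol.labels.astype(np.int32),
                             track_times=False, compression="gzip", compression_opts=4)
        d.attrs["connectivity"] = labelvol.connectivity
        if labelvol.voxel_size is not None:
            d.attrs["voxel_size_nm"] = np.asarray(labelvol.voxel_size, dtype=float)
        if labelvol.source_range is not None:
            d.attrs["source_range"] = [labelvol.source_range.lo, labelvol.source_range.hi]
        if log_dict is not None:
            d.attrs["filter_log"] = json.dumps(log_dict, sort_keys=True)


def read_labels(path) -> LabelVolume:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"labels not found: {path}")
    with h5py.File(path, "r") as f:
        d = f["labels"]
        vs = d.attrs.get("voxel_size_nm")
        sr = d.attrs.get("source_range")
        return LabelVolume(
            d[()],
            connectivity=int(d.attrs.get("connectivity", 26)),
            source_range=IntensityRange(*(float(v) for v in sr)) if sr is not None else None,
            voxel_size=tuple(float(v) for v in vs) if vs is not None else None,
        )


def write_truth(truth: PhantomTruth, path) -> None:
    """Store phantom ground truth: one HDF5 group per class, labelled masks."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["shape"] = np.asarray(truth.shape)
        f.attrs["clipped_voxel_count"] = truth.clipped_voxel_count
        f.attrs["catalogue"] = json.dumps(
            [{"class_name": o.class_name, "object_id": o.object_id, "params": o.params}
             for o in truth.catalogue],
            sort_keys=True, default=str,
        )
        g = f.create_group("classes")
        for cname in sorted(truth.class_labels):
            g.create_dataset(cname, data=truth.class_labels[cname].astype(np.int32),
                             track_times=False, compression="gzip", compression_opts=4)


def read_truth(path) -> PhantomTruth:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"truth not found: {path}")
    with h5py.File(path, "r") as f:
        truth = PhantomTruth(shape=tuple(int(v) for v in f.attrs["shape"]))
        truth.clipped_voxel_count = int(f.attrs.get("clipped_voxel_count", 0))
        for cname in f["classes"]:
            truth.class_labels[cname] = f["classes"][cname][()]
        for o in json.loads(f.attrs.get("catalogue", "[]")):
            truth.catalogue.append(ObjectInfo(o["class_name"], int(o["object_id"]), o.get("params", {})))
    return truth


def write_trials(trials, path) -> None:
    """Store a seed-trial series: datasets trial_01..trial_NN (uint8 masks)."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        for t in trials:
            d = f.create_dataset(f"trial_{t.index:02d}", data=t.roi.astype(np.uint8),
                                 track_times=False, compression="gzip", compression_opts=4)
            d.attrs["lo"] = t.range.lo
            d.attrs["hi"] = t.range.hi
            d.attrs["voxel_count"] = t.voxel_count
            if t.volume_um3 is not None:
                d.attrs["volume_um3"] = t.volume_um3
            if t.error:
                d.attrs["error"] = t.error


# ---------------------------------------------------------------------------
# Acquisition-geometry bookkeeping
# ---------------------------------------------------------------------------

def slice_count(depth_um: float, z_step_nm: float) -> int:
    """Number of z-slices covering a physical depth at a given z-step.

    E.g. an 18 µm deep FIBSEM acquisition at ~10 nm steps is 1800 slices.
    """
    if depth_um <= 0 or z_step_nm <= 0:
        raise ValueError("depth and z-step must be positive")
    return int(round(depth_um * 1000.0 / z_step_nm))


def validate_slice_count(declared: int, depth_um: float, z_step_nm: float) -> dict:
    """Check a declared slice count against the computed one.

    Off-by-one mismatches are reported as warnings (printed acquisition
    tables show such bookkeeping discrepancies in practice); larger
    mismatches raise.
    """
    expected = slice_count(depth_um, z_step_nm)
    delta = int(declared) - expected
    status = {"declared": int(declared), "expected": expected, "delta": delta}
    if delta == 0:
        status["status"] = "ok"
    elif abs(delta) <= 1:
        status["status"] = "warn"
        warnings.warn(
            f"declared z-slice count {declared} differs from computed {expected} by {delta}"
        )
    else:
        raise ValueError(
            f"declared z-slice count {declared} inconsistent with computed {expected} (Δ={delta})"
        )
    return status
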