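"""Reading and writing volumetric images (NIfTI and MetaImage).

NIfTI (.nii/.nii.gz) goes through nibabel. MetaImage (.mha single-file,
.mhd + .raw pair) is a small self-contained codec — the format is a plain
text header followed by (or pointing to) a raw voxel block.

Volumes are exchanged as :class:`~vivorate.lung_cbct.DensityVolume` with
axes (slice, row, col). Files storing Hounsfield units can be converted
on read via a :class:`~vivorate.lung_cbct.HuCalibration`.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .lung_cbct import DensityVolume, HuCalibration, LungMask, hu_to_density

_MET_TYPES = {
    "MET_UCHAR": np.uint8,
    "MET_CHAR": np.int8,
    "MET_USHORT": np.uint16,
    "MET_SHORT": np.int16,
    "MET_UINT": np.uint32,
    "MET_INT": np.int32,
    "MET_FLOAT": np.float32,
    "MET_DOUBLE": np.float64,
}
_MET_NAMES = {np.dtype(v): k for k, v in _MET_TYPES.items()}


def _read_metaimage(path: Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    header: dict[str, str] = {}
    data_offset = None
    with open(path, "rb") as fh:
        while True:
            line = fh.readline()
            if not line:
                break
            key, _, value = line.decode("latin-1").partition("=")
            header[key.strip()] = value.strip()
            if key.strip() == "ElementDataFile":
                data_offset = fh.tell()
                break
    if "ElementDataFile" not in header:
        raise ValueError(f"{path}: missing ElementDataFile in MetaImage header")
    ndims = int(header.get("NDims", "3"))
    if ndims != 3:
        raise ValueError(f"{path}: only 3-D MetaImage supported, got NDims={ndims}")
    dims = [int(d) for d in header["DimSize"].split()]  # (x, y, z) fastest-first
    spacing = [float(s) for s in header.get("ElementSpacing", "1 1 1").split()]
    dtype = _MET_TYPES.get(header.get("ElementType", "MET_FLOAT"))
    if dtype is None:
        raise ValueError(f"{path}: unsupported ElementType {header.get('ElementType')}")
    msb = header.get("BinaryDataByteOrderMSB", header.get("ElementByteOrderMSB", "False"))
    dt = np.dtype(dtype).newbyteorder(">" if msb == "True" else "<")

    datafile = header["ElementDataFile"]
    count = int(np.prod(dims))
    if datafile == "LOCAL":
        with open(path, "rb") as fh:
            fh.seek(data_offset)
            raw = np.fromfile(fh, dtype=dt, count=count)
    else:
        raw = np.fromfile(path.parent / datafile, dtype=dt, count=count)
    if raw.size != count:
        raise ValueError(f"{path}: raw block holds {raw.size} voxels, expected {count}")
    # File order is x-fastest: shape (z, y, x) = (slice, row, col).
    arr = raw.reshape(dims[2], dims[1], dims[0]).astype(np.float64)
    return arr, (spacing[2], spacing[1], spacing[0])


def _write_metaimage(path: Path, arr: np.ndarray, spacing: tuple[float, float, float]) -> None:
    arr = np.ascontiguousarray(arr)
    if arr.dtype not in _MET_NAMES:
        arr = arr.astype(np.float32)
    local = path.suffix == ".mha"
    datafile = "LOCAL" if local else path.with_suffix(".raw").name
    header = "\n".join(
        [
            "ObjectType = Image",
            "NDims = 3",
            "BinaryData = True",
            "BinaryDataByteOrderMSB = False",
            f"DimSize = {arr.shape[2]} {arr.shape[1]} {arr.shape[0]}",
            f"ElementSpacing = {spacing[2]:g} {spacing[1]:g} {spacing[0]:g}",
            f"ElementType = {_MET_NAMES[arr.dtype]}",
            f"ElementDataFile = {datafile}",
        ]
    )
    if local:
        with open(path, "wb") as fh:
            fh.write(header.encode("latin-1") + b"\n")
            fh.write(arr.tobytes())
    else:
        path.write_text(header + "\n")
        (path.parent / datafile).write_bytes(arr.tobytes())


def _is_nifti(path: Path) -> bool:
    return path.name.endswith((".nii", ".nii.gz"))


def read_volume(
    path: str | Path,
    units: str = "density",
    cal: HuCalibration | None = None,
) -> DensityVolume:
    """Read a volume as mass density.

    Parameters
    ----------
    units
        ``"density"`` if the file stores g/cm^3 directly, ``"hu"`` to
        convert Hounsfield units through ``cal`` (default air/water
        anchors) on read.
    """
    path = Path(path)
    if units not in ("density", "hu"):
        raise ValueError("units must be 'density' or 'hu'")
    if _is_nifti(path):
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj, dtype=np.float64)
        if data.ndim != 3:
            raise ValueError(f"{path}: expected a 3-D volume, got shape {data.shape}")
        # nibabel axes are (x, y, z); present as (slice, row, col) = (z, y, x).
        arr = np.transpose(data, (2, 1, 0))
        zooms = img.header.get_zooms()[:3]
        spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    elif path.suffix in (".mha", ".mhd"):
        arr, spacing = _read_metaimage(path)
    else:
        raise ValueError(f"unsupported volume format: {path.name}")
    if units == "hu":
        arr = hu_to_density(arr, cal)
    return DensityVolume(arr, spacing)


def write_volume(path: str | Path, vol: DensityVolume | LungMask) -> Path:
    """Write a density volume or a 0/1 mask to NIfTI or MetaImage."""
    path = Path(path)
    if isinstance(vol, LungMask):
        arr = vol.values.astype(np.uint8)
    else:
        arr = np.asarray(vol.values, dtype=np.float32)
    spacing = vol.spacing_mm
    if _is_nifti(path):
        affine = np.diag([spacing[2], spacing[1], spacing[0], 1.0])
        img = nib.Nifti1Image(np.transpose(arr, (2, 1, 0)), affine)
        img.header.set_zooms((spacing[2], spacing[1], spacing[0]))
        nib.save(img, str(path))
    elif path.suffix in (".mha", ".mhd"):
        _write_metaimage(path, arr, spacing)
    else:
        raise ValueError(f"unsupported volume format: {path.name}")
    return path
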