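"""Volume and lesion-mask handling.

An :class:`SuvVolume` is a 3D grid of body-weight-normalised standardized
uptake values (SUV) with physical voxel spacing (mm) and a world origin at
the centre of voxel (0, 0, 0); world position of voxel ``(i, j, k)`` is
``origin + index * spacing``.  Lesion masks are binary grids on the *same*
grid (no implicit resampling: metric features are spacing-sensitive, so a
grid mismatch is an error, never a silent resample).

Supported on-disk formats are MetaImage (``.mha``, uncompressed with local
pixel data) and NIfTI-1 (``.nii`` / ``.nii.gz`` via nibabel).  Binary masks
are written as unsigned 8-bit, SUV as 32-bit float.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .exceptions import AlignmentError, ValidationError, VolumeIOError

__all__ = [
    "SuvVolume",
    "LesionSet",
    "read_volume",
    "write_volume",
    "label_lesions",
    "isocontour_41",
]

_CONNECTIVITY_TO_RANK = {6: 1, 18: 2, 26: 3}


@dataclass(frozen=True)
class SuvVolume:
    """A 3D SUV grid with voxel spacing and origin in mm.

    Parameters
    ----------
    data
        3D array of SUV values (unitless, >= 0, finite).
    spacing
        Per-axis voxel size in mm, all > 0.
    origin
        World coordinate (mm) of the centre of voxel (0, 0, 0).
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3 or min(data.shape) < 1:
            raise ValidationError(f"SUV grid must be 3D with shape >= 1 per axis, got {data.shape}")
        if not np.all(np.isfinite(data)):
            raise ValidationError("SUV grid contains non-finite values")
        if data.min() < 0:
            raise ValidationError("SUV values must be >= 0")
        spacing = tuple(float(s) for s in self.spacing)
        origin = tuple(float(o) for o in self.origin)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValidationError(f"spacing must be 3 positive values, got {self.spacing}")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass(frozen=True)
class LesionSet:
    """Labelled connected components of a tumour mask.

    ``grid`` holds 0 for background and 1..K for lesions; labels are
    consecutive and ordered deterministically (descending voxel count, ties
    broken by the lexicographically smallest voxel index).
    """

    grid: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    connectivity: int = 26

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid)
        if grid.ndim != 3:
            raise ValidationError(f"label grid must be 3D, got shape {grid.shape}")
        if self.connectivity not in _CONNECTIVITY_TO_RANK:
            raise ValidationError(f"connectivity must be one of 6/18/26, got {self.connectivity}")
        labels = np.unique(grid)
        labels = labels[labels > 0]
        k = int(labels.size)
        if k and not np.array_equal(labels, np.arange(1, k + 1)):
            raise ValidationError("lesion labels must be consecutive 1..K")
        object.__setattr__(self, "grid", grid.astype(np.int32, copy=False))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def n_lesions(self) -> int:
        return int(self.grid.max())

    def lesion_mask(self, label: int) -> np.ndarray:
        return self.grid == label

    def lesion_slices(self) -> list[tuple[slice, slice, slice]]:
        """Bounding-box slices per lesion, index-aligned with labels 1..K."""
        return [s for s in ndimage.find_objects(self.grid) if s is not None]


def _structure(connectivity: int) -> np.ndarray:
    try:
        rank = _CONNECTIVITY_TO_RANK[connectivity]
    except KeyError:
        raise ValidationError(f"connectivity must be one of 6/18/26, got {connectivity}") from None
    return ndimage.generate_binary_structure(3, rank)


def label_lesions(
    mask: np.ndarray,
    connectivity: int = 26,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> LesionSet:
    """Label connected components of a binary mask into a :class:`LesionSet`.

    Label order is deterministic: descending voxel count, ties by the
    lexicographically smallest voxel index of the component.  An empty mask
    yields K = 0 (valid; downstream features raise their own errors).
    """
    mask = np.asarray(mask).astype(bool)
    raw, k = ndimage.label(mask, structure=_structure(connectivity))
    if k == 0:
        return LesionSet(np.zeros(mask.shape, np.int32), spacing, origin, connectivity)
    counts = ndimage.sum_labels(np.ones_like(raw), raw, index=np.arange(1, k + 1))
    # lexicographic min index per component, for a stable tie-break
    min_keys = []
    for sl, lab in zip(ndimage.find_objects(raw), range(1, k + 1)):
        idx = np.argwhere(raw[sl] == lab)
        idx += [s.start for s in sl]
        min_keys.append(tuple(idx[np.lexsort(idx.T[::-1])][0]))
    order = sorted(range(k), key=lambda i: (-counts[i], min_keys[i]))
    remap = np.zeros(k + 1, np.int32)
    for new, old in enumerate(order, start=1):
        remap[old + 1] = new
    return LesionSet(remap[raw], spacing, origin, connectivity)


def isocontour_41(suv: SuvVolume, seed_region: np.ndarray, connectivity: int = 26) -> np.ndarray:
    """Segment by the 41 %-of-SUVmax isocontour grown from a seed region.

    Returns the voxels of the connected components of
    ``{SUV >= 0.41 * max(SUV in seed)}`` that intersect the seed.  Provided
    for completeness; the pipeline's contract input is the final
    physician-validated mask.
    """
    seed = np.asarray(seed_region).astype(bool)
    if seed.shape != suv.shape:
        raise AlignmentError(f"seed shape {seed.shape} != SUV shape {suv.shape}")
    if not seed.any():
        raise ValidationError("isocontour_41 requires a nonempty seed region")
    threshold = 0.41 * float(suv.data[seed].max())
    region = suv.data >= threshold
    if not region.any():
        warnings.warn("41% SUVmax threshold region is empty", stacklevel=2)
        return np.zeros(suv.shape, bool)
    labels, k = ndimage.label(region, structure=_structure(connectivity))
    keep = np.unique(labels[seed & region])
    keep = keep[keep > 0]
    return np.isin(labels, keep)


# ---------------------------------------------------------------------------
# File I/O.  MetaImage support is implemented here directly: the local
# uncompressed variant is a plain key = value header followed by raw voxels,
# and no installed library reads it.  NIfTI goes through nibabel.
# ---------------------------------------------------------------------------

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
_NP_TO_MET = {np.dtype(v): k for k, v in _MET_TYPES.items()}


def _read_mha(path: Path) -> tuple[np.ndarray, tuple, tuple]:
    header: dict[str, str] = {}
    with open(path, "rb") as fh:
        while True:
            line = fh.readline()
            if not line:
                raise VolumeIOError(f"{path}: truncated MetaImage header")
            key, _, value = line.decode("ascii", "replace").partition("=")
            key, value = key.strip(), value.strip()
            header[key] = value
            if key == "ElementDataFile":
                if value != "LOCAL":
                    raise VolumeIOError(f"{path}: only ElementDataFile = LOCAL is supported")
                raw = fh.read()
                break
    try:
        ndims = int(header["NDims"])
        dims = tuple(int(d) for d in header["DimSize"].split())
        dtype = _MET_TYPES[header["ElementType"]]
    except KeyError as exc:
        raise VolumeIOError(f"{path}: missing MetaImage header field {exc}") from None
    if ndims != 3:
        raise VolumeIOError(f"{path}: expected NDims = 3, got {ndims}")
    if header.get("CompressedData", "False").lower() == "true":
        raise VolumeIOError(f"{path}: compressed MetaImage data is not supported")
    spacing = tuple(float(s) for s in header.get("ElementSpacing", "1 1 1").split())
    origin = tuple(float(o) for o in header.get("Offset", header.get("Position", "0 0 0")).split())
    data = np.frombuffer(raw, dtype=dtype, count=int(np.prod(dims)))
    if data.size != np.prod(dims):
        raise VolumeIOError(f"{path}: pixel payload shorter than DimSize implies")
    byte_order = header.get("BinaryDataByteOrderMSB", "False").lower() == "true"
    if byte_order:
        data = data.byteswap()
    # MetaImage stores the first listed dimension fastest
    return data.reshape(dims[::-1]).transpose(2, 1, 0), spacing, origin


def _write_mha(path: Path, data: np.ndarray, spacing: tuple, origin: tuple) -> None:
    dtype = np.dtype(data.dtype)
    if dtype not in _NP_TO_MET:
        raise VolumeIOError(f"unsupported dtype for MetaImage: {dtype}")
    header = (
        "ObjectType = Image\n"
        "NDims = 3\n"
        "BinaryData = True\n"
        "BinaryDataByteOrderMSB = False\n"
        "CompressedData = False\n"
        f"DimSize = {data.shape[0]} {data.shape[1]} {data.shape[2]}\n"
        f"ElementSpacing = {spacing[0]:.17g} {spacing[1]:.17g} {spacing[2]:.17g}\n"
        f"Offset = {origin[0]:.17g} {origin[1]:.17g} {origin[2]:.17g}\n"
        f"ElementType = {_NP_TO_MET[dtype]}\n"
        "ElementDataFile = LOCAL\n"
    )
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        fh.write(np.ascontiguousarray(data.transpose(2, 1, 0)).tobytes())


def _read_nifti(path: Path) -> tuple[np.ndarray, tuple, tuple]:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise VolumeIOError(f"{path}: expected a 3D NIfTI volume, got ndim={data.ndim}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(t) for t in img.affine[:3, 3])
    return data, spacing, origin


def _write_nifti(path: Path, data: np.ndarray, spacing: tuple, origin: tuple) -> None:
    import nibabel as nib

    affine = np.diag(list(spacing) + [1.0])
    affine[:3, 3] = origin
    nib.save(nib.Nifti1Image(data, affine), str(path))


def _format_of(path: Path) -> str:
    name = path.name.lower()
    if name.endswith(".mha"):
        return "mha"
    if name.endswith(".nii") or name.endswith(".nii.gz"):
        return "nifti"
    raise VolumeIOError(f"unrecognised volume format: {path} (expected .mha, .nii or .nii.gz)")


def read_volume(path: str | Path, kind: str = "suv"):
    """Read an MHA or NIfTI volume.

    ``kind='suv'`` returns an :class:`SuvVolume`; ``kind='mask'`` returns a
    ``(binary grid, spacing, origin)`` triple.  Nonzero mask values other
    than 1 are binarised with a warning, per the input contract.
    """
    path = Path(path)
    if not path.exists():
        raise VolumeIOError(f"no such volume file: {path}")
    try:
        data, spacing, origin = (_read_mha if _format_of(path) == "mha" else _read_nifti)(path)
    except VolumeIOError:
        raise
    except Exception as exc:  # corrupt payload, bad header...
        raise VolumeIOError(f"could not read {path}: {exc}") from exc
    if kind == "suv":
        return SuvVolume(np.asarray(data, np.float32), spacing, origin)
    if kind == "mask":
        arr = np.asarray(data)
        values = np.unique(arr)
        if not np.all(np.isin(values, (0, 1))):
            warnings.warn(
                f"{path}: mask contains values other than 0/1 ({values[:5]}...); binarising nonzero -> 1",
                stacklevel=2,
            )
        return arr != 0, spacing, origin
    raise ValidationError(f"kind must be 'suv' or 'mask', got {kind!r}")


def write_volume(
    path: str | Path,
    data: np.ndarray | SuvVolume,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> None:
    """Write a volume to MHA or NIfTI.

    Boolean/8-bit arrays are written as unsigned 8-bit masks, everything
    else as 32-bit float (SUV).  Passing an :class:`SuvVolume` takes spacing
    and origin from the object.
    """
    path = Path(path)
    if isinstance(data, SuvVolume):
        spacing, origin, data = data.spacing, data.origin, data.data
    data = np.asarray(data)
    if data.dtype == bool or data.dtype == np.uint8:
        out = data.astype(np.uint8)
    else:
        out = data.astype(np.float32)
    (_write_mha if _format_of(path) == "mha" else _write_nifti)(path, out, spacing, origin)


def pair_suv_mask(suv: SuvVolume, mask: np.ndarray) -> np.ndarray:
    """Validate that a mask shares the SUV grid; returns the boolean mask."""
    mask = np.asarray(mask).astype(bool)
    if mask.shape != suv.shape:
        raise AlignmentError(f"mask shape {mask.shape} does not match SUV shape {suv.shape}")
    return mask
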