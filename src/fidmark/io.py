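"""Image file I/O: NIfTI, TIFF, DICOM (read-only).

Physical pixel spacing is mandatory metadata everywhere -- ring radii and
ROI sizes are in mm -- so readers refuse to guess when a file carries no
resolution information.

Float NIfTI round-trips losslessly. TIFF output is 16-bit with a linear
quantization whose scale/offset are stored in the ImageDescription tag
(JSON), so reading recovers values to within half a quantization step.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import DataError
from .image import Image2D

__all__ = ["ImageStack", "read_image", "write_image"]

_NIFTI_SUFFIXES = (".nii", ".nii.gz")
_TIFF_SUFFIXES = (".tif", ".tiff")
_DICOM_SUFFIXES = (".dcm", ".dicom")


@dataclass
class ImageStack:
    """A 3D voxel array with (dz, dy, dx) spacing in mm."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]

    def slice2d(self, index: int) -> Image2D:
        return Image2D(pixels=self.voxels[index], spacing=self.spacing[1:], units="HU")


def _suffix(path: Path) -> str:
    name = path.name.lower()
    if name.endswith(".nii.gz"):
        return ".nii.gz"
    return path.suffix.lower()


def read_image(path: str | Path) -> Image2D | ImageStack:
    """Read a NIfTI/TIFF/DICOM image with its physical spacing.

    2D inputs give an :class:`Image2D`; 3D NIfTI gives an
    :class:`ImageStack`. DICOM rescale slope/intercept are applied so CT
    values come back in HU.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    suffix = _suffix(path)
    if suffix in _NIFTI_SUFFIXES:
        return _read_nifti(path)
    if suffix in _TIFF_SUFFIXES:
        return _read_tiff(path)
    if suffix in _DICOM_SUFFIXES:
        return _read_dicom(path)
    raise DataError(f"unsupported image format {suffix!r} (expect NIfTI, TIFF or DICOM)")


def write_image(image: Image2D, path: str | Path, overwrite: bool = False) -> Path:
    """Write an :class:`Image2D` to NIfTI (lossless float) or 16-bit TIFF.

    Refuses to overwrite an existing file unless ``overwrite`` is set.
    """
    path = Path(path)
    if path.exists() and not overwrite:
        raise DataError(f"{path} exists; pass overwrite=True to replace it")
    suffix = _suffix(path)
    if suffix in _NIFTI_SUFFIXES:
        import nibabel as nib

        affine = np.diag([image.spacing[1], image.spacing[0], 1.0, 1.0])
        nib.save(nib.Nifti1Image(image.pixels.T.astype(np.float64), affine), str(path))
        return path
    if suffix in _TIFF_SUFFIXES:
        import tifffile

        lo = float(image.pixels.min())
        hi = float(image.pixels.max())
        scale = (hi - lo) / 65535.0 if hi > lo else 1.0
        raw = np.round((image.pixels - lo) / scale).astype(np.uint16)
        desc = json.dumps({"scale": scale, "offset": lo, "units": image.units})
        tifffile.imwrite(
            str(path), raw,
            resolution=(10.0 / image.spacing[1], 10.0 / image.spacing[0]),
            resolutionunit="CENTIMETER", description=desc,
        )
        return path
    raise DataError(f"unsupported output format {suffix!r} (expect .nii[.gz] or .tif[f])")


def _read_nifti(path: Path) -> Image2D | ImageStack:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(float)
    zooms = img.header.get_zooms()
    if data.ndim == 2:
        return Image2D(pixels=data.T, spacing=(float(zooms[1]), float(zooms[0])))
    if data.ndim == 3:
        return ImageStack(voxels=np.moveaxis(data, (0, 1, 2), (2, 1, 0)),
                          spacing=(float(zooms[2]), float(zooms[1]), float(zooms[0])))
    raise DataError(f"unsupported NIfTI dimensionality {data.ndim}")


def _read_tiff(path: Path) -> Image2D:
    import tifffile

    with tifffile.TiffFile(str(path)) as tf:
        page = tf.pages[0]
        tags = page.tags
        if "XResolution" not in tags or "YResolution" not in tags:
            raise DataError(f"{path} carries no resolution tags; pixel spacing unknown")
        unit = tags["ResolutionUnit"].value if "ResolutionUnit" in tags else None
        unit_mm = {2: 25.4, 3: 10.0}.get(getattr(unit, "value", unit))
        if unit_mm is None:
            raise DataError(f"{path}: resolution unit missing or dimensionless")
        xr = tags["XResolution"].value
        yr = tags["YResolution"].value
        dx = unit_mm / (xr[0] / xr[1])
        dy = unit_mm / (yr[0] / yr[1])
        data = page.asarray().astype(float)
        units = "detector_signal"
        desc = tags["ImageDescription"].value if "ImageDescription" in tags else ""
        try:
            meta = json.loads(desc)
            data = data * float(meta["scale"]) + float(meta["offset"])
            units = meta.get("units", units)
        except (json.JSONDecodeError, KeyError, TypeError):
            pass
    return Image2D(pixels=data, spacing=(dy, dx), units=units)


def _read_dicom(path: Path) -> Image2D:
    import pydicom

    ds = pydicom.dcmread(str(path))
    if "PixelSpacing" not in ds:
        raise DataError(f"{path} has no PixelSpacing; refusing to guess")
    dy, dx = (float(v) for v in ds.PixelSpacing)
    data = ds.pixel_array.astype(float)
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    data = data * slope + intercept
    units = "HU" if getattr(ds, "Modality", "") == "CT" or intercept != 0 else "detector_signal"
    return Image2D(pixels=data, spacing=(dy, dx), units=units)
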