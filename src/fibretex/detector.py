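"""Detector frames, flat-detector geometry and azimuthal cake regrouping.

Frames are read from TIFF, EDF or HDF5.  Masked pixels (dead zones, module
gaps, beamstop) are carried as a mask, encoded as negative counts in files.
The regrouping step bins annulus pixels by detector azimuth and averages
them — the cake/integrate reduction that turns a 2D WAXD frame into the
azimuthal profile ``I(chi)`` the texture fit consumes.

Pixel coordinates: ``x`` is the column index (horizontal, along ``+z_L``),
``y`` the row index counted downward, so "up" on the detector is decreasing
row and ``chi = atan2(cy - y, x - cx)`` matches the laboratory azimuth
convention of :mod:`fibretex.geometry`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .geometry import GeometryError, ScatteringGeometry
from .profiles import AzimuthalProfile

__all__ = [
    "DetectorImage",
    "load_image",
    "save_image",
    "pixel_to_q",
    "azimuthal_regroup",
]

MIN_CHI_BINS = 36


@dataclass
class DetectorImage:
    """2D grid of counts with optional mask and frame metadata."""

    data: np.ndarray
    mask: np.ndarray | None = None  # True = invalid pixel
    pixel_size: float | None = None  # mm
    beam_centre: tuple[float, float] | None = None  # (x_px, y_px)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("detector image must be 2-D")
        if self.mask is None:
            self.mask = np.zeros(self.data.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.data.shape:
                raise ValueError("mask must match image shape")
        if np.any(self.data[~self.mask] < 0):
            raise ValueError("unmasked counts must be non-negative")

    @property
    def shape(self):
        return self.data.shape


# --------------------------------------------------------------------------
# file formats

_EDF_HEADER_BLOCK = 1024


def _write_edf(path, data: np.ndarray) -> None:
    payload = np.ascontiguousarray(data, dtype="<i4").tobytes()
    fields = {
        "EDF_DataBlockID": "1.Image.Psd",
        "Dim_1": str(data.shape[1]),
        "Dim_2": str(data.shape[0]),
        "DataType": "SignedInteger",
        "ByteOrder": "LowByteFirst",
        "Size": str(len(payload)),
    }
    body = "{\n" + "".join(f"{k} = {v} ;\n" for k, v in fields.items())
    pad = _EDF_HEADER_BLOCK - (len(body) + 2) % _EDF_HEADER_BLOCK
    header = (body + " " * pad + "}\n").encode("ascii")
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(payload)


def _read_edf(path) -> np.ndarray:
    raw = Path(path).read_bytes()
    end = raw.find(b"}")
    if not raw.lstrip().startswith(b"{") or end < 0:
        raise IOError(f"{path}: not a valid EDF header")
    fields = {}
    for line in raw[: end].decode("ascii", "replace").splitlines():
        key, _, val = line.partition("=")
        if _:
            fields[key.strip().lstrip("{").strip()] = val.strip().rstrip(";").strip()
    try:
        dim1, dim2 = int(fields["Dim_1"]), int(fields["Dim_2"])
    except KeyError as exc:
        raise IOError(f"{path}: EDF header missing {exc}") from exc
    dtype = {
        "SignedInteger": "<i4",
        "UnsignedInteger": "<u4",
        "FloatValue": "<f4",
        "DoubleValue": "<f8",
    }.get(fields.get("DataType", "SignedInteger"))
    if dtype is None:
        raise IOError(f"{path}: unsupported EDF DataType {fields.get('DataType')}")
    start = end + 1
    if start < len(raw) and raw[start : start + 1] == b"\n":
        start += 1
    count = dim1 * dim2
    arr = np.frombuffer(raw[start:], dtype=dtype, count=count)
    if arr.size != count:
        raise IOError(f"{path}: truncated EDF payload")
    return arr.reshape(dim2, dim1).astype(float)


def save_image(image: DetectorImage, path, dataset: str = "counts") -> None:
    """Write a frame; masked pixels are stored as −1 counts.

    Format from the extension: ``.tif/.tiff`` (signed 32-bit TIFF), ``.edf``
    or ``.h5/.hdf5`` (counts dataset plus calibration attributes).
    """
    path = Path(path)
    encoded = np.where(image.mask, -1.0, image.data)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, encoded.astype(np.int32))
    elif suffix == ".edf":
        _write_edf(path, encoded.astype(np.int32))
    elif suffix in (".h5", ".hdf5", ".nxs"):
        import h5py

        with h5py.File(path, "w") as fh:
            ds = fh.create_dataset(dataset, data=encoded)
            if image.pixel_size is not None:
                ds.attrs["pixel_size_mm"] = image.pixel_size
            if image.beam_centre is not None:
                ds.attrs["beam_centre_px"] = image.beam_centre
            for k, v in image.metadata.items():
                if isinstance(v, (int, float, str)):
                    ds.attrs[k] = v
    else:
        raise IOError(
            f"unknown image format {suffix!r}: supported are .tif/.tiff, .edf, .h5/.hdf5"
        )


def load_image(path, dataset: str = "counts") -> DetectorImage:
    """Read a detector frame; negative counts become masked pixels."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image file: {path}")
    suffix = path.suffix.lower()
    pixel_size = beam_centre = None
    metadata: dict = {}
    if suffix in (".tif", ".tiff"):
        import tifffile

        data = tifffile.imread(path).astype(float)
    elif suffix == ".edf":
        data = _read_edf(path)
    elif suffix in (".h5", ".hdf5", ".nxs"):
        import h5py

        with h5py.File(path, "r") as fh:
            if dataset not in fh:
                raise IOError(f"{path}: no dataset {dataset!r}")
            ds = fh[dataset]
            data = np.asarray(ds, dtype=float)
            if "pixel_size_mm" in ds.attrs:
                pixel_size = float(ds.attrs["pixel_size_mm"])
            if "beam_centre_px" in ds.attrs:
                beam_centre = tuple(float(v) for v in ds.attrs["beam_centre_px"])
            metadata = {
                k: v for k, v in ds.attrs.items()
                if k not in ("pixel_size_mm", "beam_centre_px")
            }
    else:
        raise IOError(
            f"unknown image format {suffix!r}: supported are .tif/.tiff, .edf, .h5/.hdf5"
        )
    if data.ndim != 2:
        raise IOError(f"{path}: expected a single 2-D frame, got shape {data.shape}")
    mask = data < 0
    data = np.where(mask, 0.0, data)
    return DetectorImage(
        data=data, mask=mask, pixel_size=pixel_size, beam_centre=beam_centre,
        metadata=metadata,
    )


# --------------------------------------------------------------------------
# flat-detector transform


def _require_calibration(geometry: ScatteringGeometry):
    if not geometry.has_detector:
        raise GeometryError(
            "geometry needs detector_distance, beam_centre and pixel_size "
            "for pixel <-> q mapping"
        )


def pixel_to_q(px, py, geometry: ScatteringGeometry):
    """Map pixel coordinates to ``(|q| in 1/Angstrom, chi in degrees)``.

    Exact flat-detector transform: ``tan(2 theta) = r / distance`` and
    ``q = (4 pi / lambda) sin(theta)``.  At the beam centre ``q = 0`` and
    chi is undefined (NaN).
    """
    _require_calibration(geometry)
    cx, cy = geometry.beam_centre
    dx = (np.asarray(px, dtype=float) - cx) * geometry.pixel_size
    dy = (cy - np.asarray(py, dtype=float)) * geometry.pixel_size  # up = -row
    r = np.hypot(dx, dy)
    two_theta = np.arctan2(r, geometry.detector_distance)
    q = (4.0 * np.pi / geometry.wavelength) * np.sin(two_theta / 2.0)
    chi = np.degrees(np.arctan2(dy, dx)) % 360.0
    chi = np.where(r == 0, np.nan, chi)
    return q, chi


def azimuthal_regroup(
    image: DetectorImage,
    geometry: ScatteringGeometry,
    q_lo: float,
    q_hi: float,
    n_chi: int = 360,
    subtract_background: bool = False,
    return_npix: bool = False,
):
    """Cake-regroup an annulus ``[q_lo, q_hi]`` into ``n_chi`` azimuth bins.

    Each bin holds the mean counts of its unmasked pixels (so the sum of
    ``bin mean x bin pixel count`` conserves the annulus counts exactly);
    empty bins are NaN.  Optional radial background: the mean of two
    flanking annuli of the same width is estimated per azimuth bin and
    subtracted (clipped at zero).

    Raises if the annulus contains no usable pixels; if more than half the
    bins are empty the profile carries a warning flag.
    """
    if not q_lo < geometry.q_ring < q_hi:
        raise ValueError("annulus must bracket q_ring: q_lo < q_ring < q_hi")
    if n_chi < MIN_CHI_BINS:
        raise ValueError(f"n_chi must be >= {MIN_CHI_BINS}")
    _require_calibration(geometry)
    if image.pixel_size is not None and image.pixel_size != geometry.pixel_size:
        raise GeometryError("image and geometry disagree on pixel size")

    ny, nx = image.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    q, chi = pixel_to_q(xx, yy, geometry)
    good = ~image.mask & np.isfinite(chi)
    step = 360.0 / n_chi
    bins = np.clip((np.nan_to_num(chi) / step).astype(int), 0, n_chi - 1)

    def bin_annulus(lo, hi):
        sel = good & (q >= lo) & (q < hi)
        npix = np.bincount(bins[sel], minlength=n_chi)
        tot = np.bincount(bins[sel], weights=image.data[sel], minlength=n_chi)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = np.where(npix > 0, tot / np.maximum(npix, 1), np.nan)
        return mean, npix, tot

    mean, npix, tot = bin_annulus(q_lo, q_hi)
    if npix.sum() == 0:
        raise ValueError("empty annulus: no unmasked pixels between q_lo and q_hi")
    warnings = []
    if np.count_nonzero(npix == 0) > n_chi // 2:
        warnings.append("more than half of the azimuth bins are empty")

    intensity = mean
    if subtract_background:
        width = q_hi - q_lo
        inner, n_in, _ = bin_annulus(q_lo - width, q_lo)
        outer, n_out, _ = bin_annulus(q_hi, q_hi + width)
        bg = np.nanmean(np.stack([inner, outer]), axis=0)
        intensity = np.clip(mean - np.where(np.isfinite(bg), bg, 0.0), 0.0, None)

    with np.errstate(invalid="ignore", divide="ignore"):
        sigma = np.where(npix > 0, np.sqrt(np.maximum(tot, 1.0)) / np.maximum(npix, 1), np.nan)
    profile = AzimuthalProfile(
        chi=(np.arange(n_chi) + 0.5) * step,
        intensity=intensity,
        sigma=sigma,
        warnings=warnings,
    )
    if return_npix:
        return profile, npix
    return profile
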