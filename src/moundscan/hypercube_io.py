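"""Hyperspectral cube I/O and radiometric preparation.

This module carries the raster substrate of the detection pipeline: an
ENVI-style header + raw binary reader/writer for VNIR hyper-cubes
(rows x cols x bands), region-of-interest cropping driven by a register
file, per-band morphological pre-cleaning, and conversion of radiance to
reflectance against a constant white-reference illuminant.

Conventions
-----------
* Cube axis order is ``(rows, cols, bands)``; wavelengths are stored in
  nanometres and must be strictly increasing.
* Pixel coordinates are 0-based; ROI windows are half-open,
  ``[row0, row0 + height) x [col0, col0 + width)``.
* Reflectance is the plain ratio radiance / white(band), clipped to a
  configurable ceiling (default 2.0) so downstream classifiers stay
  bounded when radiance exceeds the reference.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "HyperCube",
    "WhiteReference",
    "RoiRegister",
    "FormatError",
    "AlignmentError",
    "read_cube",
    "write_cube",
    "crop_roi",
    "preclean_cube",
    "to_reflectance",
]


class FormatError(ValueError):
    """Malformed or inconsistent ENVI header / payload."""


class AlignmentError(ValueError):
    """Band axes of two spectral objects do not line up."""


# ENVI 'data type' codes <-> numpy dtypes (little-endian assumed for order 0)
_DTYPE_BY_CODE = {
    1: np.dtype("u1"),
    2: np.dtype("<i2"),
    3: np.dtype("<i4"),
    4: np.dtype("<f4"),
    5: np.dtype("<f8"),
    12: np.dtype("<u2"),
    13: np.dtype("<u4"),
}
_CODE_BY_KIND = {np.dtype(d).str.lstrip("<>|="): c for c, d in _DTYPE_BY_CODE.items()}


@dataclass
class HyperCube:
    """A hyperspectral raster with its wavelength axis.

    Parameters
    ----------
    data : ndarray, shape (rows, cols, bands)
        Non-negative radiance or reflectance values.
    wavelengths_nm : ndarray, shape (bands,)
        Strictly increasing band-centre wavelengths in nanometres.
    quantity : {"radiance", "reflectance"}
    gsd_cm_per_px : float, optional
        Ground sample distance; carried as metadata only.
    """

    data: np.ndarray
    wavelengths_nm: np.ndarray
    quantity: str = "radiance"
    gsd_cm_per_px: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"cube data must be 3-D, got shape {self.data.shape}")
        if self.wavelengths_nm.ndim != 1 or len(self.wavelengths_nm) != self.data.shape[2]:
            raise FormatError(
                f"wavelength count {self.wavelengths_nm.size} does not match "
                f"band count {self.data.shape[2]}"
            )
        if np.any(np.diff(self.wavelengths_nm) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("cube contains non-finite values")
        if np.any(self.data < 0):
            raise ValueError("cube contains negative values")
        if self.quantity not in ("radiance", "reflectance"):
            raise ValueError(f"unknown quantity {self.quantity!r}")
        if self.gsd_cm_per_px is not None and self.gsd_cm_per_px <= 0:
            raise ValueError("gsd_cm_per_px must be positive")

    @property
    def rows(self) -> int:
        return self.data.shape[0]

    @property
    def cols(self) -> int:
        return self.data.shape[1]

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]


@dataclass
class WhiteReference:
    """Illuminant spectrum from the white calibration panel (one value per band)."""

    wavelengths_nm: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.wavelengths_nm.shape != self.intensity.shape or self.wavelengths_nm.ndim != 1:
            raise FormatError("white reference wavelength/intensity shape mismatch")
        if np.any(np.diff(self.wavelengths_nm) <= 0):
            raise ValueError("white reference wavelengths must be strictly increasing")
        if not np.all(self.intensity > 0):
            raise ValueError("white reference must be strictly positive at every band")

    @classmethod
    def from_csv(cls, path: str | Path) -> "WhiteReference":
        df = pd.read_csv(path)
        return cls(df["wavelength_nm"].to_numpy(), df["intensity"].to_numpy())

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"wavelength_nm": self.wavelengths_nm, "intensity": self.intensity}
        ).to_csv(path, index=False)

    def resampled_to(self, wavelengths_nm: np.ndarray) -> np.ndarray:
        """Linearly interpolate the spectrum onto a cube's wavelength axis.

        Extrapolation beyond the measured range is refused: the panel
        spectrum is only trusted where it was sampled.
        """
        w = np.asarray(wavelengths_nm, dtype=float)
        if w.min() < self.wavelengths_nm[0] - 1e-9 or w.max() > self.wavelengths_nm[-1] + 1e-9:
            raise AlignmentError(
                "cube wavelengths extend beyond the white reference range "
                f"[{self.wavelengths_nm[0]}, {self.wavelengths_nm[-1]}] nm"
            )
        return np.interp(w, self.wavelengths_nm, self.intensity)


@dataclass
class RoiEntry:
    roi_id: str
    row0: int
    col0: int
    height: int
    width: int
    lat: float | None = None
    lon: float | None = None


@dataclass
class RoiRegister:
    """Register of rectangular pixel windows (optionally georeferenced)."""

    entries: list[RoiEntry] = field(default_factory=list)

    def get(self, roi_id: str) -> RoiEntry:
        for e in self.entries:
            if e.roi_id == roi_id:
                return e
        raise KeyError(f"ROI id {roi_id!r} not found in register")

    @classmethod
    def from_csv(cls, path: str | Path) -> "RoiRegister":
        df = pd.read_csv(path, dtype={"roi_id": str})
        entries = []
        for rec in df.to_dict("records"):
            entries.append(
                RoiEntry(
                    roi_id=str(rec["roi_id"]),
                    row0=int(rec["row0"]),
                    col0=int(rec["col0"]),
                    height=int(rec["height"]),
                    width=int(rec["width"]),
                    lat=float(rec["lat"]) if "lat" in rec and pd.notna(rec.get("lat")) else None,
                    lon=float(rec["lon"]) if "lon" in rec and pd.notna(rec.get("lon")) else None,
                )
            )
        return cls(entries)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            [
                {
                    "roi_id": e.roi_id,
                    "row0": e.row0,
                    "col0": e.col0,
                    "height": e.height,
                    "width": e.width,
                    "lat": e.lat,
                    "lon": e.lon,
                }
                for e in self.entries
            ]
        ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# ENVI header + binary payload
# ---------------------------------------------------------------------------

_REQUIRED_KEYS = ("samples", "lines", "bands", "interleave", "data type", "wavelength")


def _parse_envi_header(text: str, path: Path) -> dict[str, str]:
    if "ENVI" not in text.splitlines()[0]:
        raise FormatError(f"{path}: missing ENVI magic on first line")
    fields: dict[str, str] = {}
    for m in re.finditer(r"^\s*([A-Za-z][\w ]*?)\s*=\s*(\{.*?\}|[^\n]*)", text, re.M | re.S):
        fields[m.group(1).strip().lower()] = m.group(2).strip()
    return fields


def _data_path_for(header_path: Path) -> Path:
    base = header_path.with_suffix("") if header_path.suffix == ".hdr" else header_path
    for cand in (base, base.with_suffix(".img"), base.with_suffix(".dat"), base.with_suffix(".raw")):
        if cand.exists() and cand != header_path:
            return cand
    raise FormatError(f"no binary payload found next to {header_path}")


def read_cube(header_path: str | Path) -> HyperCube:
    """Read an ENVI header + raw binary cube.

    Supports BIL, BIP and BSQ interleaves and little-endian integer/float
    payloads. The returned cube defaults to ``quantity='radiance'``.
    """
    header_path = Path(header_path)
    if not header_path.exists():
        raise FileNotFoundError(header_path)
    fields = _parse_envi_header(header_path.read_text(), header_path)
    for key in _REQUIRED_KEYS:
        if key not in fields:
            raise FormatError(f"{header_path}: required header field {key!r} missing")

    try:
        samples = int(fields["samples"])
        lines = int(fields["lines"])
        bands = int(fields["bands"])
        dtype_code = int(fields["data type"])
        offset = int(fields.get("header offset", "0"))
    except ValueError as exc:
        raise FormatError(f"{header_path}: non-integer header field ({exc})") from exc
    interleave = fields["interleave"].strip().lower()
    if interleave not in ("bil", "bip", "bsq"):
        raise FormatError(f"{header_path}: unsupported interleave {interleave!r}")
    if dtype_code not in _DTYPE_BY_CODE:
        raise FormatError(f"{header_path}: unsupported data type code {dtype_code}")
    if int(fields.get("byte order", "0")) != 0:
        raise FormatError(f"{header_path}: only byte order 0 (little-endian) is supported")

    wtext = fields["wavelength"].strip()
    if not (wtext.startswith("{") and wtext.endswith("}")):
        raise FormatError(f"{header_path}: wavelength field must be a {{...}} list")
    try:
        wavelengths = np.array(
            [float(t) for t in wtext[1:-1].replace("\n", " ").split(",") if t.strip()]
        )
    except ValueError as exc:
        raise FormatError(f"{header_path}: unparseable wavelength list ({exc})") from exc
    if wavelengths.size != bands:
        raise FormatError(
            f"{header_path}: header declares {bands} bands but "
            f"{wavelengths.size} wavelengths"
        )

    dtype = _DTYPE_BY_CODE[dtype_code]
    data_path = _data_path_for(header_path)
    raw = np.fromfile(data_path, dtype=np.uint8, offset=offset)
    expected = lines * samples * bands * dtype.itemsize
    if raw.nbytes != expected:
        raise FormatError(
            f"{data_path}: payload is {raw.nbytes} bytes, expected {expected} "
            f"({lines}x{samples}x{bands} of {dtype})"
        )
    flat = raw.view(dtype)
    if interleave == "bsq":
        data = flat.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":
        data = flat.reshape(lines, bands, samples).transpose(0, 2, 1)
    else:  # bip
        data = flat.reshape(lines, samples, bands)

    gsd = None
    if "gsd cm per pixel" in fields:
        gsd = float(fields["gsd cm per pixel"])
    quantity = fields.get("quantity", "radiance").strip().lower()
    if quantity not in ("radiance", "reflectance"):
        quantity = "radiance"
    return HyperCube(np.ascontiguousarray(data), wavelengths, quantity, gsd)


def write_cube(cube: HyperCube, header_path: str | Path, interleave: str = "bil") -> Path:
    """Write ``cube`` as an ENVI header (.hdr) plus raw binary (.img).

    Returns the path of the binary payload. Round-trips through
    :func:`read_cube` are bit-exact for little-endian dtypes.
    """
    interleave = interleave.lower()
    if interleave not in ("bil", "bip", "bsq"):
        raise ValueError(f"unsupported interleave {interleave!r}")
    header_path = Path(header_path)
    if header_path.suffix != ".hdr":
        header_path = header_path.with_suffix(header_path.suffix + ".hdr")
    data_path = header_path.with_suffix(".img")

    data = np.asarray(cube.data)
    kind = data.dtype.str.lstrip("<>|=")
    if kind not in _CODE_BY_KIND:
        data = data.astype("<f8")
        kind = "f8"
    dtype_code = _CODE_BY_KIND[kind]
    data = data.astype(data.dtype.newbyteorder("<"), copy=False)

    if interleave == "bsq":
        payload = data.transpose(2, 0, 1)
    elif interleave == "bil":
        payload = data.transpose(0, 2, 1)
    else:
        payload = data
    np.ascontiguousarray(payload).tofile(data_path)

    wl = ", ".join(repr(float(w)) for w in cube.wavelengths_nm)
    lines = [
        "ENVI",
        "description = {moundscan export}",
        f"samples = {cube.cols}",
        f"lines = {cube.rows}",
        f"bands = {cube.n_bands}",
        "header offset = 0",
        "file type = ENVI Standard",
        f"data type = {dtype_code}",
        f"interleave = {interleave}",
        "byte order = 0",
        f"quantity = {cube.quantity}",
        "wavelength units = Nanometers",
        f"wavelength = {{{wl}}}",
    ]
    if cube.gsd_cm_per_px is not None:
        lines.append(f"gsd cm per pixel = {cube.gsd_cm_per_px!r}")
    header_path.write_text("\n".join(lines) + "\n")
    return data_path


# ---------------------------------------------------------------------------
# ROI cropping, pre-cleaning, reflectance
# ---------------------------------------------------------------------------


def crop_roi(cube: HyperCube, register: RoiRegister, roi_id: str) -> HyperCube:
    """Extract the half-open window registered under ``roi_id``."""
    e = register.get(roi_id)
    if e.row0 < 0 or e.col0 < 0 or e.row0 + e.height > cube.rows or e.col0 + e.width > cube.cols:
        raise IndexError(
            f"ROI {roi_id!r} window [{e.row0}:{e.row0 + e.height}, "
            f"{e.col0}:{e.col0 + e.width}] exceeds cube extent "
            f"{cube.rows}x{cube.cols}"
        )
    window = cube.data[e.row0 : e.row0 + e.height, e.col0 : e.col0 + e.width, :].copy()
    return replace(cube, data=window)


def preclean_cube(cube: HyperCube) -> HyperCube:
    """Suppress dark speckle noise with one grayscale closing per band.

    A single iteration of morphological closing with a 3x3 rectangular
    structuring element is applied independently to every band; closing is
    extensive (output >= input) and idempotent, so repeated application is
    a no-op.
    """
    if cube.n_bands < 1:
        raise ValueError("cube must have at least one band")
    closed = ndimage.grey_closing(cube.data, size=(3, 3, 1), mode="nearest")
    return replace(cube, data=closed)


def to_reflectance(
    cube: HyperCube, white: WhiteReference, clip_ceiling: float = 2.0
) -> HyperCube:
    """Divide radiance by the white-reference illuminant, band by band.

    The white spectrum is linearly interpolated onto the cube's wavelength
    axis (no extrapolation). Values above ``clip_ceiling`` are clipped so a
    specular or mis-calibrated pixel cannot dominate classification.
    """
    if cube.quantity != "radiance":
        raise ValueError("to_reflectance expects a radiance cube")
    if clip_ceiling <= 0:
        raise ValueError("clip_ceiling must be positive")
    illum = white.resampled_to(cube.wavelengths_nm)
    if illum.shape[0] != cube.n_bands:
        raise AlignmentError("white reference band count mismatch after resampling")
    if np.any(illum <= 0):
        raise ValueError("white reference non-positive after resampling")
    refl = cube.data / illum[None, None, :]
    np.clip(refl, 0.0, clip_ceiling, out=refl)
    return replace(cube, data=refl, quantity="reflectance")
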