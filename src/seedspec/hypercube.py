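"""ENVI hypercube I/O, reflectance calibration and seed ROI extraction.

A pushbroom NIR camera records raw digital numbers; converting them to
relative reflectance requires a white reference (a ~99% reflectance
board) and a dark reference (lens cap on)::

    R = (I_raw - I_dark) / (I_white - I_dark)

Seeds are imaged embryo-up on black paper, so a single NIR band
separates them from the background by simple thresholding; each seed's
spectrum is the mean over a central rectangular region of interest.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops

from .spectra import SpectraTable

__all__ = [
    "Hypercube",
    "RoiMask",
    "read_envi",
    "write_envi",
    "calibrate",
    "segment_rois",
    "mean_roi_spectrum",
    "spectra_from_rois",
]

log = logging.getLogger(__name__)

# ENVI numeric "data type" codes for the subset we support.
_ENVI_DTYPES = {1: np.uint8, 2: np.int16, 4: np.float32, 5: np.float64, 12: np.uint16}
_DTYPE_CODES = {np.dtype(v): k for k, v in _ENVI_DTYPES.items()}


@dataclass
class Hypercube:
    """A rows x cols x bands reflectance (or raw DN) cube.

    ``kind`` is one of ``raw``, ``reference_white``, ``reference_dark``,
    ``corrected``.
    """

    data: np.ndarray
    wavelengths: np.ndarray
    kind: str = "raw"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("cube must be rows x cols x bands")
        if self.wavelengths.shape != (self.data.shape[2],):
            raise ValueError("wavelength list length != number of bands")
        if self.wavelengths.size > 1 and not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("cube contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def band_nearest(self, nm: float) -> int:
        return int(np.argmin(np.abs(self.wavelengths - nm)))


@dataclass
class RoiMask:
    """Boolean pixel mask with its tight half-open bounding box."""

    mask: np.ndarray
    bounding_box: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError("ROI mask has no true pixel")
        rows, cols = np.nonzero(self.mask)
        tight = (int(rows.min()), int(cols.min()), int(rows.max()) + 1, int(cols.max()) + 1)
        if tuple(self.bounding_box) != tight:
            raise ValueError(f"bounding_box {self.bounding_box} not tight (expected {tight})")

    @classmethod
    def from_mask(cls, mask: np.ndarray) -> "RoiMask":
        rows, cols = np.nonzero(mask)
        bb = (int(rows.min()), int(cols.min()), int(rows.max()) + 1, int(cols.max()) + 1)
        return cls(mask=mask, bounding_box=bb)


# ----------------------------------------------------------------------
# ENVI I/O.  The format is a plain-text header plus a flat binary block
# in band-interleaved (bil/bip/bsq) order.
# ----------------------------------------------------------------------

def _parse_envi_header(header_path: Path) -> dict:
    text = Path(header_path).read_text()
    if not text.lstrip().lower().startswith("envi"):
        raise ValueError(f"{header_path}: not an ENVI header (missing 'ENVI' magic)")
    fields: dict[str, str] = {}
    # join brace-delimited multi-line values before splitting on '='
    body = text.lstrip()[4:]
    pos = 0
    while pos < len(body):
        eq = body.find("=", pos)
        if eq < 0:
            break
        key = body[pos:eq].strip().lower()
        rest = body[eq + 1 :].lstrip()
        if rest.startswith("{"):
            close = rest.find("}")
            if close < 0:
                raise ValueError(f"{header_path}: unterminated '{{' for field {key!r}")
            value = rest[1:close]
            consumed = (eq + 1) + (len(body[eq + 1 :]) - len(rest)) + close + 1
        else:
            nl = rest.find("\n")
            nl = len(rest) if nl < 0 else nl
            value = rest[:nl]
            consumed = (eq + 1) + (len(body[eq + 1 :]) - len(rest)) + nl
        fields[key] = value.strip()
        pos = consumed
    return fields


def read_envi(header_path, data_path) -> Hypercube:
    """Read an ENVI header/binary pair into a rows x cols x bands cube.

    Supports ``bil``, ``bip`` and ``bsq`` interleaves and requires a
    ``wavelength`` field (nm) in the header.
    """
    fields = _parse_envi_header(Path(header_path))
    try:
        lines = int(fields["lines"])
        samples = int(fields["samples"])
        bands = int(fields["bands"])
        interleave = fields["interleave"].lower()
        dtype_code = int(fields["data type"])
    except KeyError as exc:
        raise ValueError(f"{header_path}: missing required header field {exc}") from exc
    if "wavelength" not in fields:
        raise ValueError(f"{header_path}: header has no 'wavelength' field")
    wavelengths = np.array([float(t) for t in fields["wavelength"].split(",") if t.strip()])
    if wavelengths.size != bands:
        raise ValueError(
            f"{header_path}: {wavelengths.size} wavelengths for {bands} bands"
        )
    if interleave not in ("bil", "bip", "bsq"):
        raise ValueError(f"{header_path}: unsupported interleave {interleave!r}")
    if int(fields.get("byte order", "0")) != 0:
        raise ValueError("big-endian ENVI files are not supported")
    dtype = _ENVI_DTYPES.get(dtype_code)
    if dtype is None:
        raise ValueError(f"{header_path}: unsupported ENVI data type {dtype_code}")

    buf = Path(data_path).read_bytes()
    expected = lines * samples * bands * np.dtype(dtype).itemsize
    if len(buf) != expected:
        raise ValueError(
            f"{data_path}: {len(buf)} bytes on disk but header implies {expected} "
            f"({lines}x{samples}x{bands} {np.dtype(dtype).name})"
        )
    flat = np.frombuffer(buf, dtype=dtype)
    if interleave == "bsq":  # (bands, lines, samples)
        cube = flat.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":  # (lines, bands, samples)
        cube = flat.reshape(lines, bands, samples).transpose(0, 2, 1)
    else:  # bip: (lines, samples, bands)
        cube = flat.reshape(lines, samples, bands)
    kind = fields.get("description", "raw").strip() or "raw"
    if kind not in ("raw", "reference_white", "reference_dark", "corrected"):
        kind = "raw"
    return Hypercube(data=cube.copy(), wavelengths=wavelengths, kind=kind)


def write_envi(cube: Hypercube, header_path, data_path, interleave: str = "bsq") -> None:
    """Write a cube as an ENVI header/binary pair (little-endian)."""
    interleave = interleave.lower()
    if interleave not in ("bil", "bip", "bsq"):
        raise ValueError(f"unsupported interleave {interleave!r}")
    data = cube.data
    code = _DTYPE_CODES.get(data.dtype)
    if code is None:
        data = data.astype(np.float64)
        code = _DTYPE_CODES[data.dtype]
    lines, samples, bands = data.shape
    if interleave == "bsq":
        out = data.transpose(2, 0, 1)
    elif interleave == "bil":
        out = data.transpose(0, 2, 1)
    else:
        out = data
    Path(data_path).write_bytes(np.ascontiguousarray(out).tobytes())
    wl = ", ".join(f"{w:.6f}" for w in cube.wavelengths)
    Path(header_path).write_text(
        "ENVI\n"
        f"description = {{{cube.kind}}}\n"
        f"samples = {samples}\n"
        f"lines = {lines}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {code}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        f"wavelength = {{{wl}}}\n"
    )


# ----------------------------------------------------------------------
# Calibration and ROI handling
# ----------------------------------------------------------------------

def calibrate(raw: Hypercube, white: Hypercube, dark: Hypercube) -> Hypercube:
    """Black/white reflectance correction ``(raw - dark)/(white - dark)``.

    Pixels whose white/dark difference is numerically dead (below
    ``1e-6 * max(white)``) are set to 0 with a warning rather than
    poisoning the cube with huge ratios.
    """
    for name, ref in (("white", white), ("dark", dark)):
        if ref.shape != raw.shape:
            raise ValueError(f"{name} reference shape {ref.shape} != raw shape {raw.shape}")
        if not np.allclose(ref.wavelengths, raw.wavelengths):
            raise ValueError(f"{name} reference wavelength grid differs from raw")
    denom = white.data.astype(float) - dark.data.astype(float)
    if not (denom > 0).mean() >= 0.99:
        raise ValueError(
            "white reference is not above dark on >=99% of pixels "
            "(references swapped or invalid)"
        )
    dead = np.abs(denom) < 1e-6 * float(np.max(white.data))
    if dead.any():
        log.warning("calibrate: %d dead pixels (white==dark) set to 0", int(dead.sum()))
        warnings.warn(f"calibrate: {int(dead.sum())} dead pixels set to 0", stacklevel=2)
    num = raw.data.astype(float) - dark.data.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(dead, 0.0, num / np.where(dead, 1.0, denom))
    return Hypercube(data=out, wavelengths=raw.wavelengths.copy(), kind="corrected")


def _central_rectangle(mask: np.ndarray, fraction: float) -> np.ndarray:
    """Rectangle covering ``fraction`` of a component's bbox, centred."""
    rows, cols = np.nonzero(mask)
    r0, r1 = rows.min(), rows.max() + 1
    c0, c1 = cols.min(), cols.max() + 1
    h, w = r1 - r0, c1 - c0
    dh = max(1, int(round(h * fraction)))
    dw = max(1, int(round(w * fraction)))
    rr0 = r0 + (h - dh) // 2
    cc0 = c0 + (w - dw) // 2
    out = np.zeros_like(mask)
    out[rr0 : rr0 + dh, cc0 : cc0 + dw] = True
    return out


def segment_rois(
    cube: Hypercube,
    n_expected: int,
    band_index: int | None = None,
    min_area: int = 30,
    shrink_fraction: float = 0.6,
) -> list[RoiMask]:
    """Find seed ROIs on a dark background at a single NIR band.

    Otsu-thresholds the image at ``band_index`` (default: the band
    nearest 1100 nm), labels connected components, keeps the
    ``n_expected`` largest above ``min_area`` pixels, and returns the
    central rectangle covering ``shrink_fraction`` of each component's
    bounding box (seed-edge pixels carry unstable spectra).  Masks are
    ordered row-major by component centroid.
    """
    if band_index is None:
        band_index = cube.band_nearest(1100.0)
    img = cube.data[:, :, band_index].astype(float)
    if np.ptp(img) == 0:
        raise ValueError("uniform image: nothing to segment")
    thresh = threshold_otsu(img)
    labelled = cc_label(img > thresh)
    props = [p for p in regionprops(labelled) if p.area >= min_area]
    if len(props) < n_expected:
        raise ValueError(
            f"found {len(props)} components >= {min_area} px, expected {n_expected}"
        )
    props = sorted(props, key=lambda p: p.area, reverse=True)[:n_expected]
    props = sorted(props, key=lambda p: (p.centroid[0], p.centroid[1]))
    out = []
    for p in props:
        comp = labelled == p.label
        out.append(RoiMask.from_mask(_central_rectangle(comp, shrink_fraction)))
    return out


def mean_roi_spectrum(cube: Hypercube, roi: RoiMask) -> np.ndarray:
    """Arithmetic mean spectrum over the masked pixels (length = bands)."""
    if roi.mask.shape != cube.shape[:2]:
        raise ValueError(
            f"mask shape {roi.mask.shape} != cube spatial shape {cube.shape[:2]}"
        )
    return cube.data[roi.mask, :].mean(axis=0)


def spectra_from_rois(
    cube: Hypercube, rois: list[RoiMask], labels, sample_ids=None
) -> SpectraTable:
    """Stack per-ROI mean spectra into a :class:`SpectraTable`."""
    values = np.stack([mean_roi_spectrum(cube, r) for r in rois])
    return SpectraTable(
        values=values,
        wavelengths=cube.wavelengths.copy(),
        labels=np.asarray(labels, dtype=int),
        sample_ids=list(sample_ids) if sample_ids is not None else [],
    )
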