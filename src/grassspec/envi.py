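"""ENVI cube I/O and white/dark radiometric calibration.

Line-scan hyperspectral instruments store a cube as a plain binary file
plus a small text header describing its shape, interleave and wavelength
grid.  This module reads and writes that format (BIL/BIP/BSQ interleaves,
float32/float64/uint16 samples, either byte order) and converts raw
irradiance counts to reflectance with the standard two-point calibration

    R = (I - D) / (W - D)

against a white (Spectralon tile) and a dark (lens cap) reference frame.
Reflectance is deliberately *not* clipped to [0, 1]: bright specular tissue
such as pseudostem routinely calibrates above 1 and clipping would destroy
signal.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "RawCube",
    "ReferencePair",
    "ReflectanceCube",
    "read_envi",
    "write_envi",
    "calibrate",
    "band_index",
]

# ENVI numeric codes for the sample types we support
_DTYPE_TO_CODE = {"uint16": 12, "float32": 4, "float64": 5}
_CODE_TO_DTYPE = {v: k for k, v in _DTYPE_TO_CODE.items()}


@dataclass
class RawCube:
    """Raw sensor irradiance, axis order (line, sample, band)."""

    irradiance: np.ndarray
    wavelengths: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.irradiance = np.asarray(self.irradiance)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.irradiance.ndim != 3:
            raise ValueError("irradiance must be 3-D (line, sample, band)")
        if self.wavelengths.ndim != 1 or len(self.wavelengths) != self.irradiance.shape[2]:
            raise ValueError(
                f"wavelength grid length {len(self.wavelengths)} does not match "
                f"band dimension {self.irradiance.shape[2]}"
            )
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.irradiance.shape


@dataclass
class ReferencePair:
    """White and dark reference frames, per (sample, band), broadcast along lines."""

    white: np.ndarray
    dark: np.ndarray

    def __post_init__(self) -> None:
        self.white = np.atleast_2d(np.asarray(self.white, dtype=float))
        self.dark = np.atleast_2d(np.asarray(self.dark, dtype=float))
        if self.white.shape != self.dark.shape:
            raise ValueError(
                f"white shape {self.white.shape} != dark shape {self.dark.shape}"
            )


@dataclass
class ReflectanceCube:
    """Calibrated reflectance with a mask of pixels where calibration failed."""

    reflectance: np.ndarray
    wavelengths: np.ndarray
    invalid_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.invalid_mask is None:
            self.invalid_mask = np.zeros(self.reflectance.shape[:2], dtype=bool)
        self.invalid_mask = np.asarray(self.invalid_mask, dtype=bool)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.reflectance.shape

    @property
    def valid_mask(self) -> np.ndarray:
        return ~self.invalid_mask


def _parse_header(text: str) -> dict:
    """Parse an ENVI header into a {key: value} dict.

    Values in ``{ ... }`` (possibly spanning lines) become lists of strings.
    """
    if not text.lstrip().upper().startswith("ENVI"):
        raise ValueError("not an ENVI header (missing ENVI magic line)")
    fields: dict = {}
    # strip the magic line, then match "key = value" with brace blocks
    body = text.split("\n", 1)[1] if "\n" in text else ""
    pattern = re.compile(r"^\s*([\w ]+?)\s*=\s*(\{[^}]*\}|[^\n]*)", re.M | re.S)
    for m in pattern.finditer(body):
        key = m.group(1).strip().lower()
        raw = m.group(2).strip()
        if raw.startswith("{"):
            inner = raw.strip("{}").replace("\n", " ")
            fields[key] = [tok.strip() for tok in inner.split(",") if tok.strip()]
        else:
            fields[key] = raw
    return fields


def read_envi(header_path: str | Path) -> RawCube:
    """Read an ENVI cube; returns axis order (line, sample, band) for any interleave.

    The binary file is located by replacing the header suffix (``.hdr``) or
    taken from a ``data file`` header field.
    """
    header_path = Path(header_path)
    fields = _parse_header(header_path.read_text())

    try:
        lines = int(fields["lines"])
        samples = int(fields["samples"])
        bands = int(fields["bands"])
    except KeyError as exc:
        raise ValueError(f"ENVI header missing required field {exc}") from exc
    if "wavelength" not in fields:
        raise ValueError("ENVI header has no wavelength list")
    wavelengths = np.array([float(w) for w in fields["wavelength"]])
    if len(wavelengths) != bands:
        raise ValueError(
            f"wavelength list length {len(wavelengths)} != bands {bands}"
        )

    interleave = str(fields.get("interleave", "bil")).lower()
    if interleave not in ("bil", "bip", "bsq"):
        raise ValueError(f"unsupported interleave {interleave!r}")
    code = int(fields.get("data type", 4))
    if code not in _CODE_TO_DTYPE:
        raise ValueError(f"unsupported ENVI data type code {code}")
    dtype = np.dtype(_CODE_TO_DTYPE[code])
    if int(fields.get("byte order", 0)) == 1:
        dtype = dtype.newbyteorder(">")
    else:
        dtype = dtype.newbyteorder("<")
    offset = int(fields.get("header offset", 0))

    if "data file" in fields:
        binary_path = header_path.parent / str(fields["data file"])
    else:
        binary_path = header_path.with_suffix("")
        if not binary_path.exists():
            binary_path = header_path.with_suffix(".img")
    expected = lines * samples * bands * dtype.itemsize + offset
    actual = binary_path.stat().st_size
    if actual != expected:
        raise ValueError(
            f"binary size mismatch for {binary_path}: expected {expected} bytes "
            f"from header, found {actual}"
        )

    flat = np.fromfile(binary_path, dtype=dtype, offset=offset)
    if interleave == "bil":  # (line, band, sample)
        cube = flat.reshape(lines, bands, samples).transpose(0, 2, 1)
    elif interleave == "bip":  # (line, sample, band)
        cube = flat.reshape(lines, samples, bands)
    else:  # bsq: (band, line, sample)
        cube = flat.reshape(bands, lines, samples).transpose(1, 2, 0)
    meta = {k: v for k, v in fields.items() if k not in (
        "lines", "samples", "bands", "wavelength", "interleave",
        "data type", "byte order", "header offset")}
    return RawCube(np.ascontiguousarray(cube), wavelengths, meta)


def write_envi(
    header_path: str | Path,
    cube: np.ndarray,
    wavelengths: np.ndarray,
    interleave: str = "bil",
    dtype: str = "float32",
    meta: dict | None = None,
) -> Path:
    """Write an (line, sample, band) array as an ENVI header + binary pair.

    Returns the path of the binary file (header path without its suffix).
    """
    header_path = Path(header_path)
    cube = np.asarray(cube)
    interleave = interleave.lower()
    if interleave not in ("bil", "bip", "bsq"):
        raise ValueError(f"unsupported interleave {interleave!r}")
    if dtype not in _DTYPE_TO_CODE:
        raise ValueError(f"unsupported dtype {dtype!r}")
    lines, samples, bands = cube.shape
    if len(wavelengths) != bands:
        raise ValueError("wavelength grid length must equal band count")

    if interleave == "bil":
        ordered = cube.transpose(0, 2, 1)
    elif interleave == "bip":
        ordered = cube
    else:
        ordered = cube.transpose(2, 0, 1)

    binary_path = header_path.with_suffix("")
    ordered.astype(np.dtype(dtype).newbyteorder("<")).tofile(binary_path)

    wl = ", ".join(f"{w:.6f}" for w in np.asarray(wavelengths, dtype=float))
    extra = "".join(f"{k} = {v}\n" for k, v in (meta or {}).items())
    header_path.write_text(
        "ENVI\n"
        f"samples = {samples}\n"
        f"lines = {lines}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        f"data type = {_DTYPE_TO_CODE[dtype]}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        f"{extra}"
        f"wavelength = {{{wl}}}\n"
    )
    return binary_path


def calibrate(raw: RawCube, refs: ReferencePair) -> ReflectanceCube:
    """Two-point radiometric calibration R = (I - D) / (W - D).

    The references are per-(sample, band) and broadcast along the line axis.
    Pixels where W - D <= 0 at any band are flagged invalid (reflectance set
    to 0 there) and must be excluded from downstream statistics.
    """
    irr = np.asarray(raw.irradiance, dtype=float)
    lines, samples, bands = irr.shape
    white, dark = refs.white, refs.dark
    if white.shape not in ((samples, bands), (1, bands)):
        raise ValueError(
            f"reference shape {white.shape} incompatible with cube (samples, bands)"
            f" = ({samples}, {bands})"
        )
    denom = white - dark
    bad = denom <= 0  # per (sample, band) or (1, band)
    with np.errstate(divide="ignore", invalid="ignore"):
        refl = (irr - dark[None]) / denom[None]
    bad_sample = bad.any(axis=-1)  # (samples,) or (1,)
    invalid = np.broadcast_to(bad_sample[None], (lines, samples)).copy()
    if bad.any():
        refl = np.where(np.broadcast_to(bad[None], refl.shape), 0.0, refl)
    return ReflectanceCube(refl, raw.wavelengths, invalid)


def band_index(wavelengths: np.ndarray, target_nm: float) -> int:
    """Index of the band nearest ``target_nm``; ties go to the lower wavelength.

    Targets farther than one grid spacing outside the grid are rejected.
    """
    wl = np.asarray(wavelengths, dtype=float)
    if wl.size == 0:
        raise ValueError("empty wavelength grid")
    spacing = float(np.max(np.diff(wl))) if wl.size > 1 else 0.0
    if target_nm < wl[0] - spacing or target_nm > wl[-1] + spacing:
        raise ValueError(
            f"target {target_nm} nm outside grid [{wl[0]}, {wl[-1]}] ± {spacing}"
        )
    dist = np.abs(wl - target_nm)
    # argmin returns the first (lower-wavelength) index on exact ties
    return int(np.argmin(dist))
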