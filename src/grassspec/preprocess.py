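"""Spectral preprocessing: standard normal variate, range restriction, band subsampling.

SNV standardizes each spectrum to mean 0 and unit sample (n-1) standard
deviation, removing additive offsets and multiplicative scatter/lighting
effects.  Restriction and subsampling carve out wavelength subsets for the
restricted-range and every-2nd-wavelength analyses; when SNV is wanted on a
subset it must be recomputed on that subset, not inherited from the full
spectrum.
"""

from __future__ import annotations

import numpy as np

__all__ = ["snv", "restrict_range", "subsample_bands", "apply_pipeline"]


def snv(spectrum: np.ndarray) -> np.ndarray:
    """Standard normal variate: (x - mean(x)) / sd(x), sample (n-1) sd.

    Works on a single spectrum (1-D) or a stack of spectra (last axis =
    bands).  A constant spectrum has no scatter to normalize and signals a
    degenerate or saturated pixel, so it is rejected.
    """
    x = np.asarray(spectrum, dtype=float)
    if x.shape[-1] < 2:
        raise ValueError("SNV needs at least 2 bands")
    mean = x.mean(axis=-1, keepdims=True)
    sd = x.std(axis=-1, ddof=1, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("constant spectrum: SNV undefined (sd = 0)")
    return (x - mean) / sd


def restrict_range(
    spectrum: np.ndarray,
    wavelengths: np.ndarray,
    lo_nm: float,
    hi_nm: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Keep bands with lo_nm <= wavelength <= hi_nm (inclusive both ends).

    Returns (sub_spectrum, sub_wavelengths); works on 1-D spectra or stacks.
    """
    if not lo_nm < hi_nm:
        raise ValueError(f"lo_nm {lo_nm} must be < hi_nm {hi_nm}")
    wl = np.asarray(wavelengths, dtype=float)
    keep = (wl >= lo_nm) & (wl <= hi_nm)
    if not keep.any():
        raise ValueError(f"no bands in range [{lo_nm}, {hi_nm}] nm")
    x = np.asarray(spectrum, dtype=float)
    return x[..., keep], wl[keep]


def subsample_bands(
    spectrum: np.ndarray, stride: int = 2, offset: int = 1
) -> np.ndarray:
    """Keep bands at positions offset, offset+stride, ...

    The default (stride 2, offset 1) maps a 235-band grid onto the 117 bands
    used for the every-2nd-wavelength analyses.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if not 0 <= offset < stride:
        raise ValueError(f"offset {offset} must satisfy 0 <= offset < stride {stride}")
    x = np.asarray(spectrum)
    return x[..., offset::stride]


def apply_pipeline(
    spectra: np.ndarray,
    wavelengths: np.ndarray,
    pipeline: dict,
) -> tuple[np.ndarray, np.ndarray]:
    """Apply a recorded preprocessing pipeline to raw reflectance spectra.

    ``pipeline`` is the provenance dict a fitted model carries: optional
    keys ``lo_nm``/``hi_nm`` (range restriction), ``stride``/``offset``
    (band subsampling) and ``snv`` (bool).  Steps run in that order; SNV is
    computed on the restricted/subsampled band set.  Returns the processed
    spectra and the matching wavelength grid.
    """
    x = np.asarray(spectra, dtype=float)
    wl = np.asarray(wavelengths, dtype=float)
    if "lo_nm" in pipeline or "hi_nm" in pipeline:
        x, wl = restrict_range(
            x, wl, pipeline.get("lo_nm", wl[0]), pipeline.get("hi_nm", wl[-1])
        )
    stride = int(pipeline.get("stride", 1))
    if stride > 1:
        offset = int(pipeline.get("offset", 0))
        x = subsample_bands(x, stride, offset)
        wl = subsample_bands(wl, stride, offset)
    if pipeline.get("snv", False):
        x = snv(x)
    return x, wl
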