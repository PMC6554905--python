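"""Region-of-interest segmentation and plant-level spectrum extraction.

Plant pixels are those with reflectance >= 0.3 at the band nearest 1080 nm
(a wavelength little affected by water content, so the cutoff is stable
across hydration states).  Plant-level spectra are per-band means over the
ROI, averaged (unweighted) over the 1-3 replicate images of a plant; plants
whose mean ROI pixel count falls below 5000 are flagged for exclusion.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .envi import ReflectanceCube, band_index

__all__ = [
    "RoiMask",
    "PlantSpectrum",
    "segment",
    "mean_spectrum",
    "aggregate_plant",
    "write_mask_png",
    "write_mask_csv",
    "spectra_to_frame",
]

DEFAULT_THRESHOLD_R = 0.3
DEFAULT_THRESHOLD_NM = 1080.0
DEFAULT_MIN_PIXELS = 5000.0


@dataclass
class RoiMask:
    mask: np.ndarray
    threshold_nm: float
    threshold_r: float

    @property
    def n_pixels(self) -> int:
        return int(np.count_nonzero(self.mask))


@dataclass
class PlantSpectrum:
    """Plant-level mean reflectance with replicate provenance."""

    plant_id: object
    tissue: str
    spectrum: np.ndarray
    n_pixels_mean: float
    n_images: int
    excluded: bool = False

    def __post_init__(self) -> None:
        if self.n_images not in (1, 2, 3):
            raise ValueError(f"n_images must be 1, 2 or 3, got {self.n_images}")


def segment(
    cube: ReflectanceCube,
    threshold_r: float = DEFAULT_THRESHOLD_R,
    threshold_nm: float = DEFAULT_THRESHOLD_NM,
) -> RoiMask:
    """Threshold the band nearest ``threshold_nm`` at ``threshold_r`` (inclusive).

    Pixels with invalid calibration are never selected.
    """
    band = band_index(cube.wavelengths, threshold_nm)
    mask = (cube.reflectance[:, :, band] >= threshold_r) & cube.valid_mask
    return RoiMask(mask, threshold_nm, threshold_r)


def mean_spectrum(cube: ReflectanceCube, roi: RoiMask | np.ndarray) -> tuple[np.ndarray, int]:
    """Per-band arithmetic mean over the masked pixels; returns (spectrum, n_pixels)."""
    mask = roi.mask if isinstance(roi, RoiMask) else np.asarray(roi, dtype=bool)
    n = int(np.count_nonzero(mask))
    if n == 0:
        raise ValueError("empty ROI mask: segmentation found no plant pixels")
    return cube.reflectance[mask].mean(axis=0), n


def aggregate_plant(
    replicates: list[tuple[np.ndarray, float]],
    plant_id: object = None,
    tissue: str = "BL",
    min_pixels: float = DEFAULT_MIN_PIXELS,
) -> PlantSpectrum:
    """Average 1-3 replicate (spectrum, n_pixels) pairs into one PlantSpectrum.

    The replicate mean is unweighted.  Plants averaging fewer than
    ``min_pixels`` ROI pixels are returned flagged ``excluded`` (not an
    error: the caller drops them from the analysis set).
    """
    if len(replicates) == 0:
        raise ValueError("at least one replicate image is required")
    if len(replicates) > 3:
        raise ValueError(f"at most 3 replicate images supported, got {len(replicates)}")
    spectra = np.stack([np.asarray(s, dtype=float) for s, _ in replicates])
    counts = np.array([float(n) for _, n in replicates])
    mean_count = float(counts.mean())
    return PlantSpectrum(
        plant_id=plant_id,
        tissue=tissue,
        spectrum=spectra.mean(axis=0),
        n_pixels_mean=mean_count,
        n_images=len(replicates),
        excluded=mean_count < min_pixels,
    )


def write_mask_png(roi: RoiMask, path: str | Path) -> Path:
    """Export the mask as an 8-bit PNG (foreground 255, background 0)."""
    import matplotlib.image

    path = Path(path)
    matplotlib.image.imsave(path, roi.mask.astype(np.uint8) * 255, cmap="gray",
                            vmin=0, vmax=255)
    return path


def write_mask_csv(roi: RoiMask, path: str | Path) -> Path:
    """Export the mask as a flat CSV of selected (line, sample) pairs."""
    lines, samples = np.nonzero(roi.mask)
    pd.DataFrame({"line": lines, "sample": samples}).to_csv(path, index=False)
    return Path(path)


def spectra_to_frame(plants: list[PlantSpectrum], wavelengths: np.ndarray) -> pd.DataFrame:
    """Tabulate plant spectra: id, tissue, provenance, then one column per band."""
    rows = []
    for p in plants:
        row = {
            "plant_id": p.plant_id,
            "tissue": p.tissue,
            "n_images": p.n_images,
            "n_pixels_mean": p.n_pixels_mean,
            "excluded": p.excluded,
        }
        row.update({f"{w:.1f}": v for w, v in zip(wavelengths, p.spectrum)})
        rows.append(row)
    return pd.DataFrame(rows)
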