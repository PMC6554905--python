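"""Per-pixel trait mapping and false-color visualization.

A model calibrated on plant-level mean spectra is applied to every plant
pixel: each pixel's spectrum goes through exactly the preprocessing
pipeline recorded on the model (range restriction, subsampling, SNV) and
then through the regression vector.  Because SNV standardizes each pixel
spectrum individually, the resulting maps are invariant to multiplicative
lighting gradients across the scan.  Background, invalid-calibration and
very-low-reflectance pixels are masked.

Single-pixel spectra carry sensor noise that plant-mean calibration
spectra do not; the noise inflates the per-pixel SNV scale estimate and
systematically shrinks the standardized spectrum, which a large PLS
regression vector amplifies into a concentration bias.  ``predict_map``
therefore applies a local masked box filter (default 3 x 3, set
``smooth_window=1`` to disable) before preprocessing; on a spatially
uniform cube the filter is exact, and it preserves the SNV
lighting-gradient invariance because neighbouring ramp factors stay
multiplicative.

Applying a plant-level calibration at pixel scale remains a calibration
transfer; it is unbiased for our log-linear forward model at small
absorbances but can introduce bias on real canopies (mixed pixels,
specular highlights) — see the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import pls, roi
from .envi import ReflectanceCube, band_index
from .preprocess import apply_pipeline

__all__ = ["TraitMap", "predict_map", "false_color", "write_map_csv", "write_map_png"]


@dataclass
class TraitMap:
    """Per-pixel predicted attribute values with an exclusion mask."""

    values: np.ndarray           # (line, sample), NaN where masked
    masked: np.ndarray           # True where excluded
    attribute: str = ""
    units: str = ""

    def zone_mean(self, zone: np.ndarray) -> float:
        """Mean prediction over the unmasked pixels of a boolean zone."""
        sel = np.asarray(zone, dtype=bool) & ~self.masked
        if not sel.any():
            raise ValueError("zone contains no unmasked pixels")
        return float(self.values[sel].mean())


def predict_map(
    cube: ReflectanceCube,
    model: pls.PLSModel,
    low_reflectance_cutoff: float = 0.05,
    threshold_r: float = roi.DEFAULT_THRESHOLD_R,
    threshold_nm: float = roi.DEFAULT_THRESHOLD_NM,
    smooth_window: int = 3,
    attribute: str = "",
    units: str = "",
) -> TraitMap:
    """Predict an attribute for every plant pixel of a reflectance cube.

    Pixels are masked when segmentation rejects them, their calibration is
    invalid, or their mean reflectance over all bands falls below
    ``low_reflectance_cutoff``.  ``smooth_window`` controls the masked box
    filter applied before preprocessing (odd, in pixels; 1 disables it).
    """
    if smooth_window < 1 or smooth_window % 2 == 0:
        raise ValueError("smooth_window must be a positive odd integer")
    mask = roi.segment(cube, threshold_r, threshold_nm).mask
    mask &= cube.reflectance.mean(axis=2) >= low_reflectance_cutoff
    lines, samples, _ = cube.shape
    values = np.full((lines, samples), np.nan)
    if mask.any():
        refl = cube.reflectance
        if smooth_window > 1:
            refl = _masked_box_filter(refl, mask, smooth_window)
        spectra = refl[mask]
        X, _wl = apply_pipeline(spectra, cube.wavelengths, model.pipeline)
        if X.shape[1] != model.n_bands:
            raise ValueError(
                f"cube yields {X.shape[1]} bands after preprocessing but the "
                f"model expects {model.n_bands}"
            )
        values[mask] = pls.predict(model, X)
    return TraitMap(values, ~mask, attribute, units)


def _masked_box_filter(
    refl: np.ndarray, mask: np.ndarray, window: int
) -> np.ndarray:
    """Spatial box average over plant pixels only (background never leaks in).

    Each plant pixel is replaced by the mean of the plant pixels inside its
    window; normalizing by the local mask coverage makes the filter exact on
    spatially uniform regions and at ROI edges.
    """
    from scipy import ndimage

    weights = ndimage.uniform_filter(
        mask.astype(float), size=window, mode="constant"
    )
    summed = ndimage.uniform_filter(
        refl * mask[:, :, None], size=(window, window, 1), mode="constant"
    )
    out = refl.copy()
    valid = mask & (weights > 0)
    out[valid] = summed[valid] / weights[valid][:, None]
    return out


def false_color(
    cube: ReflectanceCube,
    bands_nm: tuple[float, float, float] = (558.0, 740.0, 937.0),
) -> np.ndarray:
    """Three-channel visualization from reflectance at the named wavelengths.

    Each channel is min-max scaled to [0, 1] over valid pixels; a channel
    with zero range maps to 0.  Returns an array of shape (lines, samples, 3).
    """
    idx = [band_index(cube.wavelengths, nm) for nm in bands_nm]
    img = cube.reflectance[:, :, idx].astype(float).copy()
    valid = cube.valid_mask
    for c in range(3):
        channel = img[:, :, c]
        vals = channel[valid]
        lo, hi = float(vals.min()), float(vals.max())
        if hi > lo:
            img[:, :, c] = np.clip((channel - lo) / (hi - lo), 0.0, 1.0)
        else:
            img[:, :, c] = 0.0
    return img


def write_map_csv(trait_map: TraitMap, path: str | Path) -> Path:
    """Write the map as a plain CSV grid (empty cells where masked)."""
    path = Path(path)
    np.savetxt(path, trait_map.values, delimiter=",", fmt="%.6g")
    return path


def write_map_png(trait_map: TraitMap, path: str | Path, cmap: str = "viridis") -> Path:
    """Render the map as a PNG with masked pixels in white."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    path = Path(path)
    fig, ax = plt.subplots(figsize=(5, 6))
    data = np.ma.masked_where(trait_map.masked, trait_map.values)
    cmap_obj = matplotlib.colormaps[cmap].copy()
    cmap_obj.set_bad("white")
    im = ax.imshow(data, cmap=cmap_obj)
    label = f"{trait_map.attribute} ({trait_map.units})".strip(" ()")
    fig.colorbar(im, ax=ax, label=label)
    ax.set_xlabel("sample")
    ax.set_ylabel("line")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return path
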