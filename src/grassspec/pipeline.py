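"""End-to-end desk-scale study orchestration.

``run_study`` drives the whole chain on synthetic data: simulate plants and
acquisitions, calibrate raw counts to reflectance, segment the plant ROI,
extract and aggregate replicate mean spectra, apply the 5000-pixel-rule
(scaled to the configured scene), preprocess (SNV, optional wavelength
restriction), split plants two-thirds/one-third, fit the requested methods
per attribute and emit report rows.  Everything is seeded and reproducible
bit-for-bit from the same configuration.

The default scene is a reduced 80 x 64-pixel acquisition (the full
instrument geometry of 400 x 320 is available but unnecessary for testing
the statistics); the pixel-count exclusion threshold is scaled by the same
pixel ratio so the rule bites identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import pls, roi, selection
from .envi import calibrate
from .preprocess import apply_pipeline
from .synthetic import (
    AttributeSpec,
    EndmemberLibrary,
    SceneConfig,
    default_attribute_specs,
    default_library,
    generate_attribute_table,
    generate_cube,
)

__all__ = ["StudyConfig", "StudyResult", "run_study", "run_visual_yield",
           "visual_yield_model"]

FULL_SCENE_PIXELS = 400 * 320


@dataclass
class StudyConfig:
    """Configuration of one simulated study."""

    n_plants: int = 185
    n_ps_plants: int = 15                 # plants with separate PS acquisitions
    attributes: tuple = ("Nitrogen", "Sugars")
    dataset: str = "BL+PS"                # "BL+PS" or "BL"
    wavelength_range: tuple | None = None  # (lo_nm, hi_nm); None = full
    methods: tuple = ("PLSR-AW",)
    n_images: int | None = None           # None: 2 or 3 per plant, seeded
    snv: bool = True
    scene: SceneConfig = field(default_factory=lambda: SceneConfig(
        lines=80, samples=64, plant_fraction=0.45))
    min_pixels: float | None = None       # None: 5000 scaled by scene pixels
    sim_seed: int = 1
    split_seed: int = 2
    cv_seed: int = 3
    cv_reps: int = 15
    lv_max: int = 20
    cal_frac: float = 2.0 / 3.0
    ps_fraction: float = 0.3              # tissue weight for whole-plant values

    def __post_init__(self) -> None:
        if self.dataset not in ("BL+PS", "BL"):
            raise ValueError(f"dataset must be 'BL+PS' or 'BL', got {self.dataset!r}")

    def resolved_min_pixels(self) -> float:
        """Explicit threshold, or the 5000-pixel rule scaled to the scene size."""
        if self.min_pixels is not None:
            return float(self.min_pixels)
        scene_px = self.scene.lines * self.scene.samples
        return roi.DEFAULT_MIN_PIXELS * scene_px / FULL_SCENE_PIXELS


@dataclass
class StudyResult:
    reports: pd.DataFrame
    models: dict                     # (attribute, method) -> fitted PLSModel or None
    spectra: pd.DataFrame            # plant-level spectra table with provenance
    table: pd.DataFrame              # ground-truth attribute table
    cal_ids: np.ndarray
    val_ids: np.ndarray
    excluded_ids: list
    library: EndmemberLibrary
    config: StudyConfig
    log: list

    def write(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.reports.to_csv(out / "reports.csv", index=False)
        self.spectra.to_csv(out / "plant_spectra.csv", index=False)
        self.table.to_csv(out / "attributes.csv", index=False)
        (out / "log.txt").write_text("\n".join(self.log) + "\n")
        return out


def _replicate_counts(config: StudyConfig, rng: np.random.Generator) -> np.ndarray:
    if config.n_images is not None:
        if not 1 <= config.n_images <= 3:
            raise ValueError("n_images must be between 1 and 3")
        return np.full(config.n_plants, config.n_images, dtype=int)
    return rng.integers(2, 4, size=config.n_plants)  # 2 or 3, as acquired


def _collect_plant_spectra(
    config: StudyConfig,
    table: pd.DataFrame,
    library: EndmemberLibrary,
    specs: list[AttributeSpec],
    log: list,
) -> list[roi.PlantSpectrum]:
    """Simulate, calibrate, segment and aggregate every acquisition."""
    rng = np.random.default_rng(config.sim_seed + 7)
    reps_per_plant = _replicate_counts(config, rng)
    names = [s.name for s in specs]
    rows = {t: table[table.tissue == t].set_index("plant_id") for t in ("BL", "PS")}

    tissues_for = {}
    for plant in range(1, config.n_plants + 1):
        tissues_for[plant] = ["BL"]
        if config.dataset == "BL+PS" and plant <= config.n_ps_plants:
            tissues_for[plant].append("PS")

    plants: list[roi.PlantSpectrum] = []
    for plant in range(1, config.n_plants + 1):
        for tissue in tissues_for[plant]:
            values = rows[tissue].loc[plant, names].to_dict()
            fraction = config.scene.plant_fraction
            if "VisualYield" in values:
                # visual ground-cover drives how much of the frame is plant
                fraction = float(np.clip(values["VisualYield"] / 100.0, 0.05, 0.9))
            replicates = []
            for rep in range(reps_per_plant[plant - 1]):
                scene = replace(
                    config.scene,
                    plant_fraction=fraction,
                    seed=config.sim_seed + 10_000 * plant + 100 * rep
                    + (50 if tissue == "PS" else 0),
                )
                sim = generate_cube(values, library, scene, tissue=tissue)
                cube = calibrate(sim.raw, sim.refs)
                mask = roi.segment(cube)
                spectrum, n_px = roi.mean_spectrum(cube, mask)
                replicates.append((spectrum, n_px))
            plants.append(
                roi.aggregate_plant(
                    replicates, plant_id=plant, tissue=tissue,
                    min_pixels=config.resolved_min_pixels(),
                )
            )
    n_excluded = sum(p.excluded for p in plants)
    log.append(
        f"collected {len(plants)} plant spectra "
        f"({sum(reps_per_plant)} BL acquisitions), {n_excluded} excluded by pixel rule"
    )
    return plants


def run_study(config: StudyConfig, out_dir: str | Path | None = None) -> StudyResult:
    """Run the full simulated study; optionally write reports to ``out_dir``."""
    log: list[str] = [f"study config: {config}"]
    specs = default_attribute_specs()
    library = default_library(config.scene.bands)
    table = generate_attribute_table(
        specs, config.n_plants, config.sim_seed, ps_fraction=config.ps_fraction
    )
    log.append(f"simulated attribute table for {config.n_plants} plants (seed {config.sim_seed})")

    plants = _collect_plant_spectra(config, table, library, specs, log)
    excluded_ids = [(p.plant_id, p.tissue) for p in plants if p.excluded]
    plants = [p for p in plants if not p.excluded]

    spectra_frame = roi.spectra_to_frame(plants, library.wavelengths)

    pipeline: dict = {"snv": config.snv}
    if config.wavelength_range is not None:
        pipeline["lo_nm"], pipeline["hi_nm"] = config.wavelength_range
    raw_X = np.stack([p.spectrum for p in plants])
    X, _wl = apply_pipeline(raw_X, library.wavelengths, pipeline)
    sample_ids = np.array([p.plant_id for p in plants])
    sample_tissue = np.array([p.tissue for p in plants])

    cal_ids, val_ids = selection.split_calibration_validation(
        sample_ids, frac=config.cal_frac, seed=config.split_seed
    )
    in_cal = np.isin(sample_ids, cal_ids)
    log.append(
        f"plant-level split (seed {config.split_seed}): {len(cal_ids)} calibration, "
        f"{len(val_ids)} validation plants"
    )

    truth = {t: table[table.tissue == t].set_index("plant_id") for t in ("BL", "PS")}
    rows, models = [], {}
    for attribute in config.attributes:
        y = np.array([
            truth[t].loc[pid, attribute] for pid, t in zip(sample_ids, sample_tissue)
        ])
        Xc, yc = X[in_cal], y[in_cal]
        Xv, yv = X[~in_cal], y[~in_cal]
        for method in config.methods:
            rep = selection.run_method(
                method, Xc, yc, Xv, yv, seed=config.cv_seed,
                attribute=attribute, cv_reps=config.cv_reps, lv_max=config.lv_max,
            )
            rep.extra["dataset"] = config.dataset
            rep.extra["range"] = (
                "full" if config.wavelength_range is None
                else f"{config.wavelength_range[0]:g}-{config.wavelength_range[1]:g} nm"
            )
            rows.append(rep.to_row())
            model = None
            if method.upper().startswith("PLSR") and rep.lv:
                model = pls.fit_plsr(Xc, yc, n_lv=rep.lv, pipeline=pipeline)
            models[(attribute, method.upper())] = model
            log.append(
                f"{attribute} / {method}: R2_val = {rep.r2_val:.3f}, "
                f"RMSE_val = {rep.rmse_val:.3g}, LV = {rep.lv}"
            )

    result = StudyResult(
        reports=pd.DataFrame(rows),
        models=models,
        spectra=spectra_frame,
        table=table,
        cal_ids=cal_ids,
        val_ids=val_ids,
        excluded_ids=excluded_ids,
        library=library,
        config=config,
        log=log,
    )
    if out_dir is not None:
        result.write(out_dir)
    return result


def visual_yield_model(
    X_cal: np.ndarray,
    counts_cal: np.ndarray,
    y_cal: np.ndarray,
    X_val: np.ndarray,
    counts_val: np.ndarray,
    y_val: np.ndarray,
    cv_reps: int = 15,
    lv_max: int = 10,
    seed: int = 0,
) -> pls.ModelReport:
    """PLSR for visual yield with ROI pixel count as an extra predictor.

    The pixel-count column is standardized with calibration statistics; a
    zero-variance column is dropped, which reduces the model to the
    spectrum-only one.
    """
    counts_cal = np.asarray(counts_cal, dtype=float).ravel()
    counts_val = np.asarray(counts_val, dtype=float).ravel()
    if len(counts_cal) != len(y_cal) or len(counts_val) != len(y_val):
        raise ValueError("pixel counts must be available for every sample")
    mu, sd = counts_cal.mean(), counts_cal.std(ddof=1)
    augmented = sd > 0
    if augmented:
        X_cal = np.column_stack([X_cal, (counts_cal - mu) / sd])
        X_val = np.column_stack([X_val, (counts_val - mu) / sd])
    rep = selection.run_method(
        "PLSR-AW", X_cal, y_cal, X_val, y_val, seed=seed,
        attribute="VisualYield", cv_reps=cv_reps, lv_max=lv_max,
    )
    rep.extra["predictors"] = "spectra+pixel_count" if augmented else "spectra"
    return rep


def run_visual_yield(config: StudyConfig) -> pls.ModelReport:
    """Visual-yield study: simulate, extract spectra + pixel counts, fit."""
    log: list[str] = []
    specs = default_attribute_specs()
    library = default_library(config.scene.bands)
    table = generate_attribute_table(
        specs, config.n_plants, config.sim_seed, ps_fraction=config.ps_fraction
    )
    plants = _collect_plant_spectra(config, table, library, specs, log)
    plants = [p for p in plants if not p.excluded and p.tissue == "BL"]

    pipeline = {"snv": config.snv}
    raw_X = np.stack([p.spectrum for p in plants])
    X, _ = apply_pipeline(raw_X, library.wavelengths, pipeline)
    counts = np.array([p.n_pixels_mean for p in plants])
    ids = np.array([p.plant_id for p in plants])
    truth = table[table.tissue == "BL"].set_index("plant_id")
    y = truth.loc[ids, "VisualYield"].to_numpy()

    cal_ids, _ = selection.split_calibration_validation(
        ids, frac=config.cal_frac, seed=config.split_seed
    )
    in_cal = np.isin(ids, cal_ids)
    return visual_yield_model(
        X[in_cal], counts[in_cal], y[in_cal],
        X[~in_cal], counts[~in_cal], y[~in_cal],
        cv_reps=config.cv_reps, seed=config.cv_seed,
    )
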