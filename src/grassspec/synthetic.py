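"""Synthetic ryegrass scenes and attribute tables for the imaging pipeline.

The study's plant data are not public, so this module provides a forward
model with the statistical and spectral structure the analysis assumes:

* a per-plant attribute table for the 13 wet-chemistry forage attributes,
  drawn so that blade (BL) and pseudostem (PS) values of one plant are
  bivariate-normally coupled with a prescribed mean offset and squared
  correlation, and population summaries match published min/max/mean/SD;
* hyperspectral cubes in which foreground pixels carry

      R(lambda) = baseline_tissue(lambda)
                  * exp(-sum_f amplitude_f * concentration_f * G(lambda; c_f, w_f))
                  * lighting(line)  + noise,

  a Beer-Lambert-style attenuation with Gaussian absorption features G,
  multiplied by a linear lighting ramp along the scan axis; background
  pixels stay below the 0.3 reflectance segmentation cutoff at 1080 nm;
* matching white/dark reference frames, with raw irradiance reconstructed
  as I = R*(W-D)+D so that two-point calibration exactly inverts the
  forward model in the noise-free case.

Baselines emulate green-vegetation spectra: a red edge near 710 nm, an
NIR plateau (higher for pseudostem than blade over 800-1100 nm) and water
absorption dips at 1000, 1200 and 1450 nm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .envi import RawCube, ReferencePair, write_envi

__all__ = [
    "AttributeSpec",
    "EndmemberLibrary",
    "SceneConfig",
    "SimulatedScene",
    "DEFAULT_ATTRIBUTES",
    "default_attribute_specs",
    "default_library",
    "generate_attribute_table",
    "generate_cube",
    "generate_two_zone_cube",
    "simulate_dataset",
]

TISSUES = ("whole", "PS", "BL")


@dataclass(frozen=True)
class AttributeSpec:
    """Population parameters for one forage attribute.

    ``mean``/``sd`` describe the blade-tissue marginal (published pooled
    summaries are dominated by blade samples); the pseudostem marginal is
    shifted by ``ps_bl_shift`` and coupled to the blade value with squared
    correlation ``ps_bl_r2``.  Generated values are clipped to [min, max].
    """

    name: str
    units: str
    mean: float
    sd: float
    min: float
    max: float
    ps_bl_shift: float = 0.0
    ps_bl_r2: float = 0.7

    def __post_init__(self) -> None:
        if not self.min < self.max:
            raise ValueError(f"{self.name}: min must be < max")
        if not self.sd > 0:
            raise ValueError(f"{self.name}: sd must be positive, got {self.sd}")
        if not 0.0 <= self.ps_bl_r2 <= 1.0:
            raise ValueError(f"{self.name}: ps_bl_r2 must lie in [0, 1]")


# Published population summaries (calibration min/max/mean/SD, pooled BL+PS
# dataset) for the 13 attributes; PS-vs-BL offsets and couplings for the four
# attributes with published tissue contrasts (nitrogen, total/HMW/LMW sugars).
DEFAULT_ATTRIBUTES: tuple[AttributeSpec, ...] = (
    AttributeSpec("LMW", "mg/g", 53.9, 20.4, 22.3, 127.4, ps_bl_shift=34.0, ps_bl_r2=0.50),
    AttributeSpec("HMW", "mg/g", 36.2, 35.1, 2.4, 167.5, ps_bl_shift=58.0, ps_bl_r2=0.89),
    AttributeSpec("Sugars", "mg/g", 90.0, 52.2, 26.7, 252.8, ps_bl_shift=93.0, ps_bl_r2=0.84),
    AttributeSpec("VisualYield", "%", 19.9, 3.7, 11.4, 26.5),
    AttributeSpec("NDF", "%", 45.9, 3.2, 38.7, 53.1),
    AttributeSpec("ADF", "%", 25.7, 2.2, 21.1, 30.2),
    AttributeSpec("Nitrogen", "%", 3.2, 0.7, 0.4, 4.65, ps_bl_shift=-1.1, ps_bl_r2=0.83),
    AttributeSpec("DOMD", "% DM", 65.2, 1.8, 60.0, 69.4),
    AttributeSpec("ME", "MJ/kg DM", 10.4, 0.3, 9.6, 11.1),
    AttributeSpec("DM", "%", 94.5, 0.7, 92.9, 96.4),
    AttributeSpec("Ash", "%", 9.8, 1.2, 5.7, 12.6),
    AttributeSpec("Ca", "mg/g", 4.3, 1.1, 1.6, 7.9),
    AttributeSpec("OM", "%", 84.6, 1.5, 80.7, 89.5),
)


def default_attribute_specs() -> list[AttributeSpec]:
    """A fresh copy of the default 13-attribute specification list."""
    return list(DEFAULT_ATTRIBUTES)


@dataclass(frozen=True)
class EndmemberLibrary:
    """Tissue baseline spectra plus Gaussian absorption features.

    ``features`` maps attribute concentration to absorbance: each entry is
    (attribute name, center nm, width nm, amplitude per unit concentration).
    """

    wavelengths: np.ndarray
    baselines: dict  # tissue -> baseline reflectance spectrum
    features: tuple  # of (name, center_nm, width_nm, amplitude)

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        object.__setattr__(self, "wavelengths", wl)
        for name, center, width, amp in self.features:
            if not wl[0] <= center <= wl[-1]:
                raise ValueError(f"feature {name}@{center} nm outside grid")
            if width <= 0 or amp <= 0:
                raise ValueError(f"feature {name}@{center}: width and amplitude must be > 0")
        for tissue, base in self.baselines.items():
            base = np.asarray(base, dtype=float)
            if np.any(base <= 0) or np.any(base > 1.5):
                raise ValueError(f"baseline for {tissue!r} must lie in (0, 1.5]")

    def feature_bands(self, attribute: str) -> list[int]:
        """Band indices of the feature centers configured for ``attribute``."""
        wl = self.wavelengths
        return [
            int(np.argmin(np.abs(wl - center)))
            for name, center, width, amp in self.features
            if name == attribute
        ]


def _gauss(wl: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - center) / width) ** 2)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def default_library(n_bands: int = 235, lo_nm: float = 550.0, hi_nm: float = 1700.0) -> EndmemberLibrary:
    """Endmember library emulating ryegrass blade/pseudostem reflectance.

    Blade: red edge at ~710 nm to an NIR plateau of ~0.7, water dips at
    1000/1200/1450 nm.  Pseudostem: brighter plateau (~1.1 over 800-1100 nm)
    with deeper long-wave water dips.  Background: flat dark soil-like 0.12.

    Absorption features are placed inside the wavelength regions reported as
    informative for nitrogen (around 560, 700, 935, 1380, 1600 nm) and for
    the sugar fractions (around 565, 705, 980, 1340, 1400, 1530, 1590,
    1680 nm); amplitudes are per unit of the attribute's own scale.
    """
    wl = np.linspace(lo_nm, hi_nm, n_bands)

    bl = (
        0.25
        + 0.45 * _sigmoid((wl - 710.0) / 18.0)
        + 0.08 * _gauss(wl, 560.0, 25.0)
        - 0.06 * _gauss(wl, 1000.0, 30.0)
        - 0.14 * _gauss(wl, 1200.0, 45.0)
        - 0.38 * _gauss(wl, 1450.0, 70.0)
    )
    ps = (
        0.35
        + 0.76 * _sigmoid((wl - 700.0) / 20.0)
        + 0.05 * _gauss(wl, 560.0, 25.0)
        - 0.08 * _gauss(wl, 1000.0, 30.0)
        - 0.42 * _gauss(wl, 1200.0, 45.0)
        - 0.72 * _gauss(wl, 1450.0, 70.0)
    )
    background = np.full_like(wl, 0.12) + 0.02 * (wl - lo_nm) / (hi_nm - lo_nm)

    features = (
        # nitrogen, % scale (typical 0.4-4.65)
        ("Nitrogen", 560.0, 15.0, 0.035),
        ("Nitrogen", 700.0, 22.0, 0.028),
        ("Nitrogen", 935.0, 14.0, 0.018),
        ("Nitrogen", 1380.0, 28.0, 0.024),
        ("Nitrogen", 1600.0, 40.0, 0.020),
        # total sugars, mg/g scale (typical 27-253)
        ("Sugars", 565.0, 12.0, 4.0e-4),
        ("Sugars", 705.0, 20.0, 5.0e-4),
        ("Sugars", 1400.0, 25.0, 6.0e-4),
        ("Sugars", 1590.0, 35.0, 5.0e-4),
        ("Sugars", 1680.0, 12.0, 4.0e-4),
        # sugar fractions, mg/g
        ("HMW", 1340.0, 20.0, 4.0e-4),
        ("HMW", 1620.0, 30.0, 3.0e-4),
        ("LMW", 980.0, 18.0, 3.0e-4),
        ("LMW", 1530.0, 25.0, 4.0e-4),
    )
    return EndmemberLibrary(wl, {"BL": bl, "PS": ps, "background": background}, features)


@dataclass(frozen=True)
class SceneConfig:
    """Acquisition geometry and nuisance levels for one simulated image."""

    lines: int = 400
    samples: int = 320
    bands: int = 235
    plant_fraction: float = 0.35
    lighting_gradient: float = 0.2
    noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.lines, self.samples, self.bands) <= 0:
            raise ValueError("all scene dimensions must be positive")
        if not 0.0 < self.plant_fraction < 1.0:
            raise ValueError(
                f"plant_fraction must lie strictly in (0, 1), got {self.plant_fraction}"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class SimulatedScene:
    """One simulated acquisition: raw counts, references and ground truth."""

    raw: RawCube
    refs: ReferencePair
    truth_mask: np.ndarray       # foreground pixels, (line, sample)
    reflectance: np.ndarray      # forward-model reflectance incl. gradient+noise
    zone_labels: np.ndarray | None = None  # per-pixel tissue for two-zone scenes


def _beta_params(mean: float, sd: float, lo: float, hi: float) -> tuple[float, float]:
    """Shape parameters of a Beta on [lo, hi] with the target mean and SD.

    Clipping a normal at published bounds would bias the realized mean and
    SD whenever the bounds sit within ~3 SD of the mean, so marginals are
    moment-matched Betas instead; any (mean, sd) with
    sd^2 < (mean - lo)(hi - mean) is representable exactly.
    """
    if not lo < mean < hi:
        raise ValueError(f"mean {mean} must lie strictly inside [{lo}, {hi}]")
    m = (mean - lo) / (hi - lo)
    v = (sd / (hi - lo)) ** 2
    if v >= m * (1 - m):
        raise ValueError(
            f"sd {sd} too large for a bounded distribution on [{lo}, {hi}] "
            f"with mean {mean}"
        )
    nu = m * (1 - m) / v - 1.0
    return m * nu, (1.0 - m) * nu


def _copula_rho(ab_bl: tuple, ab_ps: tuple, target_rho: float, n_herm: int = 24) -> float:
    """Gaussian-copula correlation giving a target Pearson correlation.

    A Gaussian copula attenuates Pearson correlation when the marginals are
    skewed.  Writing each marginal transform g(z) = F^{-1}(Phi(z)) in the
    probabilists' Hermite basis, corr(rho) = sum_k c1_k c2_k k! rho^k
    (normalized), which is monotone in rho and solved by bisection.
    """
    from numpy.polynomial import hermite_e
    from scipy import optimize, special, stats as sps

    if target_rho <= 0:
        return 0.0
    nodes, weights = hermite_e.hermegauss(96)
    weights = weights / weights.sum()
    u = sps.norm.cdf(nodes)

    def herm_coeffs(alpha, beta):
        g = sps.beta.ppf(u, alpha, beta)
        ks = np.arange(n_herm + 1)
        coeffs = np.empty(n_herm + 1)
        for k in ks:
            he_k = hermite_e.hermeval(nodes, np.eye(n_herm + 1)[k])
            coeffs[k] = float(np.sum(weights * g * he_k)) / special.factorial(k)
        return coeffs

    c1, c2 = herm_coeffs(*ab_bl), herm_coeffs(*ab_ps)
    ks = np.arange(1, n_herm + 1)
    fact = special.factorial(ks)
    var1 = float(np.sum(c1[1:] ** 2 * fact))
    var2 = float(np.sum(c2[1:] ** 2 * fact))
    cross = c1[1:] * c2[1:] * fact

    def corr(rho):
        return float(np.sum(cross * rho**ks)) / np.sqrt(var1 * var2)

    if corr(0.999999) <= target_rho:
        return 0.999999
    return float(optimize.brentq(lambda r: corr(r) - target_rho, 0.0, 0.999999))


def generate_attribute_table(
    specs: list[AttributeSpec],
    n_plants: int,
    seed: int,
    ps_fraction: float = 0.3,
) -> pd.DataFrame:
    """Sample a per-plant attribute table with whole/PS/BL rows.

    Blade and pseudostem values are coupled through a Gaussian copula with
    correlation sqrt(ps_bl_r2); each tissue marginal is a moment-matched
    Beta on [min, max] with mean ``mean`` (BL) or ``mean + ps_bl_shift``
    (PS) and SD ``sd``, so published population summaries are reproduced
    without clipping bias.  The whole-plant value is the tissue-fraction-
    weighted mean (``ps_fraction`` pseudostem).
    """
    from scipy import stats as sps

    if n_plants < 2:
        raise ValueError(f"n_plants must be >= 2, got {n_plants}")
    if not specs:
        raise ValueError("specs must be non-empty")
    rng = np.random.default_rng(seed)
    plant_ids = np.arange(1, n_plants + 1)

    columns: dict[str, dict] = {}
    for spec in specs:
        z_bl = rng.standard_normal(n_plants)
        z_extra = rng.standard_normal(n_plants)
        span = spec.max - spec.min
        degenerate = spec.sd < 1e-6 * span
        rho = float(np.sqrt(spec.ps_bl_r2))
        if not degenerate:
            ab_bl = _beta_params(spec.mean, spec.sd, spec.min, spec.max)
            ab_ps = _beta_params(
                spec.mean + spec.ps_bl_shift, spec.sd, spec.min, spec.max
            )
            if 0 < rho < 1:
                rho = _copula_rho(ab_bl, ab_ps, rho)
        z_ps = rho * z_bl + np.sqrt(max(0.0, 1.0 - rho**2)) * z_extra

        tissue_vals = {}
        for tissue, z, target_mean in (
            ("BL", z_bl, spec.mean),
            ("PS", z_ps, spec.mean + spec.ps_bl_shift),
        ):
            if degenerate:
                # degenerate spread: essentially constant at the mean
                vals = target_mean + spec.sd * z
            else:
                alpha, beta = ab_bl if tissue == "BL" else ab_ps
                vals = spec.min + span * sps.beta.ppf(sps.norm.cdf(z), alpha, beta)
            tissue_vals[tissue] = np.clip(vals, spec.min, spec.max)
        whole = ps_fraction * tissue_vals["PS"] + (1.0 - ps_fraction) * tissue_vals["BL"]
        columns[spec.name] = {"whole": whole, **tissue_vals}

    frames = []
    for tissue in TISSUES:
        frame = pd.DataFrame({"plant_id": plant_ids, "tissue": tissue})
        for spec in specs:
            frame[spec.name] = columns[spec.name][tissue]
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def _foreground_mask(scene: SceneConfig) -> np.ndarray:
    """Deterministic plant-shaped blob covering ~plant_fraction of pixels.

    An ellipse whose radius is modulated by low-order sinusoidal lobes (seeded)
    so the shape is organic but exactly reproducible.
    """
    rng = np.random.default_rng(scene.seed + 17)
    ly, lx = scene.lines, scene.samples
    yy, xx = np.mgrid[0:ly, 0:lx]
    cy, cx = (ly - 1) / 2.0, (lx - 1) / 2.0
    u = (yy - cy) / (ly / 2.0)
    v = (xx - cx) / (lx / 2.0)
    r = np.sqrt(u**2 + v**2)
    theta = np.arctan2(u, v)
    lobes = 1.0 + 0.12 * np.sin(3 * theta + rng.uniform(0, 2 * np.pi)) + 0.08 * np.sin(
        5 * theta + rng.uniform(0, 2 * np.pi)
    )
    # scale the base radius so the covered fraction hits the target
    score = r / lobes
    cutoff = np.quantile(score, scene.plant_fraction)
    return score <= cutoff


def _tissue_reflectance(
    attr_values: dict,
    library: EndmemberLibrary,
    tissue: str,
) -> np.ndarray:
    """Noise-free, gradient-free reflectance spectrum for one tissue."""
    wl = library.wavelengths
    absorbance = np.zeros_like(wl)
    for name, center, width, amp in library.features:
        if name in attr_values:
            conc = float(attr_values[name])
            absorbance += amp * conc * _gauss(wl, center, width)
    return library.baselines[tissue] * np.exp(-absorbance)


def _assemble_scene(
    scene: SceneConfig,
    library: EndmemberLibrary,
    foreground_spectrum_for: callable,
    zone_labels: np.ndarray | None,
) -> SimulatedScene:
    wl = library.wavelengths
    if len(wl) != scene.bands:
        raise ValueError(
            f"library has {len(wl)} bands but scene requests {scene.bands}"
        )
    rng = np.random.default_rng(scene.seed)
    mask = _foreground_mask(scene)

    refl = np.empty((scene.lines, scene.samples, scene.bands))
    refl[:] = library.baselines["background"]
    for label in (np.unique(zone_labels[mask]) if zone_labels is not None else ["fg"]):
        spectrum = foreground_spectrum_for(label)
        where = mask if zone_labels is None else (mask & (zone_labels == label))
        refl[where] = spectrum

    if scene.lighting_gradient != 0.0:
        ramp = 1.0 + scene.lighting_gradient * (
            np.arange(scene.lines) / max(scene.lines - 1, 1) - 0.5
        )
        refl *= ramp[:, None, None]
    if scene.noise_sd > 0:
        refl += rng.normal(0.0, scene.noise_sd, size=refl.shape)

    # references: flat white tile (0.99-reflectance equivalent counts) and a
    # small positive dark offset; I = R*(W-D)+D makes calibration exact.
    full_scale = 4096.0
    white = np.full((scene.samples, scene.bands), 0.99 * full_scale)
    dark = np.full((scene.samples, scene.bands), 0.03 * full_scale)
    dark += rng.normal(0.0, 0.5, size=dark.shape)
    irradiance = refl * (white - dark)[None] + dark[None]
    raw = RawCube(irradiance, wl, meta={"seed": scene.seed})
    return SimulatedScene(raw, ReferencePair(white, dark), mask, refl, zone_labels)


def generate_cube(
    attr_values: dict,
    library: EndmemberLibrary,
    scene: SceneConfig,
    tissue: str = "BL",
) -> SimulatedScene:
    """Simulate one single-tissue acquisition of a plant.

    ``attr_values`` maps attribute names to this plant's concentrations
    (attribute names absent from the library's feature list simply do not
    modulate the spectrum).
    """
    if tissue not in library.baselines or tissue == "background":
        raise ValueError(f"unknown tissue {tissue!r}")
    spectrum = _tissue_reflectance(attr_values, library, tissue)
    return _assemble_scene(scene, library, lambda _label: spectrum, None)


def generate_two_zone_cube(
    bl_values: dict,
    ps_values: dict,
    library: EndmemberLibrary,
    scene: SceneConfig,
) -> SimulatedScene:
    """Simulate a whole plant: blade tissue in the top half of the image,
    pseudostem in the bottom half (a side-view sward geometry)."""
    labels = np.empty((scene.lines, scene.samples), dtype="U2")
    labels[: scene.lines // 2, :] = "BL"
    labels[scene.lines // 2 :, :] = "PS"
    spectra = {
        "BL": _tissue_reflectance(bl_values, library, "BL"),
        "PS": _tissue_reflectance(ps_values, library, "PS"),
    }
    return _assemble_scene(scene, library, lambda label: spectra[str(label)], labels)


def simulate_dataset(
    out_dir: str | Path,
    n_plants: int,
    seed: int,
    scene: SceneConfig | None = None,
    specs: list[AttributeSpec] | None = None,
    library: EndmemberLibrary | None = None,
    n_images: int = 2,
) -> Path:
    """Write a simulated study to disk: attribute CSV plus ENVI cubes.

    Each plant gets ``n_images`` replicate blade acquisitions (seeded
    independently); white/dark references are stored as single-line ENVI
    images next to each cube.  Returns the output directory.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    specs = specs if specs is not None else default_attribute_specs()
    scene = scene if scene is not None else SceneConfig()
    library = library if library is not None else default_library(scene.bands)

    table = generate_attribute_table(specs, n_plants, seed)
    table.to_csv(out / "attributes.csv", index=False)
    names = [s.name for s in specs]
    bl_rows = table[table.tissue == "BL"].set_index("plant_id")

    for plant_id in range(1, n_plants + 1):
        values = bl_rows.loc[plant_id, names].to_dict()
        for rep in range(n_images):
            rep_scene = replace(scene, seed=seed + 1000 * plant_id + rep)
            sim = generate_cube(values, library, rep_scene)
            stem = out / f"plant{plant_id:03d}_rep{rep + 1}"
            write_envi(stem.with_suffix(".hdr"), sim.raw.irradiance,
                       library.wavelengths, dtype="float32")
            write_envi(stem.with_name(stem.name + "_white.hdr"),
                       sim.refs.white[None], library.wavelengths, dtype="float32")
            write_envi(stem.with_name(stem.name + "_dark.hdr"),
                       sim.refs.dark[None], library.wavelengths, dtype="float32")
    return out
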