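"""Synthetic hyperspectral seed-plate generator.

Emulates a push-broom VNIR acquisition of germination plates: 8 plates
of 25 seeds each (200 seeds), 520 bands spanning roughly 391-1042 nm.
Each seed's reflectance carries vitality-linked Gaussian absorption
features on a smooth baseline, multiplicative scatter and additive
offset per seed, pixel-level Gaussian noise, and an intra-seed spatial
texture whose contrast tracks a latent that is (configurably) coupled
to vitality.  Vitality is seedling height in cm.

The generative model per seed i at wavelength lambda:

    r_i(lambda) = B(lambda) * (1 - sum_k alpha_k(g_i) * exp(-(lambda - mu_k)^2 / (2 sigma_k^2)))

with alpha_k affine in the seed's spectral driver g_i; the observed
mean spectrum is a_i * r_i + b_i + noise.  In ``fusion_sensitive`` mode
vitality mixes the spectral latent with the texture latent, so image
texture carries information the spectra alone lack.

Raw captures are synthesized so that the two-point reflectance
correction (O - Y)/(X - Y) recovers the planted reflectance exactly in
the noise-free limit.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.special import expit

from .calibration import RawCapture
from .envi import write_envi, read_envi


class ConfigError(ValueError):
    """Invalid simulation configuration."""


def _default_absorption_bands() -> list[tuple[float, float, float]]:
    # (center nm, width sigma nm, alpha slope per cm of vitality)
    # One feature fixed at 711 nm (red edge); the others sit in the
    # visible and the NIR water-absorption region.
    return [(550.0, 6.0, 0.014), (711.0, 6.0, 0.018), (970.0, 7.0, 0.012)]


@dataclass
class SimConfig:
    """Configuration of the synthetic plate study.

    Defaults reproduce the study layout: 8 plates x 25 seeds on a 5x5
    grid, 520 bands from 391 nm at a 1.254 nm step (last band ~1042 nm),
    vitality ~ N(10, 2^2) cm truncated positive.
    """

    n_plates: int = 8
    seeds_per_plate: int = 25
    n_bands: int = 520
    wavelength_start_nm: float = 391.0
    wavelength_step_nm: float = 1.254
    vitality_mean_cm: float = 10.0
    vitality_sd_cm: float = 2.0
    absorption_bands: list = field(default_factory=_default_absorption_bands)
    alpha_base: float = 0.22
    scatter_sd: float = 0.05
    offset_sd: float = 0.01
    noise_sd: float = 0.004
    texture_coupling: float = 0.6
    texture_base_amp: float = 0.06
    texture_gain: float = 1.0
    fusion_sensitive: bool = False
    # fusion-mode mixing weights (spectral, texture, noise); unit norm
    fusion_weights: tuple = (0.70, 0.65, 0.296)
    # plate geometry (pixels)
    cell_px: int = 22
    margin_px: int = 4
    seed_rx: float = 6.5
    seed_ry: float = 4.5
    background_reflectance: float = 0.06
    rng_seed: int = 42

    def validate(self) -> None:
        if self.n_plates <= 0 or self.seeds_per_plate <= 0 or self.n_bands <= 1:
            raise ConfigError("non-positive dimensions")
        if self.wavelength_step_nm <= 0:
            raise ConfigError("degenerate wavelength axis")
        if self.vitality_sd_cm <= 0 or self.vitality_mean_cm <= 0:
            raise ConfigError("vitality distribution must have positive mean and sd")
        if not 0.0 <= self.texture_coupling <= 1.0:
            raise ConfigError("texture_coupling must lie in [0, 1]")
        for mu, sig, _ in self.absorption_bands:
            if sig <= 0:
                raise ConfigError(f"absorption width must be positive (center {mu})")

    @property
    def n_seeds(self) -> int:
        return self.n_plates * self.seeds_per_plate

    @property
    def wavelengths(self) -> np.ndarray:
        return self.wavelength_start_nm + self.wavelength_step_nm * np.arange(self.n_bands)

    @property
    def grid_shape(self) -> tuple[int, int]:
        rows = int(math.ceil(math.sqrt(self.seeds_per_plate)))
        cols = int(math.ceil(self.seeds_per_plate / rows))
        return rows, cols

    @property
    def plate_shape(self) -> tuple[int, int]:
        rows, cols = self.grid_shape
        return (rows * self.cell_px + 2 * self.margin_px,
                cols * self.cell_px + 2 * self.margin_px)


@dataclass
class GroundTruth:
    """What the generator planted: the oracle for every downstream stage."""

    vitality: np.ndarray                  # (n_seeds,) cm
    masks: list                           # per plate, integer label image
    informative_band_indices: np.ndarray  # band index of each absorption center
    texture_latent: np.ndarray            # (n_seeds,) dimensionless
    spectral_latent: np.ndarray           # (n_seeds,) dimensionless
    clean_spectra: np.ndarray             # (n_seeds, n_bands) planted r_i(lambda)


@dataclass
class SimulatedDataset:
    config: SimConfig
    raw: list                             # RawCapture per plate
    truth: GroundTruth
    vitality_table: pd.DataFrame          # seed_id, plate, row, col, vitality_cm

    @property
    def wavelengths(self) -> np.ndarray:
        return self.config.wavelengths


def _baseline(wl: np.ndarray) -> np.ndarray:
    """Smooth seed-coat reflectance continuum, brighter in the NIR."""
    return 0.45 + 0.18 * np.tanh((wl - 730.0) / 120.0)


def planted_reflectance(config: SimConfig, driver_cm: np.ndarray) -> np.ndarray:
    """The analytic noise-free reflectance r_i(lambda) for each seed.

    ``driver_cm`` is the spectral driver in cm units (equal to vitality
    in the default mode).
    """
    wl = config.wavelengths
    B = _baseline(wl)
    depth = np.zeros((driver_cm.size, wl.size))
    for mu, sig, slope in config.absorption_bands:
        alpha = config.alpha_base + slope * (driver_cm - config.vitality_mean_cm)
        alpha = np.clip(alpha, 0.02, 0.60)
        depth += alpha[:, None] * np.exp(-((wl - mu) ** 2) / (2.0 * sig ** 2))[None, :]
    return B[None, :] * (1.0 - depth)


def _seed_latents(config: SimConfig, rng: np.random.Generator):
    """Draw (vitality, spectral driver, texture latent) for all seeds."""
    n = config.n_seeds
    s = rng.standard_normal(n)   # spectral latent
    u = rng.standard_normal(n)   # independent texture component
    e = rng.standard_normal(n)   # residual vitality noise (fusion mode)
    if config.fusion_sensitive:
        t = u
        ws, wt, wn = config.fusion_weights
        v = config.vitality_mean_cm + config.vitality_sd_cm * (ws * s + wt * t + wn * e)
        driver = config.vitality_mean_cm + config.vitality_sd_cm * s
    else:
        rho = config.texture_coupling
        t = rho * s + math.sqrt(1.0 - rho * rho) * u
        v = config.vitality_mean_cm + config.vitality_sd_cm * s
        driver = v
    v = np.clip(v, 0.1, None)  # heights are positive
    return v, driver, t


def _plate_layout(config: SimConfig, rng: np.random.Generator):
    """Label mask and per-seed pixel coordinates for one plate."""
    rows, cols = config.grid_shape
    lines, samples = config.plate_shape
    mask = np.zeros((lines, samples), dtype=np.uint8)
    yy, xx = np.mgrid[0:lines, 0:samples]
    label = 0
    for r in range(rows):
        for c in range(cols):
            if label >= config.seeds_per_plate:
                break
            label += 1
            cy = config.margin_px + r * config.cell_px + config.cell_px / 2.0
            cx = config.margin_px + c * config.cell_px + config.cell_px / 2.0
            cy += rng.uniform(-1.5, 1.5)
            cx += rng.uniform(-1.5, 1.5)
            ry = config.seed_ry * rng.uniform(0.9, 1.1)
            rx = config.seed_rx * rng.uniform(0.9, 1.1)
            theta = rng.uniform(-0.3, 0.3)
            ct, st = math.cos(theta), math.sin(theta)
            dx, dy = xx - cx, yy - cy
            inside = ((dx * ct + dy * st) / rx) ** 2 + ((-dx * st + dy * ct) / ry) ** 2 <= 1.0
            mask[inside & (mask == 0)] = label
    return mask


def _texture_field(mask_sel: np.ndarray, rng: np.random.Generator,
                   roughness: float) -> np.ndarray:
    """Zero-mean, unit-sd noise field over one seed's pixels.

    ``roughness`` in (0, 1) mixes a smoothed (coarse) noise field with
    pixel-scale (fine) noise.  GLCM features computed after range-
    spanning quantization are invariant to the field's amplitude, so the
    vitality-linked texture signal is carried by spatial frequency
    content: rougher coats -> higher contrast and entropy.
    """
    bbox = ndimage.find_objects(mask_sel.astype(int))[0]
    shape = [s.stop - s.start for s in bbox]
    sub = mask_sel[bbox]
    coarse = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=1.2)[sub]
    fine = rng.standard_normal(shape)[sub]
    # orthonormalize over the mask so the coarse/fine mix is exact per seed
    coarse = coarse - coarse.mean()
    coarse /= max(coarse.std(), 1e-12)
    fine = fine - fine.mean()
    fine -= (fine @ coarse) / max(coarse @ coarse, 1e-12) * coarse
    fine /= max(fine.std(), 1e-12)
    vals = (1.0 - roughness) * coarse + roughness * fine
    sd = vals.std()
    return vals / sd if sd > 0 else vals


def simulate_dataset(config: SimConfig | None = None) -> SimulatedDataset:
    """Generate raw captures, ground truth, and the vitality table."""
    config = config or SimConfig()
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    wl = config.wavelengths
    n_bands = config.n_bands

    vitality, driver, tex_latent = _seed_latents(config, rng)
    clean = planted_reflectance(config, driver)

    # per-seed scatter/offset of the observed spectra
    a = 1.0 + config.scatter_sd * rng.standard_normal(config.n_seeds)
    b = config.offset_sd * rng.standard_normal(config.n_seeds)
    # texture roughness, monotone in the latent and bounded away from 0/1
    roughness = 0.15 + 0.7 * expit(config.texture_gain * tex_latent)

    # session reference frames: constant along the scan axis
    white_dn = 3000.0 + 600.0 * np.exp(-((wl - 650.0) / 260.0) ** 2)  # lamp profile
    dark_dn = np.full(n_bands, 60.0)

    rows, cols = config.grid_shape
    lines, samples = config.plate_shape
    informative = np.array([int(np.argmin(np.abs(wl - mu)))
                            for mu, _, _ in config.absorption_bands])

    raw_captures: list[RawCapture] = []
    masks: list[np.ndarray] = []
    table_rows = []
    seed_id = 0
    for p in range(config.n_plates):
        mask = _plate_layout(config, rng)
        masks.append(mask)
        S = np.empty((lines, samples, n_bands), dtype=np.float64)
        bg = config.background_reflectance * (1.0 + 0.1 * np.tanh((wl - 700) / 200.0))
        S[:] = bg[None, None, :]
        for k in range(1, config.seeds_per_plate + 1):
            sel = mask == k
            spectrum = a[seed_id] * clean[seed_id] + b[seed_id]
            # band noise shared across the seed's pixels: survives ROI
            # averaging, so the observed mean spectrum is a*r + b + eps
            if config.noise_sd > 0:
                spectrum = spectrum + config.noise_sd * rng.standard_normal(n_bands)
            tex = _texture_field(sel, rng, roughness[seed_id])
            S[sel] = (1.0 + config.texture_base_amp * tex)[:, None] * spectrum[None, :]
            gr, gc = divmod(k - 1, cols)
            table_rows.append((seed_id, p, gr, gc, vitality[seed_id]))
            seed_id += 1
        if config.noise_sd > 0:  # per-pixel shot noise on top
            S += config.noise_sd * rng.standard_normal(S.shape)
        X = np.broadcast_to(white_dn.astype(np.float32), (lines, samples, n_bands))
        Y = np.broadcast_to(dark_dn.astype(np.float32), (lines, samples, n_bands))
        O = (Y + S * (X.astype(np.float64) - Y)).astype(np.float32)
        raw_captures.append(RawCapture(O=O, X=X, Y=Y, wavelengths=wl))

    truth = GroundTruth(vitality=vitality, masks=masks,
                        informative_band_indices=informative,
                        texture_latent=tex_latent, spectral_latent=driver,
                        clean_spectra=clean)
    table = pd.DataFrame(table_rows,
                         columns=["seed_id", "plate", "row", "col", "vitality_cm"])
    return SimulatedDataset(config=config, raw=raw_captures, truth=truth,
                            vitality_table=table)


def write_fixture(dataset: SimulatedDataset, out_dir: str | Path) -> dict:
    """Persist a dataset as ENVI raw/hdr pairs, label masks, and a CSV.

    Writes one raw/header pair per plate, one shared white/dark
    reference pair, one 8-bit label mask per plate, and the vitality
    table.  Returns a manifest mapping each file name to its SHA-256.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    wl = dataset.wavelengths
    files = []
    for p, raw in enumerate(dataset.raw):
        raw_path = out_dir / f"plate{p:02d}.raw"
        hdr = write_envi(raw_path, raw.O, wavelengths=wl, interleave="bil")
        files += [raw_path, hdr]
        mask_path = out_dir / f"plate{p:02d}_mask.png"
        iio.imwrite(mask_path, dataset.truth.masks[p].astype(np.uint8))
        files.append(mask_path)
    ref = dataset.raw[0]
    files += [out_dir / "white.raw", write_envi(out_dir / "white.raw", np.asarray(ref.X), wl)]
    files += [out_dir / "dark.raw", write_envi(out_dir / "dark.raw", np.asarray(ref.Y), wl)]
    csv_path = out_dir / "vitality.csv"
    dataset.vitality_table.to_csv(csv_path, index=False, float_format="%.6f")
    files.append(csv_path)

    manifest = {}
    for f in sorted(set(files)):
        manifest[f.name] = hashlib.sha256(f.read_bytes()).hexdigest()
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(
        {"config": asdict(dataset.config), "files": manifest}, indent=2, default=list))
    return manifest


def read_fixture(out_dir: str | Path):
    """Re-read a written fixture: (RawCapture list, mask list, vitality table)."""
    out_dir = Path(out_dir)
    white, wl = read_envi(out_dir / "white.raw")
    dark, _ = read_envi(out_dir / "dark.raw")
    captures, masks = [], []
    for raw_path in sorted(out_dir.glob("plate*.raw")):
        O, wl_p = read_envi(raw_path)
        captures.append(RawCapture(O=O, X=white, Y=dark, wavelengths=wl_p))
        masks.append(iio.imread(out_dir / f"{raw_path.stem}_mask.png"))
    table = pd.read_csv(out_dir / "vitality.csv")
    return captures, masks, table
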