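"""End-to-end orchestration of the analysis grid.

One run goes: simulate (or accept) a plate dataset -> calibrate ->
extract per-seed spectra -> one shared SPXY split -> for every
pretreatment x selector combination select wavelengths on the training
fold -> extract GLCM texture at the selected bands -> build spectral /
texture / fused feature blocks -> fit and evaluate every model -> one
report row per grid cell, mirroring the field's standard results-table
schema (Model, Pre-Processing, VN, R_C, RMSE_C, R_P, RMSE_P).

The split is computed once on the raw spectra and shared by every cell
so that pretreatments, selectors and models are compared on identical
folds; nothing downstream of the split ever sees a test-fold target
before evaluation.
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calibration import PlateCube, correct_reflectance, extract_seed_spectra
from .models import ModelSpec, evaluate, make_model
from .partition import SplitIndices, spxy_split
from .preprocess import Preprocessor
from .selection import SelectionResult, cars_select, spa_select
from .simulate import SimConfig, SimulatedDataset, simulate_dataset
from .texture import seed_texture_matrix

logger = logging.getLogger(__name__)


def derive_seed(base: int, *names: str) -> int:
    """Deterministic per-stage sub-seed, kept below 2**31."""
    h = zlib.crc32("/".join(names).encode())
    return int((base * 1_000_003 + h) % (2 ** 31))


@dataclass
class RunConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    preprocess: tuple = ("SG", "SNV", "MSC")
    selectors: tuple = ("SPA", "CARS")
    models: tuple = ("PLSR", "SVR", "CNN")
    modes: tuple = ("spectral", "texture", "fused")
    train_fraction: float = 0.7
    spa_max_vars: int = 30
    spa_val_fraction: float = 0.8     # train-within-train fraction for SPA sizing
    cars_n_mc: int = 100
    cars_cv_folds: int = 5
    n_pls_components: int = 3
    glcm_levels: int = 16
    glcm_distance: int = 1
    glcm_angle: int = 0
    rng_seed: int = 42

    def validate(self) -> None:
        for name, grid, allowed in [("preprocess", self.preprocess, {"SG", "SNV", "MSC"}),
                                    ("selectors", self.selectors, {"SPA", "CARS"}),
                                    ("models", self.models, {"PLSR", "SVR", "CNN"}),
                                    ("modes", self.modes, {"spectral", "texture", "fused"})]:
            if not grid:
                raise ValueError(f"empty {name} grid")
            unknown = set(grid) - allowed
            if unknown:
                raise ValueError(f"unknown {name} entries {unknown}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = SimConfig(**raw.pop("sim", {}))
        cfg = cls(sim=sim, **{k: tuple(v) if isinstance(v, list) else v
                              for k, v in raw.items()})
        cfg.validate()
        return cfg


@dataclass
class PlateDataset:
    """Calibrated, analysis-ready view of a plate study."""

    spectra: np.ndarray          # (n_seeds, n_bands) raw reflectance means
    vitality: np.ndarray         # (n_seeds,) cm
    cubes: list                  # PlateCube per plate
    masks: list                  # label image per plate
    wavelengths: np.ndarray
    table: pd.DataFrame | None = None


def build_dataset(sim: SimulatedDataset) -> PlateDataset:
    """Calibrate every raw plate and pull per-seed mean spectra."""
    cubes, spectra = [], []
    for raw, mask in zip(sim.raw, sim.truth.masks):
        cube = correct_reflectance(raw)
        cubes.append(cube)
        spectra.append(extract_seed_spectra(cube, mask))
    return PlateDataset(spectra=np.vstack(spectra),
                        vitality=sim.truth.vitality.copy(),
                        cubes=cubes, masks=list(sim.truth.masks),
                        wavelengths=sim.wavelengths.copy(),
                        table=sim.vitality_table)


def fuse_features(spectral_block: np.ndarray, texture_block: np.ndarray) -> np.ndarray:
    """Concatenate the selected-wavelength block with its texture block.

    Requires the same seed order in both blocks and exactly 4 texture
    columns per spectral column (contrast, correlation, energy,
    entropy per band), giving a fused width of 5x the spectral width.
    """
    spectral_block = np.atleast_2d(np.asarray(spectral_block, float))
    texture_block = np.atleast_2d(np.asarray(texture_block, float))
    if spectral_block.shape[1] == 0 or texture_block.shape[1] == 0:
        raise ValueError("empty feature block")
    if spectral_block.shape[0] != texture_block.shape[0]:
        raise ValueError("seed count mismatch between blocks")
    if texture_block.shape[1] != 4 * spectral_block.shape[1]:
        raise ValueError(
            f"band-set mismatch: texture width {texture_block.shape[1]} != "
            f"4 x spectral width {spectral_block.shape[1]}")
    return np.hstack([spectral_block, texture_block])


def select_wavelengths(X_train: np.ndarray, y_train: np.ndarray, selector: str,
                       config: RunConfig, cell_seed: int) -> SelectionResult:
    """Run one selector on the (preprocessed) training fold."""
    if selector == "SPA":
        inner = spxy_split(X_train, y_train, config.spa_val_fraction)
        return spa_select(X_train[inner.train_ids], y_train[inner.train_ids],
                          X_train[inner.test_ids], y_train[inner.test_ids],
                          max_vars=config.spa_max_vars)
    return cars_select(X_train, y_train, n_mc=config.cars_n_mc,
                       cv_folds=config.cars_cv_folds,
                       n_pls_components=config.n_pls_components,
                       rng_seed=cell_seed)


def texture_matrix_for_bands(data: PlateDataset, band_indices,
                             config: RunConfig) -> np.ndarray:
    """Stack per-plate texture matrices in global seed order."""
    blocks = [seed_texture_matrix(cube, mask, band_indices,
                                  levels=config.glcm_levels,
                                  distance=config.glcm_distance,
                                  angle=config.glcm_angle)
              for cube, mask in zip(data.cubes, data.masks)]
    return np.vstack(blocks)


def run(config: RunConfig, dataset: PlateDataset | None = None,
        split: SplitIndices | None = None) -> pd.DataFrame:
    """Execute the full grid; returns one report row per cell.

    ``dataset`` and ``split`` may be injected (e.g. to reuse a simulated
    study across runs); by default the study is simulated from
    ``config.sim`` and split once with SPXY on the raw spectra.
    """
    config.validate()
    t0 = time.time()
    if dataset is None:
        dataset = build_dataset(simulate_dataset(config.sim))
    y = dataset.vitality
    if split is None:
        split = spxy_split(dataset.spectra, y, config.train_fraction)
    tr, te = split.train_ids, split.test_ids
    logger.info("split: %d train / %d test", tr.size, te.size)

    rows = []
    texture_cache: dict[tuple, np.ndarray] = {}
    selections: dict[tuple, SelectionResult] = {}
    predictions: dict[tuple, tuple] = {}
    for prep_name in config.preprocess:
        prep = Preprocessor(prep_name).fit(dataset.spectra[tr])
        Xp = np.empty_like(dataset.spectra)
        Xp[tr] = prep.transform(dataset.spectra[tr])
        Xp[te] = prep.transform(dataset.spectra[te])
        for sel_name in config.selectors:
            cell_seed = derive_seed(config.rng_seed, prep_name, sel_name)
            sel = select_wavelengths(Xp[tr], y[tr], sel_name, config, cell_seed)
            selections[(prep_name, sel_name)] = sel
            idx = sel.indices
            logger.info("%s+%s selected %d bands", prep_name, sel_name, idx.size)
            key = tuple(idx.tolist())
            needs_texture = {"texture", "fused"} & set(config.modes)
            if needs_texture and key not in texture_cache:
                texture_cache[key] = texture_matrix_for_bands(dataset, idx, config)
            spectral_block = Xp[:, idx]
            for mode in config.modes:
                if mode == "spectral":
                    F = spectral_block
                elif mode == "texture":
                    F = texture_cache[key]
                else:
                    F = fuse_features(spectral_block, texture_cache[key])
                for model_name in config.models:
                    row = {"Model": model_name, "Pre-Processing": f"{prep_name} + {sel_name}",
                           "Mode": mode, "VN": F.shape[1]}
                    try:
                        spec = ModelSpec(
                            kind=model_name,
                            plsr_components=min(config.n_pls_components, F.shape[1]),
                            rng_seed=derive_seed(config.rng_seed, prep_name,
                                                 sel_name, mode, model_name))
                        model = make_model(spec).fit(F[tr], y[tr])
                        r_c, rmse_c = evaluate(model, F[tr], y[tr])
                        r_p, rmse_p = evaluate(model, F[te], y[te])
                        row.update(R_C=r_c, RMSE_C=rmse_c, R_P=r_p, RMSE_P=rmse_p)
                        predictions[(prep_name, sel_name, mode, model_name)] = (
                            model.predict(F[tr]), model.predict(F[te]))
                        if hasattr(model, "loss_curve_"):
                            row["loss_final"] = model.loss_curve_[-1]
                    except Exception as exc:  # cell failure: log, keep the grid
                        logger.exception("cell %s failed", row)
                        row.update(R_C=np.nan, RMSE_C=np.nan, R_P=np.nan,
                                   RMSE_P=np.nan, error=str(exc))
                    rows.append(row)
    report = pd.DataFrame(rows)
    report.attrs["selections"] = selections
    report.attrs["predictions"] = predictions
    report.attrs["split"] = split
    report.attrs["elapsed_s"] = time.time() - t0
    logger.info("grid of %d cells in %.1f s", len(rows), report.attrs["elapsed_s"])
    return report


def write_report(report: pd.DataFrame, out_dir: str | Path) -> Path:
    """Persist the grid report as CSV + JSON; returns the CSV path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / "report.csv"
    cols = [c for c in ["Model", "Pre-Processing", "Mode", "VN",
                        "R_C", "RMSE_C", "R_P", "RMSE_P", "error"]
            if c in report.columns]
    report[cols].to_csv(csv_path, index=False, float_format="%.4f")
    (out_dir / "report.json").write_text(
        json.dumps(report[cols].to_dict(orient="records"), indent=2))
    for (prep, sel), res in report.attrs.get("selections", {}).items():
        diag = out_dir / f"selection_{prep}_{sel}.csv"
        if res.method == "SPA":
            pd.DataFrame({"n_vars": np.arange(1, res.rmse_path.size + 1),
                          "rmse": res.rmse_path}).to_csv(diag, index=False)
        else:
            pd.DataFrame({"iteration": np.arange(1, res.rmsecv_path.size + 1),
                          "rmsecv": res.rmsecv_path,
                          "retained": res.retained_path}).to_csv(diag, index=False)
    return csv_path
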