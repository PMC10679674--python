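#!/usr/bin/env python
"""Segment each plate and score it, then extract GLCM texture features.

Runs the Otsu + connected-components segmenter on one NIR band image
per plate, scores it against the ground-truth masks with pixel
accuracy and mean IoU, and extracts the four texture features per seed
at the generator's planted absorption centers.  Scores go to
results/segmentation_scores.csv, the texture table to
results/texture_features.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from cottonvit import (RunConfig, SimConfig, build_dataset, extract_band_image,
                       mean_iou, pixel_accuracy, segment_plate,
                       seed_texture_matrix, simulate_dataset,
                       texture_column_names)

ROOT = Path(__file__).resolve().parents[1]
BAND = 400  # NIR band with strong seed/background contrast


def main() -> None:
    cfg = RunConfig()
    sim = simulate_dataset(SimConfig(rng_seed=42))
    data = build_dataset(sim)
    results = ROOT / "results"
    results.mkdir(exist_ok=True)

    rows = []
    for p, (cube, truth) in enumerate(zip(data.cubes, sim.truth.masks)):
        seg = segment_plate(extract_band_image(cube, BAND))
        rows.append({"plate": p, "regions": int(seg.max()),
                     "pixel_accuracy_pct": pixel_accuracy(seg, truth),
                     "mean_iou_pct": mean_iou(seg, truth)})
    scores = pd.DataFrame(rows)
    scores.to_csv(results / "segmentation_scores.csv", index=False,
                  float_format="%.2f")
    print(scores.to_string(index=False))

    bands = sim.truth.informative_band_indices
    blocks = [seed_texture_matrix(cube, mask, bands,
                                  levels=cfg.glcm_levels)
              for cube, mask in zip(data.cubes, sim.truth.masks)]
    T = np.vstack(blocks)
    cols = texture_column_names(data.wavelengths, bands)
    table = pd.DataFrame(T, columns=cols)
    table.insert(0, "seed_id", np.arange(len(T)))
    table.to_csv(results / "texture_features.csv", index=False,
                 float_format="%.5f")
    rho = spearmanr(T[:, 0::4].mean(axis=1), sim.truth.texture_latent).statistic
    print(f"\n{T.shape[1]} texture features per seed at "
          f"{len(bands)} bands; mean contrast vs planted texture latent: "
          f"Spearman rho = {rho:.3f}")


if __name__ == "__main__":
    main()
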