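"""Compare eleven regression methods for nitrogen on one synthetic study.

Reproduces the shape of a method-comparison table: four PLSR variants
(Adjusted Wold thresholds 1.0/0.99, CARS and VIP wavelength selection)
against seven generic learners, all scored on the same plant-level split.
"""

import numpy as np

import grassspec as gs
from grassspec import selection
from grassspec.preprocess import snv

config = gs.StudyConfig(
    n_plants=120, attributes=("Nitrogen",),
    scene=gs.SceneConfig(lines=48, samples=40, plant_fraction=0.45),
    cv_reps=5, sim_seed=11, split_seed=12, cv_seed=13,
)
result = gs.run_study(config)

sp = result.spectra
band_cols = [c for c in sp.columns if c[0].isdigit()]
X = snv(sp[band_cols].to_numpy())
ids = sp.plant_id.to_numpy()
truth = result.table[result.table.tissue == "BL"].set_index("plant_id")
y = truth.loc[ids, "Nitrogen"].to_numpy()
in_cal = np.isin(ids, result.cal_ids)

frame = selection.run_all_methods(
    X[in_cal], y[in_cal], X[~in_cal], y[~in_cal],
    seed=13, attribute="Nitrogen", cv_reps=5, lv_max=15, cars_runs=30,
)
print(f"{'method':12s} {'R2 cal':>7s} {'RMSE cal':>9s} {'R2 val':>7s} {'RMSE val':>9s}")
for _, row in frame.iterrows():
    print(f"{row.method:12s} {row.r2_cal:7.3f} {row.rmse_cal:9.3f} "
          f"{row.r2_val:7.3f} {row.rmse_val:9.3f}")
print("PLSR variants handle the 235-band multicollinearity natively; the "
      "MLR family runs on an every-5th-band basis to stay well-posed.")
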