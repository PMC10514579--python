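"""Hybrid wavelength selection: SPA, CARS, and their union.

SPA grows minimally-collinear band chains and sizes them by validation
RMSE; CARS runs 50 Monte Carlo PLS fits under an exponentially
decreasing retention schedule and keeps the subset with minimal
5-fold RMSECV.  The union is the CNN's input feature set.
"""

import numpy as np

from seedspec import (
    CarsConfig,
    SyntheticSpec,
    cars_select,
    crop_band_range,
    generate_dataset,
    preprocess,
    spa_select,
    stratified_split,
    union_bands,
)

ds = generate_dataset(SyntheticSpec(seed=0))
table = preprocess(crop_band_range(ds.table, 949.43, 1709.49))

split = stratified_split(table.labels, 3, seed=0)
spa = spa_select(table.take_rows(np.nonzero(split != 0)[0]),
                 table.take_rows(np.nonzero(split == 0)[0]), k_max=20)
print(f"SPA : {spa.n_selected} bands, best val RMSE "
      f"{spa.criterion_curve[spa.chosen_step][1]:.4f} at k={spa.chosen_step + 1}")

cars = cars_select(table, CarsConfig(seed=0))
print(f"CARS: {cars.n_selected} bands, min RMSECV "
      f"{cars.criterion_curve[cars.chosen_step][1]:.4f} at run {cars.chosen_step + 1}")

union = union_bands(spa, cars)
print(f"union: {union.n_selected} bands -> {np.round(union.selected_wavelengths, 1)} nm")

# score against the generator's planted dip centres (+-3 bands tolerance)
step = ds.spec.wavelengths[1] - ds.spec.wavelengths[0]
truth_wl = ds.spec.wavelengths[ds.truth_band_set]
hits = sum(bool(np.any(np.abs(union.selected_wavelengths - w) <= 3 * step)) for w in truth_wl)
print(f"recovered {hits}/{len(truth_wl)} planted dip centres within +-3 bands")
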