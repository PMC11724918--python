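"""Grid-scan the four free Potts parameters on a small phantom.

Each (lambda_V, lambda_A, J_cc, J_cm) combination is simulated from the
same start and ranked ascending by the metric m.  A tiny 8-combination
grid and a short run keep this demonstration quick; the full calibration
grid has 6 * 6 * 6 * 3 = 648 combinations at 1000 MCS.
"""

import spherogen as sg

spec = sg.PhantomSpec(shape=(32, 32, 32), sphere_radius=13, n_cells=15, seed=0)
cells = sg.clean_labels(sg.make_phantom_spheroid(spec))

grid = {
    "lambda_V": [0.001, 10.0],
    "lambda_A": [0.001, 10.0],
    "J_cc": [2.0],
    "J_cm": [10.0, 55.0],
}
table = sg.grid_scan(cells, grid, mcs=50, seed=0)
cols = ["rank", "lambda_V", "lambda_A", "J_cc", "J_cm", "mean_W", "mean_IoU", "m"]
print(table[cols].round(3).to_string(index=False))
print(
    "\nLow-m combinations change cell positions (low IoU) while keeping "
    "feature distributions stable (low W); check mean_W and mean_IoU "
    "separately to spot frozen runs, which also score m = 0."
)
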