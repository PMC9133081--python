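"""Medio-lateral association between EMG amplitude centroids and territories.

Computes surrogate MUAP amplitude distributions over the 8x8 electrode grid
for a simulated population and regresses the units' medio-lateral territory
coordinate on the EMG centroid, illustrating the depth dependence the
multiple regression's interaction term captures.
"""

import numpy as np

import muecho as m

geometry = m.MuscleGeometry()
population = m.generate_population(geometry, n_mus=200, seed=3)

emg_x = np.array([m.surrogate_amplitudes(mu).emg_centroid_mm[0] for mu in population])
true_x = np.array([mu.center_mm[0] for mu in population])
depth = np.array([mu.center_mm[1] for mu in population])

slope, intercept, r2 = m.simple_regression(emg_x, true_x)
print(f"simple regression (territory x on EMG centroid x, n={len(population)}):")
print(f"  slope {slope:.2f}, intercept {intercept:.2f} mm, R^2 = {r2:.3f}")

fit = m.multiple_regression(true_x, emg_x, depth)
b = fit.coef
print("multiple regression  x_us = b1 + b2*x_emg + b3*depth + b4*x_emg*depth:")
print(f"  b2 = {b[1]:.3f}  (95% CI {fit.conf_int[1,0]:.3f}..{fit.conf_int[1,1]:.3f})")
print(f"  b4 = {b[3]:.4f} (95% CI {fit.conf_int[3,0]:.4f}..{fit.conf_int[3,1]:.4f})")
print(f"  R^2 = {fit.r_squared:.3f}")
# b4 > 0: the medio-lateral EMG-US relation is steeper for superficial units;
# deep units' surface amplitude distributions flatten, shrinking their EMG
# centroids toward the grid centre.
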