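"""Correlation length and order parameter of a migrating-monolayer velocity field.

Generates spatially correlated velocity fields (true correlation length
30 µm, drift 10 µm/h toward the free edge), runs the autocorrelation →
radial-average → correlation-length chain, and compares the estimate with
the generator truth.
"""

import numpy as np

from monolayer_mech import (
    CorrelationCurve,
    correlation_length,
    gen_velocity_field,
    order_parameter,
    radial_average,
    spatial_autocorrelation,
)

XI_UM = 30.0  # ground-truth correlation length
SPACING_UM = 12.08  # PIV mesh (32 px windows, 50% overlap, 0.755 µm/px)

curves, orders = [], []
for seed in range(20):
    field, truth = gen_velocity_field(
        shape=(128, 128), spacing_um=SPACING_UM, xi_um=XI_UM,
        sigma=5.0, drift=(10.0, 0.0), seed=seed,
    )
    orders.append(order_parameter(field))
    ac2d = spatial_autocorrelation(field)  # perpendicular component, AC(0)=1
    curves.append(radial_average(ac2d, SPACING_UM))

# average the radial curves over realizations (= over movie frames), then
# integrate up to the first zero crossing
mean_curve = CorrelationCurve(
    curves[0].r_um, np.mean([c.ac for c in curves], axis=0), curves[0].n_pairs
)
L = correlation_length(mean_curve, normalize=True)

print(f"true correlation length : {XI_UM:.1f} µm")
print(f"recovered               : {L:.1f} µm ({100 * (L / XI_UM - 1):+.1f}%)")
print(f"mean order parameter    : {np.mean(orders):.3f}")
print()
print("The recovered length is the first moment of the radially averaged")
print("velocity autocorrelation; the order parameter is the mean cosine")
print("between local velocities and the migration direction (1 = fully")
print("edge-directed, as expected for drift >> fluctuations it is close to 1).")
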