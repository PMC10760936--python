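"""Score photosynthetic growth of colonies from synthetic plate images.

Renders matched high-light and dark plates where two positions carry
photosynthesis-deficient mutants (small, pale colonies under light), then
recovers the normalized light/dark growth metric.
"""

import numpy as np

from photoscreen.colonies import measure_plate, photosynthetic_growth, \
    plate_normalize
from photoscreen.simulate import simulate_plate

rng = np.random.default_rng(0)
GRID = (16, 24)

dark_radii = np.full(GRID, 8.0)
dark_green = np.full(GRID, 0.8)
light_radii = dark_radii.copy()
light_green = dark_green.copy()

deficient = [(2, 3), (10, 17)]
for pos in deficient:
    light_radii[pos] = 2.5  # barely grows photoautotrophically
    light_green[pos] = 0.2  # and stays pale

light = measure_plate(simulate_plate(light_radii, light_green, seed=1))
dark = measure_plate(simulate_plate(dark_radii, dark_green, seed=1))

light_sizes = plate_normalize(light.set_index(["row", "col"])["size"])
dark_sizes = plate_normalize(dark.set_index(["row", "col"])["size"])
growth = photosynthetic_growth(light_sizes, dark_sizes)

print("median normalized growth (healthy) :",
      round(growth.drop(index=deficient).median(), 3))
for pos in deficient:
    print(f"normalized growth at {pos}        : {growth.loc[pos]:.3f}")
# Values near 1 mean light growth matches dark growth; values near 0 are the
# photosynthesis-deficient signature the screen selects for.
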