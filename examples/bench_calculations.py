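"""Closed-form bench arithmetic: cytochromes, CFU counts, doubling times.

Each call is a one-line quantitation a bench scientist would otherwise do on
a calculator; the printed values show the units at each step.
"""

import numpy as np

from tfcoherence import (
    CYTOCHROME_B,
    CYTOCHROME_D,
    cfu_per_ml,
    cytochrome_concentration,
    doubling_time_linear,
    growth_slope,
)

# Reduced-minus-oxidised difference spectrum: delta A over the 560-575 nm
# pair, 1 cm path, cell suspension at 8.2 mg protein / ml
conc_b = cytochrome_concentration(0.098, CYTOCHROME_B, path_cm=1.0,
                                  protein_mg_per_ml=8.2)
conc_d = cytochrome_concentration(0.061, CYTOCHROME_D, path_cm=1.0,
                                  protein_mg_per_ml=8.2)
print(f"cytochrome b: {conc_b:.3f} nmol/mg protein")
print(f"cytochrome d: {conc_d:.3f} nmol/mg protein")

# 23 colonies in a 10 ul spot of the 10^-6 dilution
print(f"viable count: {cfu_per_ml(23, 0.01, 1e-6):.2e} CFU/ml")

# linear-growth doubling time from an hourly OD600 series
times = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
ods = np.array([0.10, 0.16, 0.21, 0.27, 0.32])
slope = growth_slope(times, ods)
td = doubling_time_linear(ods[0], slope)
print(f"slope {slope:.3f} OD/h -> doubling time at addition {td:.2f} h")
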