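"""How spatial uncertainty decays with the inter-compartment exchange rate.

Simulates an instantaneous release into compartment "111" for a ladder of
exchange-to-ventilation ratios lambda_ex / lambda and prints the
cross-compartment coefficient of variation (CV) at 6 min and at 20 min.
CV = sd of the eight compartment concentrations / their mean; CV -> 0 means
the well-mixed assumption holds.
"""

import numpy as np

from sprayroom import (EmissionEvent, FlowParameters, build_grid,
                       cv_over_time, simulate_model2)

grid = build_grid()
times = np.linspace(0.0, 1.0 / 3.0, 401)
release = EmissionEvent(source="111", mass=883.0)

print("lambda_ex/lambda    CV(0.1 h)    CV(0.33 h)")
for ratio in (0.5, 1.0, 2.0, 4.64, 10.0):
    params = FlowParameters(30.0, 1.0, ratio * 1.0)
    cv = cv_over_time(simulate_model2(grid, params, release, times))
    at = lambda t: float(np.interp(t, cv["time_h"], cv["cv"]))
    print(f"{ratio:>14.2f}{at(0.1):13.3f}{at(1 / 3):14.3f}")
print("\nFaster mixing (larger lambda_ex) shrinks the spatial spread; at "
      "the fitted rate of 4.64/h the CV 20 min after application is well "
      "below 0.5.")
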