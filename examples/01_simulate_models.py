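"""Simulate a trigger-spray application with both spatial resolutions.

An 883 mg ethanol release (2 g of a 50 % v/v trigger-spray solution) enters
compartment "111" of a 30 m^3 chamber ventilated at 1 air change per hour.
The well-mixed model spreads it instantly over the room; the
eight-compartment model mixes it at the fitted exchange rate of 4.64/h.
"""

import numpy as np

from sprayroom import (EmissionEvent, FlowParameters, build_grid, scenario,
                       simulate_model1, simulate_model2, twa)

spec = scenario("trigger_50")
params = FlowParameters(volume=30.0, air_change_rate=1.0, lambda_ex=4.64)
mass = spec.emitted_mass_mg(spec.applied_mass_g)
times = np.linspace(0.0, 1.0 / 3.0, 1201)

grid = build_grid()
m2 = simulate_model2(grid, params, EmissionEvent(source="111", mass=mass),
                     times)
m1 = simulate_model1(params, EmissionEvent(mass=mass), times)

print(f"released ethanol mass: {mass:.0f} mg into compartment 111")
print(f"{'':>12}  TWA 0.1 h   TWA 0.3 h   (mg m^-3)")
for comp in ("111", "121", "222"):
    print(f"  C_{comp:<9}{twa(m2, comp, 0.1):9.1f}{twa(m2, comp, 0.3):12.1f}")
print(f"  well-mixed {twa(m1, 'WHOLE_ROOM', 0.1):9.1f}"
      f"{twa(m1, 'WHOLE_ROOM', 0.3):12.1f}")
print("\nThe source compartment's short-term (0.1 h) average exceeds the "
      "well-mixed prediction, while the far corner (222) sees far less; "
      "by 0.3 h the compartments have largely converged.")
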