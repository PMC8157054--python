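"""Recover the inter-compartment exchange rate from synthetic measurements.

Generates a triplicate trigger-spray study (5 % multiplicative instrument
noise, drifting background, replicate-to-replicate applied-mass variation),
runs the measurement pipeline (calibrate, background-subtract, 2.5-min
running average, normalize per gram applied) and fits lambda_ex to each
replicate jointly over all eight compartments.
"""

from sprayroom import (EmissionEvent, FlowParameters, RunConfig, build_grid,
                       fit_replicates, generate_study, preprocess_replicate,
                       scenario)

spec = scenario("trigger_50", seed=7)
replicates, manifest = generate_study(spec)
config = RunConfig()
processed = [preprocess_replicate(r, config) for r in replicates]
emissions = [EmissionEvent(
    source="111",
    mass=r.meta["emitted_mass_mg"] / r.meta["applied_mass_g"])
    for r in replicates]

grid = build_grid()
fit = fit_replicates(processed, grid, FlowParameters(30.0, 1.0, 0.0),
                     emissions)

print(f"generating truth: lambda_ex = {spec.true_lambda_ex} /h")
for rid, lam, ssr in fit.per_replicate:
    print(f"  replicate {rid}: lambda_ex = {lam:.3f} /h  (SSR {ssr:.1f})")
print(f"trimmed mean (trim fraction {fit.trim_fraction}): "
      f"{fit.aggregate:.3f} /h")
print("\nEach estimate is the exchange rate whose eight-compartment model "
      "best matches that replicate's processed traces; the aggregate is "
      "the estimate a chamber study would report.")
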