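"""Effective growth rates of the two population lineages.

Runs the simulator with the full reproductive bonus of the novel technology
(f_i = 0.015 each) but no intergroup adoption (beta = -10) and no postmarital
social learning, then fits log population vs. time for each lineage over the
expansion phase. Expected: the all-adaptive migrant lineage (B) grows at
roughly twice the incumbent baseline (A).
"""

import numpy as np

import hitchsim as hs

rates_a, rates_b = [], []
for seed in (1, 2, 3):
    params = hs.SimulationParams(
        beta=-10.0, f1=0.015, f2=0.015, f3=0.015,
        p_location=0.0, p_bias=0.0,
        trait_configs=hs.uniform_trait_configs(0.0, "none"),
        seed=seed,
    )
    record = hs.run(params)
    rates = hs.lineage_growth_rates(record)
    rates_a.append(rates["A"])
    rates_b.append(rates["B"])
    print(
        f"seed {seed}: stopped {record.stop_reason} after {record.n_steps} steps, "
        f"r_A = {rates['A']:.4f}, r_B = {rates['B']:.4f} per step"
    )

print(
    f"\nmean r_A = {np.mean(rates_a):.4f} (baseline demography), "
    f"mean r_B = {np.mean(rates_b):.4f} (with adaptive bonus)"
)
print(
    "r is the OLS slope of log(lineage population) vs. time; the B lineage's "
    "higher fertility compounds into faster fission and territorial spread."
)
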