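"""Monte Carlo variability of the health burdens.

Propagates every input distribution through the integrated model with
10,000 seeded draws and prints the 5th/50th/95th percentiles per system —
the variability bars of a comparison figure.
"""

from waterhealth.pipeline import run_monte_carlo_scenario
from waterhealth.synthetic import default_scenarios
from waterhealth.uncertainty import MonteCarloSpec

spec = MonteCarloSpec(iterations=10_000, seed=42)
for name, scenario in default_scenarios().items():
    res, mc = run_monte_carlo_scenario(scenario, spec)
    t = mc.summary.loc["total_daly"]
    print(
        f"{name:6s} total DALY/yr: median={t[50.0]:.4f}  "
        f"5th={t[5.0]:.4f}  95th={t[95.0]:.4f}  "
        f"(excluded iterations: {mc.n_excluded})"
    )

# The spread reflects both natural variability (energy intensity of the
# grid, pathogen concentrations) and data uncertainty; rerunning with the
# same seed reproduces these numbers exactly.
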