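"""Uncertain input intensities and their sensitivity ranges.

Builds the nine intensity distributions of the example systems (coagulant
and energy use per m³ of water/wastewater, transport energy per
household-year) and prints each one's 5th and 95th percentile — the
low/high bounds used by the one-at-a-time sensitivity analysis.
"""

from waterhealth.inventory import system_parameter_distributions
from waterhealth.synthetic import (
    SyntheticSpec,
    falmouth_functional_unit,
    generate_system_configs,
)

systems = generate_system_configs(SyntheticSpec(seed=0))
fu = falmouth_functional_unit()

for name, system in systems.items():
    print(f"\n{name}")
    for pname, d in system_parameter_distributions(system, fu).items():
        if d.kind == "point":
            continue
        print(
            f"  {pname:45s} {d.kind:10s} median={d.median:10.4g} "
            f"p5={d.quantile(0.05):10.4g} p95={d.quantile(0.95):10.4g}"
        )

# Each row is one uncertain input: the median is its reference value and
# the p5/p95 columns bound the range explored by the tornado analysis.
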