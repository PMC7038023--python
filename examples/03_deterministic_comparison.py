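"""Reference-case comparison of the three system designs.

Scores each design at the median of every input distribution and prints
the burden decomposition: life-cycle cancer and noncancer impacts of the
chemical releases across the supply chain, plus the local microbial risk,
all in DALY/year for one town's annual water and wastewater service.
"""

from waterhealth.lcia import stage_contributions
from waterhealth.pipeline import IntegratedModel, run_deterministic
from waterhealth.reporting import compare_systems
from waterhealth.synthetic import default_scenarios

scenarios = default_scenarios()
results = []
for name, scenario in scenarios.items():
    res = run_deterministic(scenario)
    results.append(res)
    s = res.shares
    print(
        f"{name:6s} total={res.total_daly:8.4f} DALY/yr  "
        f"(cancer {res.cancer_daly:.4f}, noncancer {res.noncancer_daly:.4f}, "
        f"microbial {res.microbial_daly:.4f}; LCA share {100 * s['lca']:.0f}%)"
    )

print("\nranking (1 = lowest burden):")
print(compare_systems(results)[["system", "total_daly", "rank"]].to_string(index=False))

model = IntegratedModel(scenarios["BAU"])
contrib = stage_contributions(model.detailed_lcia(model.reference_values()), "noncancer_daly")
print("\nBAU noncancer impact by stage (fraction of gross):")
print(contrib.round(3).to_string())

# The centralized design (BAU) carries the largest chemical-release burden,
# driven by wastewater collection/treatment energy; chemical (life-cycle)
# impacts dominate the totals, with microbial risk a minor share.
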