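"""Inverse inference for athletic competitions.

If a panel size is assumed optimal, the cost calculus pins the unknown
quantity into an interval.  Figure skating: nine judges at 76% imply the
cost of an error is 100-152 judge-fees.  Boxing: three judges at 95% with a
$100,000 purse imply a per-judge fee of $305-$2138; at a $1M purse and
$2,000 fees the optimal panel is five, not three.
"""

from panelcalc import (
    CostParams,
    implied_cost_ratio_interval,
    implied_judge_cost_interval,
    majority_curve,
    optimal_panel,
)

ratio = implied_cost_ratio_interval(p=0.76, n_opt=9)
print(f"skating: implied cost ratio {ratio.rounded()[0]:.0f}-{ratio.rounded()[1]:.0f} "
      f"(raw {ratio.lower:.1f}-{ratio.upper:.1f}, {ratio.rounding}-rounded)")

fee = implied_judge_cost_interval(p=0.95, n_opt=3, cost_per_error=100_000)
print(f"boxing:  implied judge fee ${fee.rounded()[0]:.0f}-${fee.rounded()[1]:.0f} "
      f"on a $100,000 purse")

ns = list(range(1, 17, 2))
opt = optimal_panel(majority_curve(0.95, ns), CostParams(2000, 1_000_000), ns)
print(f"boxing:  at a $1M purse with $2,000 fees the optimal panel is {opt.n_opt} judges")
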