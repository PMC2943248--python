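"""Cost-optimal panel size and the more-accurate-judges paradox.

With errors costing 55 times a judge's fee, majority panels of 70% judges
are cheapest at SEVEN judges while 65% judges are cheapest at FIVE — better
judges warrant the larger panel, because their accuracy curve is steeper
where a marginal pair of judges still pays for itself.  Above cost ratio 60
the reversal disappears.
"""

import numpy as np

from panelcalc import CostParams, expected_cost_curve, majority_curve, optimal_panel, optimal_panel_contour, find_paradox_pairs

ns = list(range(1, 27, 2))
costs = CostParams(cost_per_judge=1, cost_per_error=55)
for p in (0.65, 0.70):
    curve = expected_cost_curve(majority_curve(p, ns), costs, ns)
    opt = optimal_panel(majority_curve(p, ns), costs, ns)
    print(f"judges @ {100 * p:.0f}%: optimal panel = {opt.n_opt} "
          f"(expected cost {opt.min_cost:.2f} vs {curve.cost(3):.2f} at n=3)")

r_grid = np.arange(1, 201)
contour = optimal_panel_contour([0.65, 0.70], r_grid, n_max=51)
pairs = find_paradox_pairs(contour, [0.65, 0.70], r_grid)
ratios = sorted({r for _, _, r in pairs})
print(f"\nparadox (70% optimum > 65% optimum) at {len(ratios)} cost ratios, "
      f"all of them <= {max(ratios):.0f}; none above 60: {all(r <= 60 for r in ratios)}")
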