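"""Implied reviewer accuracy in grant review.

Ten reviewers per grant, $20 of reviewer cost per grant, and a sum-rule
prescore model (each reviewer's mean score for the weaker grant ~
normal(2, 0.5), coefficient of variation 0.2).  If ten reviewers are locally
optimal, the implied single-reviewer accuracy depends sharply on what an
error costs: 87-89% if an error costs the full $400,000 grant, only 67-69%
if it costs 1% of it.
"""

from panelcalc import CostParams, implied_accuracy_interval

for cost_per_error, label in [(400_000, "error costs the full grant ($400k)"),
                              (4_000, "error costs 1% of the grant ($4k)")]:
    iv = implied_accuracy_interval(
        n_opt=10,
        costs=CostParams(cost_per_judge=20, cost_per_error=cost_per_error),
        n_mean_draws=100_000,
        seed=0,
    )
    lo, hi = iv.rounded()
    print(f"{label}: implied reviewer accuracy {lo:.0f}-{hi:.0f}% "
          f"(raw {iv.lower:.2f}-{iv.upper:.2f}%)")
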