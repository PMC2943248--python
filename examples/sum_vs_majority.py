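"""Sum rule vs majority rule under tight and broad score distributions.

Judges are calibrated to 70% individual accuracy.  With a tight spread of
judge means (figure-skating-like, normal mean 7 sd 0.7) the sum rule
aggregates confidence and beats majority voting.  With a heavy-tailed
lognormal spread (microarray-probe-like, mean 700 sd 1400) a single extreme
judge can dominate the score total and the ordering reverses.
"""

from panelcalc import (
    SimConfig,
    broad_model,
    calibrate_separation,
    simulate_accuracy_curve,
    tight_model,
)

c = calibrate_separation(0.70, cv=0.2)
print(f"separation constant for 70% judges at cv 0.2: c = {c:.4f}")

config = SimConfig(n_values=(1, 3, 9), seed=42, n_panels=100_000)

for name, model in [
    ("tight normal(7, 0.7)", tight_model(c)),
    ("broad lognormal(700, 1400)", broad_model(c)),
]:
    s = simulate_accuracy_curve(model, "sum", config)
    m = simulate_accuracy_curve(model, "majority", config)
    print(f"\n{name}:")
    for n in config.n_values:
        if s.accuracy(n) == m.accuracy(n):
            verdict = "rules coincide for one judge" if n == 1 else "tie"
        else:
            verdict = ("sum" if s.accuracy(n) > m.accuracy(n) else "majority") + " rule ahead"
        print(
            f"  n={n}: sum {100 * s.accuracy(n):5.2f}%  majority {100 * m.accuracy(n):5.2f}%"
            f"   ({verdict})"
        )
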