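"""Majority-rule panel accuracy and the effect of adding inferior judges.

A panel of three 80%-accurate judges reaches 89.6% under majority rule.
Adding worse judges can *lower* the panel accuracy for a long stretch: 60%
judges must be added 22 at a time (25 total) before the mixture beats the
original trio.
"""

from panelcalc import PanelGroup, majority_accuracy, min_added_judges, mixed_panel_accuracy

base = PanelGroup(count=3, accuracy=0.80)
baseline = majority_accuracy(base.accuracy, base.count)
print(f"3 judges @ 80% -> panel accuracy {100 * baseline:.1f}%")

for added in (2, 10, 20, 22):
    acc = mixed_panel_accuracy(base, PanelGroup(added, 0.60))
    mark = "beats" if acc > baseline else "still below"
    print(f"  + {added:2d} judges @ 60% -> {100 * acc:.2f}%  ({mark} baseline)")

needed = min_added_judges(base, 0.60, max_added=100)
print(f"smallest helpful addition of 60% judges: {needed} (total panel {3 + needed})")
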