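"""Pairwise-majority ranking and the Voter's paradox.

Three judges rank three options cyclically; every pairwise contest splits
2-1 and the majority relation forms a cycle, so no option beats all others.
"""

import numpy as np

from panelcalc import RankProfile, condorcet_winner, pairwise_majority

profile = RankProfile(
    options=("A", "B", "C"),
    ranks=np.array([[1, 2, 3], [3, 1, 2], [2, 3, 1]]),  # A>B>C, B>C>A, C>A>B
)
digraph = pairwise_majority(profile)
for winner, loser in sorted(digraph.edges):
    print(f"{winner} beats {loser} (2 judges to 1)")
winner = condorcet_winner(digraph)
print(f"Condorcet winner: {winner if winner else 'none — the majority relation cycles'}")
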