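"""Shared brute-force oracles: exhaustive enumeration over vote patterns.

These deliberately avoid the package's analytic shortcuts (binomial tails,
convolutions) so they can serve as independent checks at small panel sizes.
"""

import itertools

import pytest


def enumerate_majority_accuracy(accuracies):
    """Probability that a strict majority of independent judges (given
    per-judge accuracies) vote correctly, by summing over all 2^n outcomes."""
    n = len(accuracies)
    total = 0.0
    for votes in itertools.product((0, 1), repeat=n):
        if sum(votes) > n / 2:
            prob = 1.0
            for v, p in zip(votes, accuracies):
                prob *= p if v else (1.0 - p)
            total += prob
    return total


@pytest.fixture
def majority_oracle():
    return enumerate_majority_accuracy
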