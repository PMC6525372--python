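"""Independent brute-force reference implementations used only by tests."""

import numpy as np


def brute_scaled_mann_whitney(values_a, values_b):
    """Explicit pair counting: U = #{a > b} with ties counted one half."""
    u = 0.0
    for a in values_a:
        for b in values_b:
            if a > b:
                u += 1.0
            elif a == b:
                u += 0.5
    return 2.0 * u / (len(values_a) * len(values_b)) - 1.0


def brute_enrichment_score(correlations, ordering, member_indices, exponent=1.0):
    """Explicit loop over ranked genes; signed extremum of the running sum."""
    member_indices = set(member_indices)
    n = len(correlations)
    n_set = len(member_indices)
    n_r = sum(abs(correlations[g]) ** exponent for g in member_indices)
    running = []
    total = 0.0
    for g in ordering:
        if g in member_indices:
            total += abs(correlations[g]) ** exponent / n_r
        else:
            total -= 1.0 / (n - n_set)
        running.append(total)
    best = 0
    for i, v in enumerate(running):
        if abs(v) > abs(running[best]):
            best = i
    return running[best], np.array(running)
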