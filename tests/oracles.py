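"""Independent brute-force oracles used only by the test suite.

Deliberately naive (explicit Python loops, no shared code with the
package) so they stay independent of the implementations they check.
"""


def ks_oracle(tag_positions, n_genes):
    """Enrichment score by explicit evaluation of both running
    deviations at every j."""
    v = sorted(tag_positions)
    t = len(v)
    a_candidates = []
    b_candidates = []
    for j in range(1, t + 1):
        a_candidates.append(j / t - v[j - 1] / n_genes)
        b_candidates.append(v[j - 1] / n_genes - (j - 1) / t)
    a = max(a_candidates)
    b = max(b_candidates)
    return a if a > b else -b


def bh_oracle(p_values):
    """Benjamini-Hochberg step-up by the textbook definition."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [None] * m
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        value = p_values[i] * m / rank_from_top
        running_min = min(running_min, value)
        adjusted[i] = min(running_min, 1.0)
    return adjusted


def exhaustive_resample_pvalue(observed_mean, n, pool):
    """Exact two-sided resampling p over all n-subsets of the pool,
    with the same +1 pseudo-count convention."""
    from itertools import combinations

    means = [sum(c) / n for c in combinations(pool, n)]
    exceed = sum(1 for m in means if abs(m) >= abs(observed_mean))
    return (1 + exceed) / (len(means) + 1)
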