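"""Independent reference implementations used only to cross-check results.

Each oracle deliberately avoids the code path it verifies: nearest distances
by an explicit double loop over strings, Fisher p-values by exact-integer
hypergeometric enumeration, KDE mode counts by scipy's normal pdf and a
scalar scan.
"""

import math

import numpy as np
from scipy.stats import norm


def hamming_fraction(seq_a, seq_b):
    assert len(seq_a) == len(seq_b)
    return sum(1 for x, y in zip(seq_a, seq_b) if x != y) / len(seq_a)


def brute_force_nearest(table, modal_ids, rare_ids):
    """All-pairs scan: rare id -> (min distance, lexicographically first argmin)."""
    seq_of = dict(zip(table.otu_ids, table.sequences))
    out = {}
    for rid in rare_ids:
        best, best_id = None, None
        for mid in sorted(modal_ids):
            d = hamming_fraction(seq_of[rid], seq_of[mid])
            if best is None or d < best:
                best, best_id = d, mid
        out[rid] = (best, best_id)
    return out


def conserved_columns_scan(sequences):
    """Column-by-column identity scan."""
    L = len(sequences[0])
    count = 0
    for col in range(L):
        first = sequences[0][col]
        if all(seq[col] == first for seq in sequences):
            count += 1
    return count


def fisher_point_numerators(r1, r2, c1):
    """Exact integer numerators C(r1,a)*C(r2,c1-a) over the feasible a range."""
    amin = max(0, c1 - r2)
    amax = min(r1, c1)
    return amin, [math.comb(r1, a) * math.comb(r2, c1 - a) for a in range(amin, amax + 1)]


def fisher_p_enumeration(a, b, c, d, tie_tol=1e-7):
    """Two-sided probability-mass p by full enumeration with fixed margins."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    amin, nums = fisher_point_numerators(r1, r2, c1)
    denom = math.comb(n, c1)
    obs = nums[a - amin]
    total = sum(num for num in nums if num <= obs * (1.0 + tie_tol))
    return min(1.0, total / denom)


def count_modes_direct(sample, h, grid_size=4096):
    """Mode count from a fine-grid KDE built with scipy's normal pdf."""
    x = np.asarray(sample, dtype=float)
    grid = np.linspace(x.min() - 3 * h, x.max() + 3 * h, grid_size)
    density = norm.pdf(grid[:, None], loc=x[None, :], scale=h).mean(axis=1)
    # scalar scan with plateau collapse
    values = [density[0]]
    for v in density[1:]:
        if v != values[-1]:
            values.append(v)
    if len(values) == 1:
        return 1
    count = 0
    for i, v in enumerate(values):
        left = values[i - 1] if i > 0 else -math.inf
        right = values[i + 1] if i < len(values) - 1 else -math.inf
        if v > left and v > right:
            count += 1
    return count
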