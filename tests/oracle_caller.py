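"""Naive O(N*W) re-implementation of the pause-calling criterion.

Written independently of the production code path: explicit loops over
candidate positions and background windows, plain-python moments.  Used
as the equivalence oracle for the vectorized caller.
"""

import math


def naive_call_gene(counts, window=200, z=3.0, min_reads=2,
                    min_informative=50, max_iter=10):
    """Return the boolean pause mask for one gene's count vector."""
    counts = [float(c) for c in counts]
    L = len(counts)
    half = window // 2
    mask = [False] * L
    for _ in range(max_iter):
        new = [False] * L
        for i in range(L):
            if counts[i] < min_reads:
                continue
            vals = []
            for j in range(max(0, i - half), min(L, i + half + 1)):
                if j == i or mask[j]:
                    continue
                vals.append(counts[j])
            n = len(vals)
            if n < min_informative:
                continue
            total = sum(vals)
            if total == 0:
                mean, sd = 0.0, 0.0
            else:
                mean = total / n
                var = sum((v - mean) ** 2 for v in vals) / (n - 1) \
                    if n > 1 else 0.0
                sd = math.sqrt(var) if var > mean else math.sqrt(mean)
            if counts[i] > mean + z * sd:
                new[i] = True
        if new == mask:
            break
        mask = new
    return mask
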