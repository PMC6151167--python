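"""Independent brute-force oracles shared across test modules.

These deliberately avoid the package's own code paths: pair loops
instead of allele-count algebra, and Tajima constants recomputed from
first principles.
"""

import itertools
import math

import numpy as np


def brute_force_pair_mean(a, pairs, scale_to_span=None):
    vals = []
    n_sites = a.shape[1]
    for i, j in pairs:
        d = c = 0
        for s in range(n_sites):
            if a[i, s] >= 0 and a[j, s] >= 0:
                c += 1
                if a[i, s] != a[j, s]:
                    d += 1
        denom = c if scale_to_span is None else c * scale_to_span / n_sites
        if denom > 0:
            vals.append(d / denom)
    return float(np.mean(vals)) if vals else math.nan


def tajima_oracle(a):
    """Tajima (1989) D recomputed from first principles (pair counting)."""
    n, s_total = a.shape
    seg = [s for s in range(s_total) if 0 < a[:, s].sum() < n]
    s = len(seg)
    if s == 0 or n < 4:
        return math.nan
    pi_hat = 0.0
    npairs = n * (n - 1) / 2
    for i, j in itertools.combinations(range(n), 2):
        pi_hat += sum(a[i, k] != a[j, k] for k in seg) / npairs
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i ** 2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n ** 2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    return (pi_hat - s / a1) / math.sqrt(e1 * s + e2 * s * (s - 1))
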