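"""Independent brute-force oracles shared by the test suites."""

import numpy as np


def brute_force_stats(mat):
    """Enumeration-based summary statistics for a binary haplotype matrix.

    Returns (S, theta_w, pi, fay_wu_h, K, haplotype_diversity, zns) with
    zns None when fewer than two segregating sites remain.
    """
    n = mat.shape[0]
    counts = mat.sum(axis=0)
    keep = (counts > 0) & (counts < n)
    mat = mat[:, keep]
    s = mat.shape[1]
    pi_sum = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            pi_sum += int(np.sum(mat[i] != mat[j]))
    pi = pi_sum / (n * (n - 1) / 2)
    a1 = sum(1.0 / k for k in range(1, n))
    theta_w = s / a1
    theta_h = 0.0
    for col in mat.T:
        i = int(col.sum())
        theta_h += 2.0 * i * i / (n * (n - 1))
    counts_h = {}
    for row in mat:
        key = tuple(row)
        counts_h[key] = counts_h.get(key, 0) + 1
    k_distinct = len(counts_h)
    dvh = n / (n - 1) * (1 - sum((c / n) ** 2 for c in counts_h.values()))
    zns = None
    if s >= 2:
        vals = []
        for i in range(s):
            for j in range(i + 1, s):
                pa, pb = mat[:, i].mean(), mat[:, j].mean()
                d = np.mean(mat[:, i] * mat[:, j]) - pa * pb
                vals.append(d * d / (pa * (1 - pa) * pb * (1 - pb)))
        zns = float(np.mean(vals))
    return s, theta_w, pi, pi - theta_h, k_distinct, dvh, zns
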