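"""Independent brute-force oracles (kept free of segfuse internals)."""

import numpy as np


def brute_force_glcm(q, offset, levels, symmetric):
    """Exhaustive double-loop pair counter (independent of segfuse.texture)."""
    dy, dx = offset
    h, w = q.shape
    counts = np.zeros((levels, levels), dtype=np.int64)
    for y in range(h):
        for x in range(w):
            yy, xx = y + dy, x + dx
            if 0 <= yy < h and 0 <= xx < w:
                counts[q[y, x], q[yy, xx]] += 1
                if symmetric:
                    counts[q[yy, xx], q[y, x]] += 1
    return counts


def brute_force_haralick(counts):
    """Direct formula evaluation on raw counts (independent path)."""
    total = counts.sum()
    if total == 0:
        return 0.0, 0.0, 0.0
    levels = counts.shape[0]
    p = counts / total
    asm = 0.0
    contrast = 0.0
    mu_i = mu_j = 0.0
    for i in range(levels):
        for j in range(levels):
            asm += p[i, j] ** 2
            contrast += (i - j) ** 2 * p[i, j]
            mu_i += i * p[i, j]
            mu_j += j * p[i, j]
    var_i = var_j = cov = 0.0
    for i in range(levels):
        for j in range(levels):
            var_i += (i - mu_i) ** 2 * p[i, j]
            var_j += (j - mu_j) ** 2 * p[i, j]
            cov += (i - mu_i) * (j - mu_j) * p[i, j]
    if var_i <= 0 or var_j <= 0:
        return asm, contrast, 0.0
    return asm, contrast, cov / np.sqrt(var_i * var_j)
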