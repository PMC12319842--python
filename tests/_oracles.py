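"""Independent brute-force oracles shared by the test modules."""
import numpy as np


def otsu_bruteforce(values, bins=256):
    """Exhaustive scan over all histogram-bin boundaries maximizing
    between-class variance (independent of the production implementation)."""
    counts, edges = np.histogram(values, bins=bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    best, best_t = -1.0, edges[1]
    for k in range(1, bins):
        w0, w1 = counts[:k].sum(), counts[k:].sum()
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (counts[:k] * centers[:k]).sum() / w0
        mu1 = (counts[k:] * centers[k:]).sum() / w1
        v = w0 * w1 * (mu0 - mu1) ** 2
        if v > best:
            best, best_t = v, edges[k]
    return best_t
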