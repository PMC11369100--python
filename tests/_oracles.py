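"""Brute-force reference implementations, independent of the package."""

import numpy as np
from scipy import stats


def oracle_kruskal(samples):
    """H from first principles: explicit midranks and the defining formula."""
    pooled = np.concatenate(samples)
    order = np.sort(pooled)

    def midrank(v):
        positions = [i + 1 for i, x in enumerate(order) if x == v]
        return sum(positions) / len(positions)

    N = pooled.size
    h = 0.0
    for s in samples:
        rs = sum(midrank(v) for v in s)
        h += rs**2 / len(s)
    h = 12 / (N * (N + 1)) * h - 3 * (N + 1)
    ties = 0.0
    for v in set(pooled.tolist()):
        t = (pooled == v).sum()
        ties += t**3 - t
    return h / (1 - ties / (N**3 - N))


def oracle_dunn_z(samples, i, j):
    pooled = np.concatenate(samples)
    ranks = stats.rankdata(pooled)
    N = pooled.size
    bounds = np.cumsum([0] + [len(s) for s in samples])
    mean_ranks = [
        ranks[bounds[a]:bounds[a + 1]].mean() for a in range(len(samples))
    ]
    ties = sum((c**3 - c) for c in np.unique(pooled, return_counts=True)[1])
    var = N * (N + 1) / 12 - ties / (12 * (N - 1))
    se = np.sqrt(var * (1 / len(samples[i]) + 1 / len(samples[j])))
    return (mean_ranks[i] - mean_ranks[j]) / se


def oracle_levene(samples):
    g = len(samples)
    N = sum(len(s) for s in samples)
    z = [np.abs(np.asarray(s) - np.mean(s)) for s in samples]
    zbar = np.concatenate(z).mean()
    num = sum(len(s) * (zi.mean() - zbar) ** 2 for s, zi in zip(samples, z))
    den = sum(((zi - zi.mean()) ** 2).sum() for zi in z)
    return (N - g) / (g - 1) * num / den
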