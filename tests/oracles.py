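"""Independent brute-force oracles used to check the implementation.

Everything here is written as plain, slow enumeration with no shared code
with the package internals.
"""

from __future__ import annotations

import numpy as np

ANGLE_OFFSETS = {0: (0, 1), 45: (1, 1), 90: (1, 0), 135: (1, -1)}


def glcm_bruteforce(levels: np.ndarray, mask: np.ndarray, L: int, d: int,
                    angles=(0, 45, 90, 135)) -> np.ndarray:
    """Exhaustive symmetric pair counts by looping over every voxel pair."""
    counts = np.zeros((L, L), dtype=np.int64)
    nr, nc, nz = levels.shape
    for z in range(nz):
        for r in range(nr):
            for c in range(nc):
                if not mask[r, c, z]:
                    continue
                for ang in angles:
                    ur, uc = ANGLE_OFFSETS[ang]
                    r2, c2 = r + ur * d, c + uc * d
                    if 0 <= r2 < nr and 0 <= c2 < nc and mask[r2, c2, z]:
                        a, b = levels[r, c, z], levels[r2, c2, z]
                        counts[a, b] += 1
                        counts[b, a] += 1
    return counts


def haralick_bruteforce(p: np.ndarray) -> dict[str, float]:
    """Double-loop evaluation of the eleven texture parameters."""
    L = p.shape[0]
    px = [sum(p[i, j] for j in range(L)) for i in range(L)]
    mu = sum(i * px[i] for i in range(L))
    sigma2 = sum((i - mu) ** 2 * px[i] for i in range(L))

    p_sum = [0.0] * (2 * L - 1)
    p_diff = [0.0] * L
    for i in range(L):
        for j in range(L):
            p_sum[i + j] += p[i, j]
            p_diff[abs(i - j)] += p[i, j]

    def ent(probs):
        return -sum(q * np.log(q) for q in probs if q > 0)

    out = {}
    out["uniformity"] = sum(p[i, j] ** 2 for i in range(L) for j in range(L))
    out["contrast"] = sum((i - j) ** 2 * p[i, j] for i in range(L) for j in range(L))
    if sigma2 > 0:
        out["correlation"] = sum(
            (i - mu) * (j - mu) * p[i, j] for i in range(L) for j in range(L)
        ) / sigma2
    else:
        out["correlation"] = 0.0
    out["variance"] = sum((i - mu) ** 2 * p[i, j] for i in range(L) for j in range(L))
    out["homogeneity"] = sum(
        p[i, j] / (1 + (i - j) ** 2) for i in range(L) for j in range(L)
    )
    out["entropy"] = ent(p.ravel())
    sa = sum(k * p_sum[k] for k in range(2 * L - 1))
    out["sum_average"] = sa
    out["sum_variance"] = sum((k - sa) ** 2 * p_sum[k] for k in range(2 * L - 1))
    out["sum_entropy"] = ent(p_sum)
    da = sum(k * p_diff[k] for k in range(L))
    out["difference_variance"] = sum((k - da) ** 2 * p_diff[k] for k in range(L))
    out["difference_entropy"] = ent(p_diff)
    return out


def random_symmetric_glcm(rng: np.random.Generator, L: int = 8) -> np.ndarray:
    """A random valid symmetric probability matrix."""
    counts = rng.integers(0, 20, size=(L, L))
    counts = counts + counts.T
    if counts.sum() == 0:
        counts[0, 0] = 2
    return counts / counts.sum()


def mean_sd_twopass(values) -> tuple[float, float]:
    values = list(map(float, values))
    n = len(values)
    mean = sum(values) / n
    if n == 1:
        return mean, 0.0
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    return mean, var ** 0.5
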