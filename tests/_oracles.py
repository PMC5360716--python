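"""Independent oracles used by the test suite.

These deliberately avoid the library code paths they are used to check:
finite differences for gradients, naive loops for sums, quaternion
superposition for RMSD, closed-form truncated-normal moments.
"""

import numpy as np


def finite_difference(f, x, eps=1e-6):
    """Central finite-difference gradient of a scalar function."""
    x = np.asarray(x, dtype=np.float64)
    g = np.zeros_like(x)
    for i in range(x.size):
        xp = x.copy()
        xp.flat[i] += eps
        xm = x.copy()
        xm.flat[i] -= eps
        g.flat[i] = (f(xp) - f(xm)) / (2.0 * eps)
    return g


def rel_err(a, b):
    a, b = np.asarray(a, float), np.asarray(b, float)
    scale = max(np.max(np.abs(a)), np.max(np.abs(b)), 1e-12)
    return np.max(np.abs(a - b)) / scale


def quaternion_superposed_rmsd(a, b):
    """Least-squares superposed RMSD via the quaternion eigenvalue method."""
    a = np.asarray(a, float) - np.mean(a, axis=0)
    b = np.asarray(b, float) - np.mean(b, axis=0)
    # correlation matrix and the 4x4 key matrix of Kearsley/Kabsch theory
    R = b.T @ a
    K = np.array(
        [
            [R[0, 0] + R[1, 1] + R[2, 2], R[1, 2] - R[2, 1], R[2, 0] - R[0, 2], R[0, 1] - R[1, 0]],
            [R[1, 2] - R[2, 1], R[0, 0] - R[1, 1] - R[2, 2], R[0, 1] + R[1, 0], R[0, 2] + R[2, 0]],
            [R[2, 0] - R[0, 2], R[0, 1] + R[1, 0], -R[0, 0] + R[1, 1] - R[2, 2], R[1, 2] + R[2, 1]],
            [R[0, 1] - R[1, 0], R[0, 2] + R[2, 0], R[1, 2] + R[2, 1], -R[0, 0] - R[1, 1] + R[2, 2]],
        ]
    )
    lam_max = np.linalg.eigvalsh(K)[-1]
    ssd = (a * a).sum() + (b * b).sum() - 2.0 * lam_max
    return float(np.sqrt(max(ssd, 0.0) / a.shape[0]))


def truncated_normal_mean(mu, sd):
    """Mean of a Normal(mu, sd) truncated to (0, inf)."""
    from scipy.stats import norm

    a = -mu / sd
    return mu + sd * norm.pdf(a) / norm.sf(a)


def block_mean_downsample(values, k):
    """Naive loop block-mean decimation (edge blocks over what exists)."""
    values = np.asarray(values, float)
    shape = [int(np.ceil(s / k)) for s in values.shape]
    out = np.zeros(shape)
    for i in range(shape[0]):
        for j in range(shape[1]):
            for l in range(shape[2]):
                block = values[i * k:(i + 1) * k, j * k:(j + 1) * k, l * k:(l + 1) * k]
                out[i, j, l] = block.mean()
    return out
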