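"""Independent brute-force reference implementations used only by tests.

These deliberately mirror the mathematical definitions with nested Python
loops and stay independent of the vectorized implementations they check.
"""

import math

import numpy as np


def naive_gaussian_convolve(image, sd, positions, spacing):
    """Per-channel convolution with a unit-sum Gaussian kernel, zero padding."""
    n, n_dir = image.shape
    total = sum(
        math.exp(-0.5 * ((k * spacing) / sd) ** 2) for k in range(-(n - 1), n)
    )
    out = np.zeros_like(image, dtype=float)
    for d in range(n_dir):
        for i in range(n):
            acc = 0.0
            for j in range(n):
                w = math.exp(-0.5 * ((positions[i] - positions[j]) / sd) ** 2)
                acc += image[j, d] * w
            out[i, d] = acc / total
    return out


def naive_excitatory(stim_image, params, grid):
    return naive_gaussian_convolve(
        stim_image, params.excit_width, grid.positions, grid.spacing
    )


def naive_suppressive(E, params, grid):
    n, n_dir = E.shape
    pooled = np.zeros((n, 1))
    for i in range(n):
        for d in range(n_dir):
            pooled[i, 0] += E[i, d]
    blurred = naive_gaussian_convolve(
        pooled, params.suppress_width, grid.positions, grid.spacing
    )
    out = np.zeros_like(E, dtype=float)
    for d in range(n_dir):
        for i in range(n):
            out[i, d] = blurred[i, 0]
    return out


def naive_attention(center, params, grid):
    n = grid.positions.size
    out = np.zeros((n, grid.n_directions))
    for d in range(grid.n_directions):
        for i in range(n):
            x = grid.positions[i]
            out[i, d] = 1.0 + (params.attn_amplitude - 1.0) * math.exp(
                -0.5 * ((x - center) / params.attn_width) ** 2
            )
    return out


def naive_population(E, S, A, sigma):
    n, n_dir = E.shape
    out = np.zeros_like(E, dtype=float)
    for i in range(n):
        for d in range(n_dir):
            out[i, d] = A[i, d] * E[i, d] / (S[i, d] + sigma)
    return out


def naive_max(values):
    best = -math.inf
    for row in values:
        for v in row:
            if v > best:
                best = v
    return best


def brute_expected_entropy(state):
    """Expected posterior entropy per lattice value by explicit enumeration."""

    def entropy(p):
        p = p[p > 0]
        return float(-(p * np.log(p)).sum())

    post = state.posterior
    A = state.alpha_grid[None, :, None]
    B = state.beta_grid[None, None, :]
    X = np.asarray(state.stimulus_lattice)[:, None, None]
    P = state.gamma + (1 - state.gamma - state.lam) * (1 - np.exp(-((X / A) ** B)))
    out = []
    for ix in range(len(state.stimulus_lattice)):
        eh = 0.0
        for outcome in (True, False):
            like = P[ix] if outcome else 1 - P[ix]
            unnorm = post * like
            mass = unnorm.sum()
            eh += mass * entropy((unnorm / mass).ravel())
        out.append(eh)
    return np.array(out)


def textbook_pearson(x, y):
    """Direct-formula product-moment r and two-sided p via the t transform."""
    from scipy.stats import t as t_dist

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    mx, my = x.mean(), y.mean()
    num = ((x - mx) * (y - my)).sum()
    den = math.sqrt(((x - mx) ** 2).sum() * ((y - my) ** 2).sum())
    r = num / den
    r_clipped = min(max(r, -1.0), 1.0)
    if abs(r_clipped) == 1.0:
        return r_clipped, 0.0, n
    t = r_clipped * math.sqrt((n - 2) / (1 - r_clipped**2))
    p = 2 * t_dist.sf(abs(t), n - 2)
    return r, p, n
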