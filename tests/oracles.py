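"""Independent reference computations used to validate the package.

These deliberately avoid the package's own code paths: explicit loops,
scalar root equations and plain IRLS, so they can serve as oracles.
"""

import numpy as np


def symmetric_net_growth(x, r, alpha=1.5, beta=1.0, c=1.0):
    """Net per-capita growth of the symmetric 1 plant + 1 pollinator
    system at state P = A = x (self-similarity 1, intraspecific
    competition 1), written as a scalar equation."""
    return r + alpha * x / (1.0 + beta * x + c * x) - x


def brute_force_nodf(IM):
    """Literal pairwise NODF: explicit loops over row and column pairs."""
    def half(X):
        total, pairs = 0.0, 0
        n = X.shape[0]
        for i in range(n):
            for j in range(i + 1, n):
                pairs += 1
                fi, fj = X[i].sum(), X[j].sum()
                if fi == fj:
                    continue
                dense, sparse = (i, j) if fi > fj else (j, i)
                shared = sum(
                    1 for k in range(X.shape[1])
                    if X[dense, k] == 1 and X[sparse, k] == 1
                )
                total += 100.0 * shared / X[sparse].sum()
        return total, pairs

    rs, rp = half(IM)
    cs, cp = half(IM.T)
    return (rs + cs) / (rp + cp)


def irls_binomial(X, y, w, tol=1e-12, max_iter=200):
    """Plain IRLS for a binomial-logit GLM with prior weights."""
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        W = w * mu * (1.0 - mu)
        z = eta + (y - mu) / (mu * (1.0 - mu))
        new = np.linalg.solve(X.T @ (W[:, None] * X), X.T @ (W * z))
        if np.max(np.abs(new - beta)) < tol:
            return new
        beta = new
    return beta


def random_binary(rng, shape, p=0.5):
    """A random 0/1 matrix without empty rows or columns."""
    while True:
        M = (rng.random(shape) < p).astype(float)
        if M.sum() and (M.sum(0) > 0).all() and (M.sum(1) > 0).all():
            return M
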