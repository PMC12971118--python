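"""Independent oracles used by the unit and acceptance tests.

Each function here recomputes a quantity by a route deliberately
different from the package implementation: scalar step-by-step formula
evaluation for the Weir-Cockerham components, and direct numerical
maximisation of the binomial log-likelihood for the GLM fits.
"""

import math

import numpy as np
from scipy.optimize import minimize


def wc_site_oracle(pop_dosages):
    """Weir-Cockerham (a, b, c) for one site, evaluated step by step from
    per-population dosage lists (missing encoded as negative)."""
    ns, ps, hs = [], [], []
    for dos in pop_dosages:
        dos = [d for d in dos if d >= 0]
        n_i = len(dos)
        ns.append(n_i)
        ps.append(sum(dos) / (2.0 * n_i))
        hs.append(sum(1 for d in dos if d == 1) / n_i)
    r = len(ns)
    nbar = sum(ns) / r
    nc = (r * nbar - sum(n**2 for n in ns) / (r * nbar)) / (r - 1)
    pbar = sum(n * p for n, p in zip(ns, ps)) / (r * nbar)
    s2 = sum(n * (p - pbar) ** 2 for n, p in zip(ns, ps)) / ((r - 1) * nbar)
    hbar = sum(n * h for n, h in zip(ns, hs)) / (r * nbar)
    pq = pbar * (1.0 - pbar)

    a = (nbar / nc) * (
        s2 - (pq - s2 * (r - 1) / r - hbar / 4.0) / (nbar - 1.0)
    )
    b = (nbar / (nbar - 1.0)) * (
        pq - s2 * (r - 1) / r - hbar * (2.0 * nbar - 1.0) / (4.0 * nbar)
    )
    c = hbar / 2.0
    return a, b, c


def binom_loglik(beta, X, y, m=2.0):
    """Binomial log-likelihood (incl. binomial coefficients) at beta."""
    eta = X @ np.asarray(beta)
    pi = 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))
    pi = np.clip(pi, 1e-12, 1.0 - 1e-12)
    ll = 0.0
    for yi, pii in zip(y, pi):
        ll += (
            math.log(math.comb(int(m), int(yi)))
            + yi * math.log(pii)
            + (m - yi) * math.log(1.0 - pii)
        )
    return ll


def glm_oracle_loglik(X, y, m=2.0):
    """Maximum binomial log-likelihood via a generic numerical optimiser
    (multi-start Nelder-Mead + BFGS), independent of IRLS."""
    best = -np.inf
    p = X.shape[1]
    for start in ([0.0] * p, [0.5] * p, [-0.5] * p):
        for method in ("BFGS", "Nelder-Mead"):
            res = minimize(
                lambda b: -binom_loglik(b, X, y, m), start, method=method,
                options={"maxiter": 5000, "xatol": 1e-10, "fatol": 1e-12}
                if method == "Nelder-Mead" else {"maxiter": 2000},
            )
            best = max(best, -res.fun)
    return best
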