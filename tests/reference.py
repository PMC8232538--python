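"""Brute-force posterior references, independent of the Gibbs sampler.

Two routes:

* dense quadrature over 1-2 free parameters (exact up to grid error), and
* a long-run adaptive random-walk Metropolis sampler for 3-10 free
  parameters, with Monte Carlo standard errors from effective sample sizes.

Both consume only a log-posterior callable, so they share no code path
with the Pólya-Gamma blocked Gibbs implementation they are used to check.
"""

from __future__ import annotations

import numpy as np
from scipy.special import logsumexp


def loglik_logistic(eta, y):
    return float(np.sum(y * eta) - np.sum(np.logaddexp(0.0, eta)))


def constraint_basis(a):
    """Orthonormal basis Z of the subspace {x : a'x = 0} (columns)."""
    a = np.asarray(a, dtype=float)
    k = a.shape[0]
    q, _ = np.linalg.qr(np.column_stack([a, np.eye(k)[:, : k - 1]]))
    # first column spans a; the rest span its orthogonal complement
    return q[:, 1:]


def grid_posterior(logpost, bounds, num=351):
    """Posterior mean/sd/quantiles by dense quadrature over 1 or 2 dims.

    ``bounds`` is a list of (lo, hi) per dimension. Returns per-dimension
    dicts with mean, sd, q2.5, q97.5 (marginals).
    """
    axes = [np.linspace(lo, hi, num) for lo, hi in bounds]
    if len(bounds) == 1:
        lp = np.array([logpost(np.array([x])) for x in axes[0]])
        w = np.exp(lp - logsumexp(lp))
        return [_weighted_summary(axes[0], w)]
    X, Y = np.meshgrid(axes[0], axes[1], indexing="ij")
    lp = np.empty(X.shape)
    for i in range(num):
        for j in range(num):
            lp[i, j] = logpost(np.array([X[i, j], Y[i, j]]))
    w = np.exp(lp - logsumexp(lp))
    return [
        _weighted_summary(axes[0], w.sum(axis=1)),
        _weighted_summary(axes[1], w.sum(axis=0)),
    ]


def _weighted_summary(x, w):
    w = w / w.sum()
    mean = float(np.sum(w * x))
    sd = float(np.sqrt(np.sum(w * (x - mean) ** 2)))
    cdf = np.cumsum(w)
    q025 = float(np.interp(0.025, cdf, x))
    q975 = float(np.interp(0.975, cdf, x))
    return {"mean": mean, "sd": sd, "q2.5": q025, "q97.5": q975, "mcse": 0.0}


def rwm_reference(logpost, x0, n_iter=150_000, burn=20_000, seed=0):
    """Adaptive random-walk Metropolis, returning draws after burn-in.

    Proposal covariance adapts to the empirical covariance during burn-in
    (frozen afterwards so the kept chain is a genuine Markov chain).
    """
    rng = np.random.default_rng(seed)
    x = np.asarray(x0, dtype=float).copy()
    d = x.shape[0]
    lp = logpost(x)
    cov_chol = 0.1 * np.eye(d)
    draws = np.empty((n_iter - burn, d))
    hist = np.empty((burn, d))
    accepted = 0
    for it in range(n_iter):
        prop = x + cov_chol @ rng.standard_normal(d)
        lp_prop = logpost(prop)
        if np.log(rng.random()) < lp_prop - lp:
            x, lp = prop, lp_prop
            accepted += 1
        if it < burn:
            hist[it] = x
            if it in (2000, 5000, 10000, burn - 1) and it > 0:
                emp = np.cov(hist[: it + 1].T).reshape(d, d)
                emp += 1e-8 * np.eye(d)
                cov_chol = np.linalg.cholesky(2.38**2 / d * emp)
        else:
            draws[it - burn] = x
    return draws


def chain_summary(draws):
    """Posterior summaries with Monte Carlo SEs from effective sample sizes."""
    import arviz as az

    draws = np.atleast_2d(draws)
    if draws.shape[0] == 1:
        draws = draws.T
    out = []
    for j in range(draws.shape[1]):
        col = draws[:, j]
        ess = max(float(az.ess(col[None, :])), 4.0)
        q = np.quantile(col, [0.025, 0.975])
        mcse_q = float(az.mcse(col[None, :], method="quantile", prob=0.025))
        out.append(
            {
                "mean": float(col.mean()),
                "sd": float(col.std(ddof=1)),
                "q2.5": float(q[0]),
                "q97.5": float(q[1]),
                "mcse": float(col.std(ddof=1) / np.sqrt(ess)),
                "mcse_q": mcse_q,
            }
        )
    return out


def assert_posterior_close(got, ref, label, factor=3.0, floor=1e-3):
    """Means agree within ``factor`` x combined Monte Carlo SE (plus floor)."""
    tol = factor * np.hypot(got["mcse"], ref["mcse"]) + floor
    diff = abs(got["mean"] - ref["mean"])
    assert diff <= tol, (
        f"{label}: posterior mean {got['mean']:.4f} vs reference "
        f"{ref['mean']:.4f}, |diff|={diff:.4f} > tol={tol:.4f}"
    )


def assert_quantiles_close(got, ref, label, factor=3.0, floor=None):
    """2.5%/97.5% quantiles agree within combined MC error."""
    if floor is None:
        floor = 0.12 * ref["sd"]  # quantile MCSE floors for short chains
    for q in ("q2.5", "q97.5"):
        tol = factor * np.hypot(got.get("mcse_q", got["mcse"]),
                                ref.get("mcse_q", ref["mcse"])) + floor
        diff = abs(got[q] - ref[q])
        assert diff <= tol, (
            f"{label} {q}: {got[q]:.4f} vs reference {ref[q]:.4f}, "
            f"|diff|={diff:.4f} > tol={tol:.4f}"
        )
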