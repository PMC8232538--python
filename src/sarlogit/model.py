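"""Bayesian structured additive logistic regression.

``StructuredAdditiveLogit`` is the model object (built from a respondent
DataFrame, a region graph and a :class:`~sarlogit.design.ModelSpec`);
``fit`` runs a blocked Gibbs sampler with Pólya-Gamma augmentation and
returns a :class:`~sarlogit.results.StructuredAdditiveLogitResults`.

Sampler outline, per iteration:

1. omega_i ~ PG(1, eta_i) — exact augmentation of the logistic likelihood,
   after which every latent block is conditionally Gaussian.
2. Gaussian block updates (fixed effects; each smooth's spline
   coefficients under the RW2 precision K/tau_j^2; the spatial field under
   the ICAR precision Q/tau_s^2; household and community intercepts).
   Sum-to-zero constraints on the spatial field (over regions) and on each
   smooth (over observations) are imposed by conditioning-by-kriging:
   the unconstrained block draw is corrected after sampling.
3. Conjugate inverse-Gamma updates for every variance parameter.

The posterior approximation is exact in the Monte Carlo limit (no
truncation or Laplace step), so posterior summaries can be validated
against brute-force references on small instances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, solve_triangular

from ._pg import polya_gamma
from .design import Design, ModelSpec, build_design
from .graph import RegionGraph


def log_likelihood(eta, y):
    """Bernoulli-logit log likelihood sum_i [y_i eta_i - log(1 + e^{eta_i})].

    Overflow-safe via logaddexp, valid for |eta| well past 700.
    """
    eta = np.asarray(eta, dtype=float)
    y = np.asarray(y, dtype=float)
    if eta.shape != y.shape:
        raise ValueError("eta and y must have the same length")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("y must be binary")
    return float(np.sum(y * eta) - np.sum(np.logaddexp(0.0, eta)))


def _draw_gaussian_block(P, rhs, rng, constraint=None):
    """Draw from N(P^{-1} rhs, P^{-1}), optionally constrained to A x = 0.

    Constraints (a vector, or a matrix with one constraint per row) are
    imposed by conditioning-by-kriging: the unconstrained draw x is
    corrected to x - Sigma A' (A Sigma A')^{-1} A x, an exact draw from the
    conditional distribution given A x = 0.
    """
    try:
        c, low = cho_factor(P, lower=True)
    except np.linalg.LinAlgError:
        P = P + 1e-8 * np.eye(P.shape[0])
        c, low = cho_factor(P, lower=True)
    mean = cho_solve((c, low), rhs)
    z = rng.standard_normal(P.shape[0])
    x = mean + solve_triangular(c, z, lower=True, trans=1)
    if constraint is not None:
        A = np.atleast_2d(constraint)
        SA = cho_solve((c, low), A.T)  # Sigma A'
        x = x - SA @ np.linalg.solve(A @ SA, A @ x)
    return x


def _ig_draw(rng, shape, rate):
    """One inverse-Gamma(shape, rate) draw (rate = the IG scale parameter b)."""
    return 1.0 / rng.gamma(shape, 1.0 / rate)


@dataclass
class EngineSettings:
    """MCMC engine configuration. A seed is always required at fit time."""

    n_iter: int = 4000
    burn: int = 1000
    init_tau2: float = 0.5
    init_sigma2: float = 0.1

    def __post_init__(self):
        if self.burn >= self.n_iter:
            raise ValueError("burn must be smaller than n_iter")


class StructuredAdditiveLogit:
    """Structured additive logistic model for a binary survey outcome.

    Parameters
    ----------
    design : Design
        Assembled matrices (see :func:`sarlogit.design.build_design`).

    Use :meth:`from_dataframe` for the common path.
    """

    def __init__(self, design: Design):
        self.design = design
        self.spec = design.spec

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        spec: ModelSpec,
        graph: RegionGraph | None = None,
    ) -> "StructuredAdditiveLogit":
        return cls(build_design(df, spec, graph))

    # ------------------------------------------------------------------
    def fit(self, seed: int, settings: EngineSettings | None = None, **kwargs):
        """Run the blocked Pólya-Gamma Gibbs sampler.

        Parameters
        ----------
        seed : int
            Required; identical seed and settings give identical results.
        settings : EngineSettings, optional
            Iteration counts and initial values; keyword overrides
            (``n_iter=``, ``burn=``) are accepted directly.
        """
        from .results import StructuredAdditiveLogitResults

        if settings is None:
            settings = EngineSettings(**kwargs)
        elif kwargs:
            raise TypeError("pass either settings or keyword overrides, not both")
        d = self.design
        spec = self.spec
        priors = spec.priors
        rng = np.random.default_rng(seed)
        n = d.n
        y = d.y
        kappa = y - 0.5

        X = d.X
        p = X.shape[1]
        beta = np.zeros(p)
        alphas = [np.zeros(sd.k) for sd in d.smooths]
        tau2_sm = [
            sd.term.fixed_tau2 if sd.term.fixed_tau2 is not None else settings.init_tau2
            for sd in d.smooths
        ]
        has_spatial = d.region_idx is not None
        if has_spatial:
            S = len(d.region_ids)
            f = np.zeros(S)
            Q = d.Q_spatial
            # one sum-to-zero constraint per connected component of >= 2
            # regions; singletons carry an independent N(0, tau^2) effect
            comps = d.spatial_components or [np.arange(S)]
            big = [c for c in comps if len(c) > 1]
            singletons = np.concatenate(
                [c for c in comps if len(c) == 1]
            ).astype(np.int64) if any(len(c) == 1 for c in comps) else np.empty(0, np.int64)
            A_spat = np.zeros((len(big), S))
            for r, c in enumerate(big):
                A_spat[r, c] = 1.0
            diag_single = np.zeros(S)
            diag_single[singletons] = 1.0
            # ICAR rank = S - n_components; each singleton's proper normal
            # prior contributes one more degree of freedom to the IG shape
            rank_spat = (S - len(comps)) + len(singletons)
            tau2_s = (
                spec.spatial.fixed_tau2
                if spec.spatial.fixed_tau2 is not None
                else settings.init_tau2
            )
        has_random = d.house_idx is not None
        if has_random:
            u_h = np.zeros(d.n_households)
            u_c = np.zeros(d.n_communities)
            sig2_h = settings.init_sigma2
            sig2_c = settings.init_sigma2

        eta = np.zeros(n)
        n_keep = settings.n_iter - settings.burn
        draws = {
            "beta": np.empty((n_keep, p)),
            "deviance": np.empty(n_keep),
        }
        for sd in d.smooths:
            draws[f"smooth:{sd.term.covariate}"] = np.empty((n_keep, sd.k))
            draws[f"tau2:{sd.term.covariate}"] = np.empty(n_keep)
        if has_spatial:
            draws["spatial"] = np.empty((n_keep, S))
            draws["tau2_spatial"] = np.empty(n_keep)
        if has_random:
            draws["sigma2_household"] = np.empty(n_keep)
            draws["sigma2_community"] = np.empty(n_keep)
        eta_sum = np.zeros(n)

        lam0 = priors.fixed_precision
        ig_a, ig_b = priors.ig_a, priors.ig_b

        for it in range(settings.n_iter):
            omega = polya_gamma(eta, int(rng.integers(2**31 - 1)))

            # ---- fixed effects -------------------------------------------
            eta -= X @ beta
            P = (X * omega[:, None]).T @ X + lam0 * np.eye(p)
            rhs = X.T @ (kappa - omega * eta)
            beta = _draw_gaussian_block(P, rhs, rng)
            eta += X @ beta

            # ---- smooths -------------------------------------------------
            for j, sd in enumerate(d.smooths):
                B = sd.basis
                eta -= B @ alphas[j]
                P = (B * omega[:, None]).T @ B + sd.penalty / tau2_sm[j]
                rhs = B.T @ (kappa - omega * eta)
                alphas[j] = _draw_gaussian_block(P, rhs, rng, constraint=sd.constraint)
                eta += B @ alphas[j]
                if sd.term.fixed_tau2 is None:
                    quad = alphas[j] @ sd.penalty @ alphas[j]
                    tau2_sm[j] = _ig_draw(
                        rng, ig_a + 0.5 * (sd.k - 2), ig_b + 0.5 * quad
                    )

            # ---- spatial field -------------------------------------------
            if has_spatial:
                eta -= f[d.region_idx]
                w = np.bincount(d.region_idx, weights=omega, minlength=S)
                r = np.bincount(
                    d.region_idx, weights=kappa - omega * eta, minlength=S
                )
                P = np.diag(w + diag_single / tau2_s) + Q / tau2_s
                f = _draw_gaussian_block(
                    P, r, rng, constraint=A_spat if len(A_spat) else None
                )
                eta += f[d.region_idx]
                if spec.spatial.fixed_tau2 is None:
                    quad = f @ Q @ f + f[singletons] @ f[singletons]
                    tau2_s = _ig_draw(rng, ig_a + 0.5 * rank_spat, ig_b + 0.5 * quad)

            # ---- household / community intercepts ------------------------
            if has_random:
                eta -= u_h[d.house_idx]
                w = np.bincount(d.house_idx, weights=omega, minlength=d.n_households)
                r = np.bincount(
                    d.house_idx, weights=kappa - omega * eta, minlength=d.n_households
                )
                prec = w + 1.0 / sig2_h
                u_h = r / prec + rng.standard_normal(d.n_households) / np.sqrt(prec)
                eta += u_h[d.house_idx]
                sig2_h = _ig_draw(
                    rng, ig_a + 0.5 * d.n_households, ig_b + 0.5 * (u_h @ u_h)
                )

                eta -= u_c[d.comm_idx]
                w = np.bincount(d.comm_idx, weights=omega, minlength=d.n_communities)
                r = np.bincount(
                    d.comm_idx, weights=kappa - omega * eta, minlength=d.n_communities
                )
                prec = w + 1.0 / sig2_c
                u_c = r / prec + rng.standard_normal(d.n_communities) / np.sqrt(prec)
                eta += u_c[d.comm_idx]
                sig2_c = _ig_draw(
                    rng, ig_a + 0.5 * d.n_communities, ig_b + 0.5 * (u_c @ u_c)
                )

            # ---- record --------------------------------------------------
            if it >= settings.burn:
                t = it - settings.burn
                draws["beta"][t] = beta
                draws["deviance"][t] = -2.0 * log_likelihood(eta, y)
                for j, sd in enumerate(d.smooths):
                    draws[f"smooth:{sd.term.covariate}"][t] = alphas[j]
                    draws[f"tau2:{sd.term.covariate}"][t] = tau2_sm[j]
                if has_spatial:
                    draws["spatial"][t] = f
                    draws["tau2_spatial"][t] = tau2_s
                if has_random:
                    draws["sigma2_household"][t] = sig2_h
                    draws["sigma2_community"][t] = sig2_c
                eta_sum += eta

        return StructuredAdditiveLogitResults(
            design=d,
            draws=draws,
            eta_mean=eta_sum / n_keep,
            seed=seed,
            settings=settings,
        )
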