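"""Posterior results of the structured additive logistic model.

``StructuredAdditiveLogitResults`` carries the retained MCMC draws per
parameter block and exposes posterior summaries (mean, sd, 2.5% and 97.5%
quantiles), odds-ratio tables, the spatial significance classification,
smooth-effect curves with credible bands, DIC, and convergence diagnostics.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import arviz as az
import numpy as np
import pandas as pd

from .design import Design
from .model import EngineSettings


def summarize_draws(draws: np.ndarray, names=None) -> pd.DataFrame:
    """Posterior mean, sd and central 95% interval per column of ``draws``."""
    draws = np.atleast_2d(np.asarray(draws, dtype=float))
    if draws.shape[0] == 1 and names is not None and len(names) == 1:
        draws = draws.T
    q = np.quantile(draws, [0.025, 0.975], axis=0)
    out = pd.DataFrame(
        {
            "mean": draws.mean(axis=0),
            "sd": draws.std(axis=0, ddof=1),
            "q2.5": q[0],
            "q97.5": q[1],
        }
    )
    if names is not None:
        out.index = pd.Index(names, name="parameter")
    return out


def posterior_transform_or(coef_draws: np.ndarray, names=None) -> pd.DataFrame:
    """Odds-ratio summaries by exponentiating posterior coefficient draws.

    Quantiles commute with the monotone exp transform; the posterior mean
    does not, which is why draws (not coefficient summaries) are required:
    the reported OR mean is the mean of the exponentiated draws.
    """
    return summarize_draws(np.exp(np.asarray(coef_draws, dtype=float)), names)


@dataclass
class StructuredAdditiveLogitResults:
    """Posterior summaries and draws for one fitted model."""

    design: Design
    draws: dict
    eta_mean: np.ndarray
    seed: int
    settings: EngineSettings

    # ------------------------------------------------------------------
    @property
    def spec(self):
        return self.design.spec

    @property
    def model_label(self) -> str:
        return self.spec.level

    @property
    def n_draws(self) -> int:
        return self.draws["beta"].shape[0]

    def fingerprint(self) -> str:
        return self.design.fingerprint()

    # ------------------------------------------------------------------
    def fixed_summary(self) -> pd.DataFrame:
        """Posterior summaries of the intercept and linear coefficients."""
        return summarize_draws(self.draws["beta"], self.design.fixed_labels)

    def or_summary(self) -> pd.DataFrame:
        """Posterior odds-ratio summaries (mean of exponentiated draws)."""
        return posterior_transform_or(self.draws["beta"], self.design.fixed_labels)

    def spatial_summary(self) -> pd.DataFrame:
        """Posterior summaries of the spatial field, one row per region."""
        if "spatial" not in self.draws:
            raise ValueError("model has no spatial term")
        return summarize_draws(self.draws["spatial"], list(self.design.region_ids))

    def variance_summary(self) -> pd.DataFrame:
        """Posterior summaries of every variance parameter (tau^2 scale)."""
        rows, names = [], []
        for key in self.draws:
            if key.startswith("tau2") or key.startswith("sigma2"):
                rows.append(self.draws[key])
                names.append(key)
        if not rows:
            return pd.DataFrame(columns=["mean", "sd", "q2.5", "q97.5"])
        return summarize_draws(np.column_stack(rows), names)

    def smooth_curve(self, covariate: str, num: int = 101) -> pd.DataFrame:
        """Posterior mean curve and 95% band of one smooth on a grid."""
        key = f"smooth:{covariate}"
        if key not in self.draws:
            raise ValueError(f"covariate {covariate!r} is not modeled smoothly")
        sd = next(s for s in self.design.smooths if s.term.covariate == covariate)
        grid = sd.grid(num)
        curves = self.draws[key] @ sd.basis_at(grid).T  # (T, num)
        q = np.quantile(curves, [0.025, 0.975], axis=0)
        return pd.DataFrame(
            {
                "grid": grid,
                "mean": curves.mean(axis=0),
                "lower": q[0],
                "upper": q[1],
            }
        )

    def smooth_at_observations(self, covariate: str) -> np.ndarray:
        """Posterior draws of the smooth evaluated at the observed values."""
        key = f"smooth:{covariate}"
        if key not in self.draws:
            raise ValueError(f"covariate {covariate!r} is not modeled smoothly")
        sd = next(s for s in self.design.smooths if s.term.covariate == covariate)
        return self.draws[key] @ sd.basis.T

    # ------------------------------------------------------------------
    def dic(self):
        from .selection import dic

        return dic(self)

    def classify_regions(self) -> pd.DataFrame:
        from .reporting import classify_regions

        return classify_regions(self)

    def or_table(self) -> pd.DataFrame:
        from .reporting import or_table

        return or_table(self)

    # ------------------------------------------------------------------
    def diagnostics(self) -> dict:
        """Effective sample sizes; flags (never silences) poor mixing."""
        ess = {}
        beta = self.draws["beta"]
        for i, lab in enumerate(self.design.fixed_labels):
            ess[f"beta:{lab}"] = float(az.ess(beta[None, :, i]))
        ess["deviance"] = float(az.ess(self.draws["deviance"][None, :]))
        min_ess = min(ess.values())
        return {
            "ess": ess,
            "min_ess": min_ess,
            "converged": bool(min_ess >= 100.0),
            "n_draws": self.n_draws,
        }

    def summary(self) -> str:
        """Human-readable posterior summary table."""
        diag = self.diagnostics()
        lines = [
            "Structured additive logistic regression "
            f"(model {self.model_label}, n={self.design.n})",
            f"posterior draws: {self.n_draws} "
            f"(iterations {self.settings.n_iter}, burn-in {self.settings.burn}, "
            f"seed {self.seed})",
            f"min effective sample size: {diag['min_ess']:.0f}"
            + ("" if diag["converged"] else "  [WARNING: poor mixing]"),
            "",
            "Fixed effects (logit scale):",
            self.fixed_summary().round(4).to_string(),
        ]
        var = self.variance_summary()
        if len(var):
            lines += ["", "Variance parameters:", var.round(4).to_string()]
        if "spatial" in self.draws:
            sp = self.spatial_summary()
            lines += [
                "",
                f"Spatial field over {len(sp)} regions: "
                f"posterior means in [{sp['mean'].min():.3f}, {sp['mean'].max():.3f}], "
                f"sum {sp['mean'].sum():.2e}",
            ]
        d = self.dic()
        lines += [
            "",
            f"DIC: {d.dic:.2f}  (Dbar {d.dbar:.2f}, Dhat {d.dhat:.2f}, pD {d.pd:.2f})",
        ]
        return "\n".join(lines)

    # ------------------------------------------------------------------
    def save(self, outdir: str) -> None:
        """Write per-block summary CSVs plus a run-metadata record.

        The written files fully determine every report (odds-ratio table,
        significance map, smooth curves), so reporting is a pure function
        of this directory.
        """
        os.makedirs(outdir, exist_ok=True)
        self.fixed_summary().to_csv(os.path.join(outdir, "fixed_summary.csv"))
        self.or_summary().to_csv(os.path.join(outdir, "or_summary.csv"))
        var = self.variance_summary()
        if len(var):
            var.to_csv(os.path.join(outdir, "variance_summary.csv"))
        if "spatial" in self.draws:
            self.spatial_summary().to_csv(os.path.join(outdir, "spatial_summary.csv"))
        for sd in self.design.smooths:
            cov = sd.term.covariate
            self.smooth_curve(cov).to_csv(
                os.path.join(outdir, f"smooth_{cov}.csv"), index=False
            )
        d = self.dic()
        pd.DataFrame(
            [
                {
                    "model": d.model,
                    "dbar": d.dbar,
                    "dhat": d.dhat,
                    "pd": d.pd,
                    "dic": d.dic,
                }
            ]
        ).to_csv(os.path.join(outdir, "dic.csv"), index=False)
        diag = self.diagnostics()
        meta = {
            "model": self.model_label,
            "n": int(self.design.n),
            "seed": int(self.seed),
            "n_iter": int(self.settings.n_iter),
            "burn": int(self.settings.burn),
            "fingerprint": self.fingerprint(),
            "min_ess": diag["min_ess"],
            "converged": diag["converged"],
            "fixed_covariates": {k: list(v) for k, v in self.spec.fixed.items()},
            "references": {
                k: self.spec.reference_of(k) for k in self.spec.fixed
            },
        }
        with open(os.path.join(outdir, "run_metadata.json"), "w") as fh:
            json.dump(meta, fh, indent=2, sort_keys=True)
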