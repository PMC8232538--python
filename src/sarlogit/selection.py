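"""Deviance information criterion and model-ladder comparison.

DIC = Dbar + pD with Dbar the posterior mean deviance, Dhat the deviance at
the posterior mean of the linear predictor, and pD = Dbar - Dhat the
effective number of parameters. Dhat is evaluated at the posterior mean of
eta (not of the parameters): this is well defined under the sum-to-zero
constraints and is the usual plug-in for latent Gaussian models; DIC
variants differ in this choice, so it is stated prominently here.
Lower DIC is better; ties are broken by the smaller pD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import log_likelihood


def deviance(eta, y) -> float:
    """Bernoulli deviance -2 * log_likelihood(eta, y)."""
    return -2.0 * log_likelihood(eta, y)


@dataclass(frozen=True)
class DICResult:
    model: str
    dbar: float
    dhat: float
    pd: float
    dic: float
    fingerprint: str = ""

    def __post_init__(self):
        if not np.isfinite(self.pd):
            raise ValueError("pD must be finite")


def dic(results) -> DICResult:
    """DIC of a fitted model from its deviance draws and posterior-mean eta."""
    dev = np.asarray(results.draws.get("deviance"))
    if dev is None or dev.size == 0:
        raise ValueError("fitted model carries no deviance draws")
    dbar = float(dev.mean())
    dhat = deviance(results.eta_mean, results.design.y)
    pd_ = dbar - dhat
    return DICResult(
        model=results.model_label,
        dbar=dbar,
        dhat=dhat,
        pd=pd_,
        dic=dbar + pd_,
        fingerprint=results.fingerprint(),
    )


def compare_models(results: list, group: str = "all") -> pd.DataFrame:
    """Rank >= 2 models fitted to identical data by ascending DIC.

    Accepts fitted results or DICResult objects; raises if the data
    fingerprints differ (models must be compared on the same data).
    Ties on DIC are broken by the smaller effective parameter count pD.
    """
    if len(results) < 2:
        raise ValueError("need at least two models to compare")
    dics = [r if isinstance(r, DICResult) else dic(r) for r in results]
    prints = {d.fingerprint for d in dics if d.fingerprint}
    if len(prints) > 1:
        raise ValueError("models were fitted to different data (fingerprints differ)")
    order = sorted(range(len(dics)), key=lambda i: (dics[i].dic, dics[i].pd))
    rows = []
    for rank, i in enumerate(order):
        d = dics[i]
        rows.append(
            {
                "group": group,
                "model": d.model,
                "diagnostic": "DIC",
                "value": d.dic,
                "dbar": d.dbar,
                "dhat": d.dhat,
                "pd": d.pd,
                "rank": rank + 1,
                "best": rank == 0,
            }
        )
    return pd.DataFrame(rows)
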