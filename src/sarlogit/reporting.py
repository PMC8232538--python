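"""Report surfaces: odds-ratio table, spatial significance map, smooth curves.

The spatial classification follows the three-colour map convention: a
region is "higher" when the 95% credible interval of its spatial effect
lies entirely above zero, "lower" when entirely below, and
"not_significant" otherwise. Judging significance on the effect's own
(logit) scale is equivalent to the odds-ratio scale (interval excluding 1).
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd


def classify_interval(lower: float, upper: float) -> str:
    if lower > 0:
        return "higher"
    if upper < 0:
        return "lower"
    return "not_significant"


def classify_regions(results) -> pd.DataFrame:
    """Three-way significance classification per region (Fig-1-style map data).

    Returns one row per region with the posterior mean, the 95% interval
    and the classification; joinable to any shapefile by region id.
    """
    sp = results.spatial_summary()
    out = sp.copy()
    out["classification"] = [
        classify_interval(lo, hi) for lo, hi in zip(sp["q2.5"], sp["q97.5"])
    ]
    out.index.name = "region"
    return out


def or_table(results) -> pd.DataFrame:
    """Posterior odds-ratio table with explicit reference rows.

    Rows are grouped by covariate; the reference level of each covariate is
    rendered as 1 / 1 / 1, the other levels carry the posterior mean and
    2.5%/97.5% quantiles of the exponentiated coefficient draws.
    """
    ors = results.or_summary()
    spec = results.spec
    rows = [
        {
            "covariate": "intercept",
            "level": "",
            "mean": ors.loc["intercept", "mean"],
            "q2.5": ors.loc["intercept", "q2.5"],
            "q97.5": ors.loc["intercept", "q97.5"],
            "reference": False,
        }
    ]
    for cov, levels in spec.fixed.items():
        ref = spec.reference_of(cov)
        for lev in levels:
            if lev == ref:
                rows.append(
                    {
                        "covariate": cov,
                        "level": lev,
                        "mean": 1.0,
                        "q2.5": 1.0,
                        "q97.5": 1.0,
                        "reference": True,
                    }
                )
            else:
                key = f"{cov}={lev}"
                rows.append(
                    {
                        "covariate": cov,
                        "level": lev,
                        "mean": ors.loc[key, "mean"],
                        "q2.5": ors.loc[key, "q2.5"],
                        "q97.5": ors.loc[key, "q97.5"],
                        "reference": False,
                    }
                )
    return pd.DataFrame(rows)


def smooth_report(results, covariate: str, num: int = 101) -> pd.DataFrame:
    """Grid evaluation of one smooth: posterior mean flanked by 95% bands."""
    curve = results.smooth_curve(covariate, num=num)
    bad = (curve["lower"] > curve["mean"]) | (curve["mean"] > curve["upper"])
    if bad.any():
        raise AssertionError("credible band does not bracket the posterior mean")
    return curve


def write_reports(results, outdir: str) -> dict:
    """Write all report CSVs for one fitted model; returns the file map."""
    os.makedirs(outdir, exist_ok=True)
    files = {}
    path = os.path.join(outdir, "or_table.csv")
    or_table(results).to_csv(path, index=False)
    files["or_table"] = path
    if "spatial" in results.draws:
        path = os.path.join(outdir, "significance_map.csv")
        classify_regions(results).to_csv(path)
        files["significance_map"] = path
    for sd in results.design.smooths:
        cov = sd.term.covariate
        path = os.path.join(outdir, f"smooth_{cov}.csv")
        smooth_report(results, cov).to_csv(path, index=False)
        files[f"smooth_{cov}"] = path
    return files


def plot_smooth(curve: pd.DataFrame, covariate: str, path: str) -> None:
    """Optional matplotlib rendering of a smooth curve with its band."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curve["grid"], curve["mean"], color="black")
    ax.fill_between(curve["grid"], curve["lower"], curve["upper"], alpha=0.25)
    ax.axhline(0.0, color="grey", lw=0.5)
    ax.set_xlabel(covariate)
    ax.set_ylabel("effect on logit scale")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
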