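"""Inference engine: likelihood, parameter recovery, determinism."""

import numpy as np
import pandas as pd
import pytest

from sarlogit.design import ModelSpec, SpatialTerm, default_model_spec
from sarlogit.graph import make_lattice_graph
from sarlogit.model import EngineSettings, StructuredAdditiveLogit, log_likelihood
from sarlogit.synthetic import SimulationConfig, TruthParams, simulate_dataset


# ---------------------------------------------------------------------------
# log likelihood
# ---------------------------------------------------------------------------

def test_log_likelihood_trivial_values():
    assert log_likelihood(np.array([0.0]), np.array([1.0])) == pytest.approx(-np.log(2))
    assert log_likelihood(np.zeros(2), np.array([1.0, 0.0])) == pytest.approx(
        -2 * np.log(2)
    )


def test_log_likelihood_matches_extended_precision_oracle(rng):
    """Random instance against a 50-digit sympy evaluation."""
    import sympy as sp

    eta = rng.normal(scale=3, size=12)
    y = (rng.random(12) < 0.5).astype(float)
    exact = sum(
        sp.Float(yi, 50) * sp.Float(ei, 50) - sp.log(1 + sp.exp(sp.Float(ei, 50)))
        for ei, yi in zip(eta, y)
    )
    assert log_likelihood(eta, y) == pytest.approx(float(exact), rel=1e-12)


def test_log_likelihood_overflow_safe_and_validates():
    val = log_likelihood(np.array([700.0, -700.0]), np.array([1.0, 0.0]))
    assert np.isfinite(val) and val == pytest.approx(0.0, abs=1e-250)
    with pytest.raises(ValueError, match="length"):
        log_likelihood(np.zeros(3), np.zeros(2))
    with pytest.raises(ValueError, match="binary"):
        log_likelihood(np.zeros(2), np.array([0.5, 1.0]))


# ---------------------------------------------------------------------------
# fit behaviour
# ---------------------------------------------------------------------------

def _intercept_only_frame(n, n_ones, region="r0c0"):
    y = np.zeros(n, int)
    y[:n_ones] = 1
    return pd.DataFrame({"sufficient": y, "region": region})


def test_intercept_posterior_centred_for_balanced_data():
    g = make_lattice_graph(1, 2)
    df = _intercept_only_frame(1000, 500)
    df["region"] = np.where(np.arange(1000) % 2 == 0, "r0c0", "r0c1")
    spec = ModelSpec(level="M1", spatial=SpatialTerm("region", fixed_tau2=1.0))
    res = StructuredAdditiveLogit.from_dataframe(df, spec, g).fit(
        seed=2, n_iter=1500, burn=500
    )
    s = res.fixed_summary().loc["intercept"]
    assert abs(s["mean"]) < 3 * s["sd"]
    assert s["q2.5"] <= s["mean"] <= s["q97.5"]


def test_single_covariate_posterior_recovers_truth():
    """Logistic regression with one binary covariate generated at gamma=0.7."""
    rng = np.random.default_rng(8)
    n = 2000
    x = rng.integers(0, 2, size=n)
    eta = -0.2 + 0.7 * x
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
    df = pd.DataFrame({"sufficient": y, "grp": np.where(x == 1, "b", "a")})
    spec = ModelSpec(level="M2", fixed={"grp": ("a", "b")}, spatial=None)
    res = StructuredAdditiveLogit.from_dataframe(df, spec, None).fit(
        seed=3, n_iter=2000, burn=500
    )
    s = res.fixed_summary().loc["grp=b"]
    assert abs(s["mean"] - 0.7) < 3 * s["sd"]


def test_two_region_spatial_effects_have_opposite_signs():
    """M1 on two regions with strongly different prevalences: the sum-to-zero
    spatial effects must be mirror images with opposite signs."""
    rng = np.random.default_rng(1)
    n = 1200
    region = np.where(np.arange(n) < n // 2, "r0c0", "r0c1")
    p = np.where(region == "r0c0", 0.75, 0.35)
    df = pd.DataFrame({"sufficient": (rng.random(n) < p).astype(int), "region": region})
    spec = ModelSpec(level="M1")
    res = StructuredAdditiveLogit.from_dataframe(df, spec, make_lattice_graph(1, 2)).fit(
        seed=4, n_iter=1500, burn=500
    )
    sp = res.spatial_summary()
    assert sp["mean"].iloc[0] > 0 > sp["mean"].iloc[1]
    assert sp["mean"].sum() == pytest.approx(0.0, abs=1e-10)
    assert np.allclose(res.draws["spatial"].sum(axis=1), 0.0, atol=1e-10)


def test_identical_seed_and_settings_give_identical_summaries(small_dataset):
    df = small_dataset.women.head(600)
    spec = default_model_spec("M2", n_knots=8)
    m = StructuredAdditiveLogit.from_dataframe(df, spec, small_dataset.graph)
    r1 = m.fit(seed=42, n_iter=300, burn=100)
    r2 = m.fit(seed=42, n_iter=300, burn=100)
    pd.testing.assert_frame_equal(r1.fixed_summary(), r2.fixed_summary())
    assert np.array_equal(r1.draws["deviance"], r2.draws["deviance"])
    r3 = m.fit(seed=43, n_iter=300, burn=100)
    assert not np.array_equal(r1.draws["beta"], r3.draws["beta"])


def test_quantiles_bracket_mean_everywhere(small_dataset):
    df = small_dataset.women.head(800)
    spec = default_model_spec("M3", n_knots=8)
    res = StructuredAdditiveLogit.from_dataframe(df, spec, small_dataset.graph).fit(
        seed=5, n_iter=400, burn=150
    )
    for table in (res.fixed_summary(), res.spatial_summary(), res.variance_summary()):
        assert (table["q2.5"] <= table["mean"] + 1e-12).all()
        assert (table["mean"] <= table["q97.5"] + 1e-12).all()


def test_vague_prior_insensitivity():
    """Doubling the fixed-effect prior variance moves posterior means by
    far less than the inferential scale at n=5000."""
    from sarlogit.design import PriorConfig

    rng = np.random.default_rng(6)
    n = 5000
    x = rng.integers(0, 2, size=n)
    y = (rng.random(n) < 1 / (1 + np.exp(-(0.1 + 0.5 * x)))).astype(int)
    df = pd.DataFrame({"sufficient": y, "grp": np.where(x == 1, "b", "a")})
    means = {}
    for label, prec in (("base", 1e-6), ("half", 5e-7)):
        spec = ModelSpec(
            level="M2",
            fixed={"grp": ("a", "b")},
            spatial=None,
            priors=PriorConfig(fixed_precision=prec),
        )
        res = StructuredAdditiveLogit.from_dataframe(df, spec, None).fit(
            seed=7, n_iter=2500, burn=500
        )
        means[label] = res.fixed_summary()["mean"]
    assert np.all(np.abs(means["base"] - means["half"]) < 0.01)


def test_diagnostics_flag_never_silent(small_dataset):
    """A very short chain must carry an explicit non-convergence flag."""
    df = small_dataset.women.head(400)
    spec = default_model_spec("M3", n_knots=8)
    res = StructuredAdditiveLogit.from_dataframe(df, spec, small_dataset.graph).fit(
        seed=8, n_iter=60, burn=20
    )
    diag = res.diagnostics()
    assert "min_ess" in diag and "converged" in diag
    assert diag["converged"] in (True, False)


def test_disconnected_graph_constrained_per_component():
    """On a disconnected region graph the sum-to-zero constraint applies
    per connected component, and an isolated region gets an independent
    zero-mean effect rather than being pinned to zero."""
    from sarlogit.graph import RegionGraph

    g = RegionGraph(
        ("a", "b", "c", "d", "e", "f"),
        {"a": ("b",), "b": ("a", "c"), "c": ("b",), "d": ("e",), "e": ("d",), "f": ()},
    )
    rng = np.random.default_rng(0)
    region = rng.choice(list("abcdef"), size=900)
    p = {"a": 0.7, "b": 0.5, "c": 0.35, "d": 0.6, "e": 0.4, "f": 0.55}
    y = (rng.random(900) < np.array([p[r] for r in region])).astype(int)
    df = pd.DataFrame({"sufficient": y, "region": region})
    res = StructuredAdditiveLogit.from_dataframe(df, ModelSpec(level="M1"), g).fit(
        seed=1, n_iter=800, burn=300
    )
    sp = res.draws["spatial"]
    assert np.allclose(sp[:, :3].sum(axis=1), 0.0, atol=1e-10)
    assert np.allclose(sp[:, 3:5].sum(axis=1), 0.0, atol=1e-10)
    # the singleton is not constrained to zero but is shrunk by its prior
    assert sp[:, 5].std() > 0.01


def test_engine_settings_validation():
    with pytest.raises(ValueError):
        EngineSettings(n_iter=100, burn=100)
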