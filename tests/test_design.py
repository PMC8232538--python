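"""Design assembly: dummy coding, B-spline bases, RW2 penalty."""

import numpy as np
import pandas as pd
import pytest

from sarlogit.design import (
    ModelSpec,
    PriorConfig,
    SmoothTerm,
    build_design,
    build_spline_basis,
    default_model_spec,
    encode_fixed,
    rw2_penalty,
)
from sarlogit.graph import make_lattice_graph
from sarlogit.outcome import tabulate_covariates


# ---------------------------------------------------------------------------
# fixed effects
# ---------------------------------------------------------------------------

def test_five_level_covariate_yields_four_indicator_columns():
    df = pd.DataFrame({"wealth": ["poorest", "poorer", "middle", "richer", "richest"]})
    X, labels = encode_fixed(df, {"wealth": ("poorest", "poorer", "middle", "richer", "richest")})
    assert X.shape == (5, 5)  # intercept + 4 indicators
    assert labels[0] == "intercept" and len(labels) == 5
    assert "wealth=poorest" not in labels  # reference level omitted


def test_all_reference_records_give_intercept_only_design():
    df = pd.DataFrame({"residence": ["rural"] * 4})
    X, labels = encode_fixed(df, {"residence": ("rural", "urban")})
    assert np.array_equal(X, np.ones((4, 2)) * [1, 0])


def test_design_column_sums_equal_tabulated_level_counts(small_dataset):
    """Cross-module recount: indicator column sums match the frequency table."""
    df = small_dataset.women
    covs = {"wealth": ("poorest", "poorer", "middle", "richer", "richest")}
    X, labels = encode_fixed(df, covs)
    table = tabulate_covariates(df, covs)
    for j, lab in enumerate(labels):
        if lab == "intercept":
            continue
        level = lab.split("=")[1]
        count = table[table.level == level]["count"].iloc[0]
        assert X[:, j].sum() == count


def test_unseen_level_raises_with_covariate_name():
    df = pd.DataFrame({"residence": ["rural", "peri-urban"]})
    with pytest.raises(ValueError, match="peri-urban"):
        encode_fixed(df, {"residence": ("rural", "urban")})


# ---------------------------------------------------------------------------
# splines
# ---------------------------------------------------------------------------

def test_spline_basis_partition_of_unity(rng):
    z = rng.uniform(15, 49, size=300)
    B, _ = build_spline_basis(z, n_knots=12, degree=3)
    assert B.shape == (300, 14)
    assert np.allclose(B.sum(axis=1), 1.0, atol=1e-10)


def test_degree_zero_basis_is_histogram_indicator():
    z = np.array([0.0, 0.4, 1.1, 2.6, 3.0, 2.9])
    B, _ = build_spline_basis(z, n_knots=4, degree=0)
    assert B.shape == (6, 3)
    assert np.allclose(B.sum(axis=1), 1.0)
    assert set(np.unique(B)) <= {0.0, 1.0}
    # bins [0,1), [1,2), [2,3]
    assert np.array_equal(np.argmax(B, axis=1), [0, 0, 1, 2, 2, 2])


def _deboor(x, t, i, d):
    """Cox-de Boor recursion, written independently of scipy."""
    if d == 0:
        return 1.0 if t[i] <= x < t[i + 1] else 0.0
    left = 0.0
    if t[i + d] != t[i]:
        left = (x - t[i]) / (t[i + d] - t[i]) * _deboor(x, t, i, d - 1)
    right = 0.0
    if t[i + d + 1] != t[i + 1]:
        right = (t[i + d + 1] - x) / (t[i + d + 1] - t[i + 1]) * _deboor(x, t, i + 1, d - 1)
    return left + right


def test_spline_basis_matches_de_boor_recursion_oracle():
    z = np.linspace(0, 10, 50)
    degree = 3
    B, t = build_spline_basis(z, n_knots=8, degree=degree)
    # evaluate at interior knot midpoints (away from edge conventions)
    mids = (t[degree + 1 : -degree - 1] + t[degree + 2 : -degree]) / 2
    Bm, _ = build_spline_basis(np.concatenate([z, mids]), n_knots=8, degree=degree)
    Bm = Bm[len(z):]
    for r, x in enumerate(mids):
        oracle = [_deboor(x, t, i, degree) for i in range(B.shape[1])]
        assert np.allclose(Bm[r], oracle, atol=1e-12)


def test_constant_covariate_rejected():
    with pytest.raises(ValueError, match="linear term"):
        build_spline_basis(np.ones(50), n_knots=10, degree=3)


# ---------------------------------------------------------------------------
# RW2 penalty
# ---------------------------------------------------------------------------

def test_rw2_penalty_k3_exact_matrix():
    K = rw2_penalty(3)
    assert np.array_equal(K, [[1, -2, 1], [-2, 4, -2], [1, -2, 1]])


def test_rw2_penalty_annihilates_constant_and_linear_sequences():
    for k in (3, 7, 20):
        K = rw2_penalty(k)
        assert np.allclose(K @ np.ones(k), 0.0)
        assert np.allclose(K @ np.arange(k, dtype=float), 0.0)
        quad = np.arange(k, dtype=float) ** 2
        assert quad @ K @ quad > 0


@pytest.mark.parametrize("k", [3, 5, 12, 30])
def test_rw2_penalty_rank_is_k_minus_2(k):
    assert np.linalg.matrix_rank(rw2_penalty(k)) == k - 2


def test_rw2_penalty_needs_three_coefficients():
    with pytest.raises(ValueError):
        rw2_penalty(2)


# ---------------------------------------------------------------------------
# spec and assembly
# ---------------------------------------------------------------------------

def test_model_ladder_nesting_flags():
    spec = default_model_spec("M1")
    assert not spec.has_fixed and not spec.has_smooths and not spec.has_random
    spec2 = spec.at_level("M2")
    assert spec2.has_fixed and spec2.has_smooths and not spec2.has_random
    spec3 = spec.at_level("M3")
    assert spec3.has_fixed and spec3.has_smooths and spec3.has_random


def test_spec_validation():
    with pytest.raises(ValueError, match="level"):
        ModelSpec(level="M4")
    with pytest.raises(ValueError, match="reference"):
        ModelSpec(level="M2", fixed={"a": ("x", "y")}, references={"a": "z"})
    with pytest.raises(ValueError):
        PriorConfig(ig_a=-1)


def test_build_design_smooth_constraint_is_basis_column_sums(small_dataset):
    spec = default_model_spec("M2", n_knots=8)
    d = build_design(small_dataset.women, spec, small_dataset.graph)
    for sd in d.smooths:
        assert np.allclose(sd.constraint, sd.basis.sum(axis=0))
        assert sd.penalty.shape == (sd.k, sd.k)


def test_build_design_rejects_region_missing_from_graph(small_dataset):
    df = small_dataset.women.copy()
    df.loc[df.index[0], "region"] = "atlantis"
    spec = default_model_spec("M1")
    with pytest.raises(ValueError, match="atlantis"):
        build_design(df, spec, small_dataset.graph)


def test_intercept_invariance_under_smooth_level_shift(small_dataset):
    """With the sum-to-zero constraint, adding a constant to a smooth and
    subtracting it from the intercept leaves the likelihood unchanged and
    the constrained representation maps back to the same (intercept, smooth)
    decomposition."""
    from sarlogit.model import log_likelihood

    df = small_dataset.women.head(500)
    spec = default_model_spec("M2", n_knots=8)
    d = build_design(df, spec, small_dataset.graph)
    sd = d.smooths[0]
    rng = np.random.default_rng(3)
    alpha = rng.normal(size=sd.k)
    beta0 = 0.4
    c = 0.7
    eta1 = beta0 + sd.basis @ alpha
    # shift the smooth by +c (via the constant coefficient direction),
    # compensate in the intercept
    eta2 = (beta0 - c) + sd.basis @ (alpha + c)  # partition of unity: B(alpha+c)=B alpha+c
    assert np.allclose(eta1, eta2)
    y = d.y[:500]
    assert log_likelihood(eta1, y) == pytest.approx(log_likelihood(eta2, y))
    # the constraint projects both parameterizations to the same smooth
    a = sd.constraint
    proj = lambda v: v - np.ones(sd.k) * (a @ v) / (a @ np.ones(sd.k))
    assert np.allclose(proj(alpha), proj(alpha + c))
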