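"""Design assembly for the structured additive logistic predictor.

The predictor is

    logit p_i = x_i' beta + sum_j f_j(z_ij) + f_s(s_i) + u_household + u_community

with dummy-coded categorical fixed effects, penalized B-spline smooths
f_j carrying a second-order random-walk (RW2) penalty, an ICAR spatial
field f_s on the region graph, and iid Gaussian random intercepts at the
household and community level. This module builds the matrices; the
sampler in :mod:`sarlogit.model` consumes them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

from .graph import RegionGraph, icar_precision


# ---------------------------------------------------------------------------
# specification containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PriorConfig:
    """Priors of the Bayesian structured additive model.

    fixed_precision : prior precision of the vague zero-mean normal on the
        linear coefficients (default 1e-6, i.e. sd = 1000).
    ig_a, ig_b : shape/scale of the weakly informative inverse-Gamma prior
        IG(a, b) shared by every variance parameter tau^2.
    """

    fixed_precision: float = 1e-6
    ig_a: float = 0.001
    ig_b: float = 0.001

    def __post_init__(self):
        if self.fixed_precision <= 0 or self.ig_a <= 0 or self.ig_b <= 0:
            raise ValueError("prior hyperparameters must be positive")


@dataclass(frozen=True)
class SmoothTerm:
    """A penalized B-spline smooth of one metrical covariate.

    ``fixed_tau2`` pins the smoothing variance instead of sampling it
    under the IG hyperprior (useful for validation against references).
    """

    covariate: str
    n_knots: int = 20
    degree: int = 3
    fixed_tau2: float | None = None


@dataclass(frozen=True)
class SpatialTerm:
    """ICAR spatial effect over the units of a region column."""

    region_col: str = "region"
    fixed_tau2: float | None = None


@dataclass(frozen=True)
class ModelSpec:
    """Which terms are active, and their priors.

    The ladder M1 / M2 / M3 is nested by construction:
      M1: intercept + spatial field only (crude geographical variation);
      M2: M1 + categorical fixed effects + nonlinear smooths;
      M3: M2 + household and community random intercepts.
    """

    level: str = "M3"
    fixed: dict = field(default_factory=dict)  # covariate -> tuple of levels
    references: dict = field(default_factory=dict)  # covariate -> reference level
    smooths: tuple = ()
    spatial: SpatialTerm = SpatialTerm()
    household_col: str = "household"
    community_col: str = "cluster"
    priors: PriorConfig = PriorConfig()
    outcome_col: str = "sufficient"

    def __post_init__(self):
        if self.level not in ("M1", "M2", "M3"):
            raise ValueError("level must be one of M1, M2, M3")
        for cov, ref in self.references.items():
            if cov not in self.fixed:
                raise ValueError(f"reference for unknown covariate {cov!r}")
            if ref not in self.fixed[cov]:
                raise ValueError(f"reference {ref!r} not a level of {cov!r}")

    @property
    def has_fixed(self) -> bool:
        return self.level in ("M2", "M3") and bool(self.fixed)

    @property
    def has_smooths(self) -> bool:
        return self.level in ("M2", "M3") and bool(self.smooths)

    @property
    def has_random(self) -> bool:
        return self.level == "M3"

    def at_level(self, level: str) -> "ModelSpec":
        """Same covariate/prior configuration at another rung of the ladder."""
        return replace(self, level=level)

    def reference_of(self, covariate: str) -> str:
        if covariate in self.references:
            return self.references[covariate]
        return self.fixed[covariate][0]


#: Covariate level sets of the DHS-like survey table, reference level first
#: (reference choices follow the published odds-ratio table: rural,
#: ever-married, the residual "others" groups, no education, poorest,
#: not working, and "no" for each media channel).
DEFAULT_COVARIATES = {
    "newspaper": ("no", "yes"),
    "television": ("no", "yes"),
    "radio": ("no", "yes"),
    "ethnicity": ("others", "igbo", "yoruba", "hausa_fulani"),
    "religion": ("others", "islam", "christian"),
    "education": ("none", "primary", "secondary", "higher"),
    "wealth": ("poorest", "poorer", "middle", "richer", "richest"),
    "residence": ("rural", "urban"),
    "working": ("not_working", "working"),
    "marital": ("ever_married", "never_married"),
}

DEFAULT_SMOOTH_COVARIATES = ("age", "age_first_birth", "anc_visits")


def default_model_spec(level: str = "M3", n_knots: int = 20, degree: int = 3,
                       priors: "PriorConfig | None" = None) -> "ModelSpec":
    """ModelSpec for the DHS-like survey table at one rung of the M1-M3 ladder."""
    return ModelSpec(
        level=level,
        fixed=dict(DEFAULT_COVARIATES),
        smooths=tuple(
            SmoothTerm(c, n_knots=n_knots, degree=degree)
            for c in DEFAULT_SMOOTH_COVARIATES
        ),
        spatial=SpatialTerm("region"),
        priors=priors or PriorConfig(),
    )


# ---------------------------------------------------------------------------
# fixed effects
# ---------------------------------------------------------------------------

def encode_fixed(df: pd.DataFrame, covariates: dict, references: dict | None = None):
    """Dummy-code categorical covariates with an explicit intercept.

    Parameters
    ----------
    df : DataFrame with one row per respondent.
    covariates : mapping covariate -> ordered sequence of admissible levels.
    references : optional mapping covariate -> reference level
        (default: the first declared level).

    Returns
    -------
    (X, labels) : design matrix (n, 1 + sum_k (L_k - 1)) including the
        intercept column, and the column labels
        ["intercept", "cov=level", ...].
    """
    references = references or {}
    n = len(df)
    cols = [np.ones(n)]
    labels = ["intercept"]
    for cov, levels in covariates.items():
        levels = list(levels)
        ref = references.get(cov, levels[0])
        if ref not in levels:
            raise ValueError(f"reference {ref!r} not among levels of {cov!r}")
        vals = df[cov].to_numpy()
        known = set(levels)
        bad = [v for v in pd.unique(vals) if v not in known]
        if bad:
            where = df.index[df[cov] == bad[0]][0]
            raise ValueError(
                f"unseen level {bad[0]!r} for covariate {cov!r} (first at record {where})"
            )
        for lev in levels:
            if lev == ref:
                continue
            cols.append((vals == lev).astype(float))
            labels.append(f"{cov}={lev}")
    return np.column_stack(cols), labels


# ---------------------------------------------------------------------------
# smooths
# ---------------------------------------------------------------------------

def build_spline_basis(z, n_knots: int = 20, degree: int = 3):
    """B-spline basis on equidistant knots spanning the observed range.

    ``n_knots`` equidistant knots are placed from min(z) to max(z)
    inclusive; boundary knots are repeated ``degree`` times so the basis is
    a partition of unity on the whole range. The basis has
    ``n_knots + degree - 1`` columns.

    Returns (basis, knots) with basis a dense (n, k) array.
    """
    z = np.asarray(z, dtype=float)
    if np.unique(z).size < 4:
        raise ValueError(
            "need at least 4 distinct covariate values for a smooth; "
            "use a linear term for (near-)constant covariates"
        )
    if n_knots < degree + 2:
        raise ValueError("n_knots must be at least degree + 2")
    lo, hi = z.min(), z.max()
    inner = np.linspace(lo, hi, n_knots)
    t = np.concatenate([np.full(degree, lo), inner, np.full(degree, hi)])
    dm = BSpline.design_matrix(z, t, degree, extrapolate=False)
    return np.asarray(dm.todense()), t


def rw2_penalty(k: int) -> np.ndarray:
    """Second-order random-walk penalty K = D2' D2 on k ordered coefficients.

    D2 is the (k-2) x k second-difference operator, so K annihilates
    constant and linear coefficient sequences and has rank k - 2. Under
    the prior, beta_t = 2 beta_{t-1} - beta_{t-2} + u_t with
    u_t ~ N(0, tau^2), i.e. second differences are iid Gaussian.
    """
    if k < 3:
        raise ValueError("RW2 penalty needs at least 3 coefficients")
    d2 = np.diff(np.eye(k), n=2, axis=0)
    return d2.T @ d2


# ---------------------------------------------------------------------------
# assembled design
# ---------------------------------------------------------------------------

@dataclass
class SmoothDesign:
    term: SmoothTerm
    basis: np.ndarray          # (n, k)
    knots: np.ndarray
    penalty: np.ndarray        # (k, k), rank k-2
    constraint: np.ndarray     # column sums: 1'B, enforcing sum_i f(z_i) = 0
    values: np.ndarray         # observed covariate values (for grids)

    @property
    def k(self) -> int:
        return self.basis.shape[1]

    def grid(self, num: int = 101) -> np.ndarray:
        return np.linspace(self.values.min(), self.values.max(), num)

    def basis_at(self, grid) -> np.ndarray:
        dm = BSpline.design_matrix(
            np.clip(grid, self.values.min(), self.values.max()),
            self.knots,
            self.term.degree,
            extrapolate=False,
        )
        return np.asarray(dm.todense())


@dataclass
class Design:
    """Everything the sampler needs, in matrix form."""

    y: np.ndarray
    X: np.ndarray | None
    fixed_labels: list
    smooths: list            # of SmoothDesign
    region_idx: np.ndarray | None
    Q_spatial: np.ndarray | None   # dense ICAR structure matrix
    region_ids: tuple | None
    spatial_components: list | None  # index arrays, one per connected component
    house_idx: np.ndarray | None
    n_households: int
    comm_idx: np.ndarray | None
    n_communities: int
    spec: ModelSpec

    @property
    def n(self) -> int:
        return self.y.shape[0]

    def fingerprint(self) -> str:
        """Hash of the outcome/nesting data, for comparability checks."""
        import hashlib

        h = hashlib.sha256()
        h.update(self.y.tobytes())
        if self.region_idx is not None:
            h.update(self.region_idx.tobytes())
        return h.hexdigest()[:16]


def build_design(df: pd.DataFrame, spec: ModelSpec, graph: RegionGraph | None) -> Design:
    """Assemble the design for one model level from a respondent table."""
    y = df[spec.outcome_col].to_numpy(dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError(f"outcome column {spec.outcome_col!r} must be binary 0/1")

    if spec.has_fixed:
        X, labels = encode_fixed(df, spec.fixed, spec.references)
    else:
        X, labels = np.ones((len(df), 1)), ["intercept"]

    smooths = []
    if spec.has_smooths:
        for term in spec.smooths:
            z = df[term.covariate].to_numpy(dtype=float)
            basis, knots = build_spline_basis(z, term.n_knots, term.degree)
            smooths.append(
                SmoothDesign(
                    term=term,
                    basis=basis,
                    knots=knots,
                    penalty=rw2_penalty(basis.shape[1]),
                    constraint=basis.sum(axis=0),
                    values=z,
                )
            )

    region_idx = Q = region_ids = components = None
    if spec.spatial is not None:
        if graph is None:
            raise ValueError("a RegionGraph is required for the spatial term")
        idx = graph.index_of()
        regions = df[spec.spatial.region_col]
        missing = set(regions.unique()) - set(graph.region_ids)
        if missing:
            raise ValueError(f"regions not in graph: {sorted(missing)}")
        region_idx = regions.map(idx).to_numpy(dtype=np.int64)
        Q = icar_precision(graph).toarray()
        region_ids = graph.region_ids
        # sum-to-zero is applied per connected component; isolated regions
        # instead get an independent zero-mean normal effect with variance
        # tau^2 (a singleton cannot carry a sum-to-zero constraint)
        components = [
            np.array([idx[r] for r in comp], dtype=np.int64)
            for comp in graph.connected_components()
        ]

    house_idx = comm_idx = None
    n_h = n_c = 0
    if spec.has_random:
        house_codes, house_uniq = pd.factorize(df[spec.household_col])
        comm_codes, comm_uniq = pd.factorize(df[spec.community_col])
        house_idx = house_codes.astype(np.int64)
        comm_idx = comm_codes.astype(np.int64)
        n_h, n_c = len(house_uniq), len(comm_uniq)

    return Design(
        y=y,
        X=X,
        fixed_labels=labels,
        smooths=smooths,
        region_idx=region_idx,
        Q_spatial=Q,
        region_ids=region_ids,
        spatial_components=components,
        house_idx=house_idx,
        n_households=n_h,
        comm_idx=comm_idx,
        n_communities=n_c,
        spec=spec,
    )
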