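"""DHS-like synthetic survey data with known ground truth.

The generator emulates the structure of a national women's survey: regions
on a contiguity graph, clusters (communities) nested in regions, households
nested in clusters, categorical socio-demographic covariates with realistic
marginals, metrical covariates (current age, age at first birth, ANC-visit
count), and a binary outcome drawn from the structured additive predictor

    logit p = beta0 + x'gamma + f_age(age) + f_afb(age at first birth)
              + f_anc(ANC visits) + f_s(region) + u_household + u_community

so that every downstream stage (design, inference, model selection,
reporting) can be validated against known effects.

Default covariate marginals follow the published 2018 Nigerian survey
frequencies; default fixed effects are the log odds ratios reported for
the all-women analysis, so the defaults describe the study conditions
rather than arbitrary choices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit, logit

from .graph import RegionGraph, make_lattice_graph, icar_precision, write_neighbor_list
from .outcome import RESPONSE_COLUMNS


def _norm(counts: dict) -> dict:
    total = sum(counts.values())
    return {k: v / total for k, v in counts.items()}


# Level frequencies of the 2018 all-women sample (counts normalised to
# proportions; the newspaper rows total 34,866 in the source against an
# overall N of 34,837 — proportions are taken within each covariate).
DEFAULT_MARGINALS = {
    "residence": _norm({"urban": 14625, "rural": 20212}),
    "marital": _norm({"never_married": 8409, "ever_married": 26427}),
    "religion": _norm({"others": 260, "christian": 17879, "islam": 16698}),
    "ethnicity": _norm(
        {"others": 13301, "hausa_fulani": 11097, "igbo": 5970, "yoruba": 4469}
    ),
    "education": _norm(
        {"none": 11134, "primary": 5289, "secondary": 14417, "higher": 3997}
    ),
    "wealth": _norm(
        {"poorest": 5914, "poorer": 6650, "middle": 7433, "richer": 7742, "richest": 7098}
    ),
    "working": _norm({"not_working": 11733, "working": 23104}),
    "newspaper": _norm({"no": 29122, "yes": 5744}),
    "radio": _norm({"no": 14779, "yes": 20058}),
    "television": _norm({"no": 16499, "yes": 18338}),
    # partner education: no marginals are published for ever-married women;
    # these are plausible shares consistent with the women's own education mix
    "partner_education": {"none": 0.35, "primary": 0.15, "secondary": 0.32, "higher": 0.18},
}

# Age-group shares of the all-women sample: <20 17.9%, 20-29 34.2%,
# 30-39 28.4%, 40+ 19.6%; ages drawn uniformly within the group.
AGE_GROUPS = ((15, 20, 0.179), (20, 30, 0.342), (30, 40, 0.284), (40, 50, 0.196))

# Default fixed effects: log posterior odds ratios of the published
# all-women analysis (reference levels carry 0 by construction).
DEFAULT_GAMMA = {
    "newspaper=yes": float(np.log(0.967)),
    "television=yes": float(np.log(0.818)),
    "radio=yes": float(np.log(0.947)),
    "ethnicity=igbo": float(np.log(1.052)),
    "ethnicity=yoruba": float(np.log(1.159)),
    "ethnicity=hausa_fulani": float(np.log(1.043)),
    "religion=islam": float(np.log(0.789)),
    "religion=christian": float(np.log(0.785)),
    "education=primary": float(np.log(1.035)),
    "education=secondary": float(np.log(1.084)),
    "education=higher": float(np.log(1.371)),
    "wealth=poorer": float(np.log(1.016)),
    "wealth=middle": float(np.log(0.996)),
    "wealth=richer": float(np.log(1.067)),
    "wealth=richest": float(np.log(1.153)),
    "residence=urban": float(np.log(1.061)),
    "working=working": float(np.log(0.873)),
    "marital=never_married": float(np.log(0.799)),
}

DEFAULT_BETA0 = float(np.log(2.242))  # published all-women intercept OR


def default_smooth_age(age):
    """Default truth for the age effect: smooth rise peaking at 35, then a
    drastic decline among older women (asymmetric Gaussian bump, C^1)."""
    age = np.asarray(age, dtype=float)
    if np.any(age < 15) or np.any(age > 49):
        raise ValueError("age must lie in [15, 49]")
    width = np.where(age < 35.0, 10.0, 4.5)
    return 0.8 * np.exp(-((age - 35.0) ** 2) / (2.0 * width**2))


def default_smooth_age_first_birth(afb):
    """Flat at zero below age 20, then increasing (smoothed hinge)."""
    afb = np.asarray(afb, dtype=float)
    return 0.05 * np.log1p(np.exp(2.0 * (afb - 20.0))) / 2.0


def default_smooth_anc(anc):
    """Linearly increasing in the number of antenatal-care visits."""
    return 0.08 * np.asarray(anc, dtype=float)


DEFAULT_SMOOTHS = {
    "age": default_smooth_age,
    "age_first_birth": default_smooth_age_first_birth,
    "anc_visits": default_smooth_anc,
}


def center_over(f, values):
    """Mean-zero version of ``f`` over the realized covariate values."""
    offset = float(np.mean(f(values)))
    return lambda x: f(x) - offset


def sample_icar_field(graph: RegionGraph, tau2: float, seed) -> np.ndarray:
    """Draw one intrinsic-CAR field, constrained to sum to zero.

    The intrinsic prior with precision Q/tau^2 (Q the graph Laplacian) is
    improper; the draw is taken in the (n-1)-dimensional eigenspace
    orthogonal to the constant vector, which both defines a proper
    distribution and enforces the sum-to-zero identifiability constraint.
    """
    if tau2 <= 0:
        raise ValueError("tau2 must be positive")
    if not graph.is_connected():
        raise ValueError(
            "graph is disconnected: draw per connected component with a "
            "sum-to-zero constraint on each component"
        )
    Q = icar_precision(graph).toarray()
    lam, V = np.linalg.eigh(Q)
    # connected graph: exactly one (numerically) zero eigenvalue
    keep = lam > 1e-10
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(int(keep.sum()))
    f = V[:, keep] @ (np.sqrt(tau2 / lam[keep]) * z)
    return f - f.mean()  # exact zero sum (removes rounding residue)


@dataclass
class TruthParams:
    """Ground-truth parameters embedded in a synthetic dataset."""

    beta0: float = DEFAULT_BETA0
    gamma: dict = field(default_factory=lambda: dict(DEFAULT_GAMMA))
    smooths: dict = field(default_factory=lambda: dict(DEFAULT_SMOOTHS))
    tau2_spatial: float = 0.25
    spatial: np.ndarray | None = None  # sampled from the ICAR prior if None
    sd_household: float = 0.3
    sd_community: float = 0.3


@dataclass
class SimulationConfig:
    n_women: int = 5000
    grid_rows: int = 6
    grid_cols: int = 6
    clusters_per_region: int = 8
    marginals: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_MARGINALS.items()})
    truth: TruthParams = field(default_factory=TruthParams)

    def validate(self):
        if self.n_women < 1:
            raise ValueError("n_women must be positive")
        for cov, m in self.marginals.items():
            s = sum(m.values())
            if abs(s - 1.0) > 1e-8:
                raise ValueError(f"marginals for {cov!r} sum to {s}, not 1")
        if self.truth.tau2_spatial <= 0:
            raise ValueError("tau2_spatial must be positive")
        if self.truth.sd_household < 0 or self.truth.sd_community < 0:
            raise ValueError("random-effect sds must be nonnegative")


@dataclass
class SyntheticDataset:
    women: pd.DataFrame
    graph: RegionGraph
    truth: TruthParams
    seed: int
    eta: np.ndarray  # realized linear predictor (for diagnostics)

    def write(self, outdir):
        """Write women.csv, graph.txt and truth.yaml into ``outdir``."""
        import os

        os.makedirs(outdir, exist_ok=True)
        self.women.to_csv(os.path.join(outdir, "women.csv"), index=False)
        write_neighbor_list(self.graph, os.path.join(outdir, "graph.txt"))
        truth = {
            "seed": int(self.seed),
            "beta0": float(self.truth.beta0),
            "gamma": {k: float(v) for k, v in self.truth.gamma.items()},
            "tau2_spatial": float(self.truth.tau2_spatial),
            "sd_household": float(self.truth.sd_household),
            "sd_community": float(self.truth.sd_community),
            "spatial": {
                r: float(v)
                for r, v in zip(self.graph.region_ids, self.truth.spatial)
            },
        }
        with open(os.path.join(outdir, "truth.yaml"), "w") as fh:
            yaml.safe_dump(truth, fh, sort_keys=True)


def _draw_categorical(rng, marginal: dict, n: int) -> np.ndarray:
    levels = list(marginal)
    p = np.array([marginal[lv] for lv in levels])
    return np.array(levels, dtype=object)[rng.choice(len(levels), size=n, p=p)]


def _draw_ages(rng, n: int) -> np.ndarray:
    lows = np.array([g[0] for g in AGE_GROUPS], dtype=float)
    highs = np.array([g[1] for g in AGE_GROUPS], dtype=float)
    p = np.array([g[2] for g in AGE_GROUPS])
    p = p / p.sum()
    g = rng.choice(len(AGE_GROUPS), size=n, p=p)
    return np.floor(lows[g] + rng.random(n) * (highs[g] - lows[g])).clip(15, 49)


def simulate_dataset(config: SimulationConfig | None = None, seed: int = 0) -> SyntheticDataset:
    """Generate one synthetic survey with known ground truth.

    Identical (config, seed) pairs produce bitwise-identical datasets.
    """
    config = config or SimulationConfig()
    config.validate()
    rng = np.random.default_rng(seed)
    n = config.n_women

    graph = make_lattice_graph(config.grid_rows, config.grid_cols)
    truth = config.truth
    if truth.spatial is None:
        spatial = sample_icar_field(
            graph, truth.tau2_spatial, rng.integers(2**31 - 1)
        )
    else:
        spatial = np.asarray(truth.spatial, dtype=float)
        if spatial.shape[0] != graph.n_regions:
            raise ValueError("truth.spatial length must equal the region count")
    truth = TruthParams(
        beta0=truth.beta0,
        gamma=dict(truth.gamma),
        smooths=dict(truth.smooths),
        tau2_spatial=truth.tau2_spatial,
        spatial=spatial,
        sd_household=truth.sd_household,
        sd_community=truth.sd_community,
    )

    # nested geography: region -> cluster -> household
    region_idx = rng.integers(graph.n_regions, size=n)
    regions = np.array(graph.region_ids, dtype=object)[region_idx]
    cluster_no = rng.integers(config.clusters_per_region, size=n)
    clusters = np.array(
        [f"{r}_k{c:03d}" for r, c in zip(regions, cluster_no)], dtype=object
    )
    # households: eligible-women-per-household counts of 1/2/3 (p=.75/.2/.05)
    order = np.argsort(clusters, kind="stable")
    households = np.empty(n, dtype=object)
    h_counter = 0
    i = 0
    while i < len(order):
        j = i
        cl = clusters[order[i]]
        while j < len(order) and clusters[order[j]] == cl:
            j += 1
        k = i
        while k < j:
            size = rng.choice([1, 2, 3], p=[0.75, 0.20, 0.05])
            size = min(size, j - k)
            hid = f"{cl}_h{h_counter:05d}"
            h_counter += 1
            for m in range(size):
                households[order[k + m]] = hid
            k += size
        i = j
    house_codes, house_ids = pd.factorize(households)
    comm_codes, comm_ids = pd.factorize(clusters)

    # covariates
    df = pd.DataFrame({"region": regions, "cluster": clusters, "household": households})
    for cov, marginal in config.marginals.items():
        df[cov] = _draw_categorical(rng, marginal, n)
    age = _draw_ages(rng, n)
    afb = np.clip(np.round(rng.normal(20.0, 4.5, size=n)), 12, None)
    afb = np.minimum(afb, age)
    anc = np.minimum(rng.poisson(4.0, size=n), 16)
    df["age"] = age
    df["age_first_birth"] = afb
    df["anc_visits"] = anc.astype(float)

    # linear predictor per the structured additive model
    eta = np.full(n, truth.beta0)
    for key, coef in truth.gamma.items():
        cov, _, lev = key.partition("=")
        if cov not in df.columns:
            raise ValueError(f"truth effect {key!r} refers to unknown covariate")
        eta += coef * (df[cov].to_numpy() == lev)
    metr = {"age": age, "age_first_birth": afb, "anc_visits": anc}
    for name, f in truth.smooths.items():
        vals = metr[name]
        eta += center_over(f, vals)(vals)
    eta += spatial[region_idx]
    u_h = rng.normal(0.0, truth.sd_household, size=len(house_ids))
    u_c = rng.normal(0.0, truth.sd_community, size=len(comm_ids))
    eta += u_h[house_codes] + u_c[comm_codes]

    y = (rng.random(n) < expit(eta)).astype(int)

    # five response indicators consistent with the composite outcome:
    # sufficient <=> all five are 1
    resp = {c: np.ones(n, dtype=int) for c in RESPONSE_COLUMNS}
    insuff = np.flatnonzero(y == 0)
    partial_p = {
        "mtct_pregnancy": 0.65,
        "mtct_delivery": 0.72,
        "mtct_breastfeeding": 0.88,
        "knows_pmtct_drugs": 0.70,
    }
    for c, p in partial_p.items():
        resp[c][insuff] = (rng.random(insuff.size) < p).astype(int)
    # guarantee at least one "no" among the insufficient
    all_yes = insuff[
        np.all([resp[c][insuff] == 1 for c in partial_p], axis=0)
    ]
    if all_yes.size:
        force = rng.choice(list(partial_p), size=all_yes.size)
        for c in partial_p:
            resp[c][all_yes[force == c]] = 0
    for c in RESPONSE_COLUMNS:
        df[c] = resp[c]
    df["score"] = sum(df[c] for c in RESPONSE_COLUMNS)
    df["sufficient"] = y

    return SyntheticDataset(women=df, graph=graph, truth=truth, seed=seed, eta=eta)


def null_prevalence_config(prevalence: float, **kwargs) -> SimulationConfig:
    """All effects zero; outcome prevalence set through the intercept alone."""
    truth = TruthParams(
        beta0=float(logit(prevalence)),
        gamma={},
        smooths={},
        tau2_spatial=1.0,
        spatial=np.zeros(0),  # replaced below
        sd_household=0.0,
        sd_community=0.0,
    )
    cfg = SimulationConfig(truth=truth, **kwargs)
    truth.spatial = np.zeros(cfg.grid_rows * cfg.grid_cols)
    return cfg
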