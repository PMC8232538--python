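"""Composite "sufficient knowledge of MTCT/PMTCT" outcome and descriptive tables.

The binary outcome is built from five survey questions: ever heard of HIV;
HIV transmissible during pregnancy; during delivery; during breastfeeding;
awareness of drugs that prevent transmission to the baby. Each affirmative
answer scores 1; a respondent scoring 5 of 5 has *sufficient* knowledge,
anything less is insufficient. Respondents missing any of the five answers
are excluded (complete-case rule) and the exclusion is reported, never
silently coerced to "no".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

RESPONSE_COLUMNS = (
    "heard_hiv",
    "mtct_pregnancy",
    "mtct_delivery",
    "mtct_breastfeeding",
    "knows_pmtct_drugs",
)

QUESTION_LABELS = {
    "heard_hiv": "Ever heard HIV and AIDS",
    "mtct_pregnancy": "HIV transmitted during pregnancy",
    "mtct_delivery": "HIV transmitted during delivery",
    "mtct_breastfeeding": "HIV transmitted during breastfeeding",
    "knows_pmtct_drugs": "Knows drugs to avoid transmission to the child",
}


@dataclass(frozen=True)
class KnowledgeScore:
    score: int
    sufficient: int


def round_half_up(x, decimals: int = 1):
    """Decimal rounding with ties away from zero (presentation only)."""
    x = np.asarray(x, dtype=float)
    factor = 10.0**decimals
    return np.floor(x * factor + 0.5) / factor


def percentage(count, denominator) -> float:
    """Share as a percentage rounded half-up to one decimal."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return float(round_half_up(100.0 * count / denominator, 1))


def score_responses(responses) -> KnowledgeScore:
    """Score one respondent's five answers.

    ``responses`` is any mapping with the five RESPONSE_COLUMNS keys; each
    value must be exactly 0 or 1. A missing or NA answer raises — record-level
    exclusion is handled by :func:`filter_complete`.
    """
    total = 0
    for col in RESPONSE_COLUMNS:
        if col not in responses:
            raise ValueError(f"missing response {col!r}; record is incomplete")
        v = responses[col]
        if v is None or (isinstance(v, float) and np.isnan(v)):
            raise ValueError(f"missing response {col!r}; record is incomplete")
        if v not in (0, 1):
            raise ValueError(f"response {col!r} must be 0 or 1, got {v!r}")
        total += int(v)
    return KnowledgeScore(score=total, sufficient=int(total == 5))


def filter_complete(df: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Complete-case filter on the five outcome questions.

    Returns the retained rows and the number dropped; dropped counts are
    also logged so every run records the exclusion.
    """
    missing = [c for c in RESPONSE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing response columns: {missing}")
    block = df[list(RESPONSE_COLUMNS)]
    ok = block.notna().all(axis=1)
    ok &= block.isin((0, 1)).all(axis=1)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("complete-case rule dropped %d of %d records", n_dropped, len(df))
    return df.loc[ok].copy(), n_dropped


def add_outcome(df: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Score all complete records: adds ``score`` and ``sufficient`` columns."""
    kept, n_dropped = filter_complete(df)
    block = kept[list(RESPONSE_COLUMNS)].astype(int)
    kept["score"] = block.sum(axis=1)
    kept["sufficient"] = (kept["score"] == 5).astype(int)
    return kept, n_dropped


def tabulate_knowledge(df: pd.DataFrame) -> pd.DataFrame:
    """Per-question yes/no counts and percentages, plus the sufficient split.

    Operates on complete cases only. Percentages are computed from this
    table's own denominator and rounded half-up to one decimal.
    """
    if len(df) == 0:
        raise ValueError("cannot tabulate an empty record set")
    scored, _ = add_outcome(df)
    n = len(scored)
    if n == 0:
        raise ValueError("no complete cases to tabulate")
    rows = []
    for col in RESPONSE_COLUMNS:
        yes = int(scored[col].sum())
        no = n - yes
        rows.append((QUESTION_LABELS[col], "Yes", yes, percentage(yes, n)))
        rows.append((QUESTION_LABELS[col], "No", no, percentage(no, n)))
    suff = int(scored["sufficient"].sum())
    rows.append(("Knowledge of MTCT and PMTCT", "Sufficient", suff, percentage(suff, n)))
    rows.append(
        ("Knowledge of MTCT and PMTCT", "Insufficient", n - suff, percentage(n - suff, n))
    )
    out = pd.DataFrame(rows, columns=["question", "response", "count", "percent"])
    out.attrs["n"] = n
    return out


def knowledge_table_from_counts(yes_counts: dict, n: int) -> pd.DataFrame:
    """Same layout as :func:`tabulate_knowledge` but from published counts.

    ``yes_counts`` maps question key (or 'sufficient') -> yes count; useful
    for re-deriving percentages printed in a report from its raw counts.
    """
    rows = []
    for key, yes in yes_counts.items():
        label = QUESTION_LABELS.get(key, key)
        rows.append((label, "Yes", yes, percentage(yes, n)))
        rows.append((label, "No", n - yes, percentage(n - yes, n)))
    return pd.DataFrame(rows, columns=["question", "response", "count", "percent"])


def tabulate_covariates(df: pd.DataFrame, covariates: dict) -> pd.DataFrame:
    """Frequency table (count, percent) per level per categorical covariate.

    ``covariates`` maps covariate name -> ordered admissible levels; a value
    outside the declared set raises, naming the offending value.
    """
    if len(df) == 0:
        raise ValueError("cannot tabulate an empty record set")
    rows = []
    for cov, levels in covariates.items():
        vals = df[cov]
        known = set(levels)
        bad = [v for v in vals.unique() if v not in known]
        if bad:
            raise ValueError(f"unknown level {bad[0]!r} for covariate {cov!r}")
        denom = len(vals)
        counts = vals.value_counts()
        for lev in levels:
            c = int(counts.get(lev, 0))
            rows.append((cov, lev, c, percentage(c, denom)))
    return pd.DataFrame(rows, columns=["covariate", "level", "count", "percent"])


def covariate_table_from_counts(counts: dict) -> pd.DataFrame:
    """Covariate frequency table from published level counts.

    ``counts`` maps covariate -> {level: count}; each covariate's percentage
    uses its own column total as denominator.
    """
    rows = []
    for cov, level_counts in counts.items():
        denom = sum(level_counts.values())
        for lev, c in level_counts.items():
            rows.append((cov, lev, c, percentage(c, denom)))
    return pd.DataFrame(rows, columns=["covariate", "level", "count", "percent"])
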