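"""Factorial statistics on trajectory AUCs and the network rank score.

The experimental design crosses three binary culturing factors — medium
(NB vs BPI), laminin substrate (mouse vs human) and seeding density (low
vs high) — across multiple plates.  Each well contributes one AUC per
metric; the model is ordinary least squares

    Y = b0 + b1*x1 + b2*x2 + b3*x3 + b4*x1*x2 + b5*x1*x3 + b6*x2*x3 + Z + e

with x1..x3 treatment-coded (reference levels NB / mouse / low, so each
coefficient reads as the effect of switching that factor on) and Z a
categorical plate nuisance covariate.  Benjamini-Hochberg correction is
applied across all main-effect and interaction p-values.

The network score ranks the 8 condition means of the two
network-formation metrics (CDF and neurite coherency), higher mean AUC
getting the higher rank, and sums the two ranks per condition; tied
means share the mean rank.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

from .errors import ParameterError

logger = logging.getLogger(__name__)

FACTORS = ("media", "laminin", "density")
#: Treatment-coding reference level per factor (coded 0); the other level is 1.
REFERENCE_LEVELS = {"media": "NB", "laminin": "mouse", "density": "low"}
OTHER_LEVELS = {"media": "BPI", "laminin": "human", "density": "high"}

EFFECT_TERMS = [
    "media", "laminin", "density",
    "media:laminin", "media:density", "laminin:density",
]


@dataclass
class ModelResult:
    """Fitted interaction model: one row per term plus plate estimates.

    ``terms`` has columns term, beta, se, t, p, p_adj (p_adj only for the
    six effect terms); ``plate_effects`` holds the nuisance estimates.
    """

    terms: pd.DataFrame
    plate_effects: pd.DataFrame
    n_obs: int
    metric: str = ""


def code_design(design: pd.DataFrame) -> pd.DataFrame:
    """Map factor level labels to 0/1 treatment coding (reference = 0)."""
    coded = design.copy()
    for f in FACTORS:
        levels = set(coded[f].unique())
        expected = {REFERENCE_LEVELS[f], OTHER_LEVELS[f]}
        if not levels <= expected:
            raise ParameterError(f"{f}: unknown levels {sorted(levels - expected)}")
        coded[f] = (coded[f] == OTHER_LEVELS[f]).astype(float)
    return coded


def fit_interaction_model(auc_table: pd.DataFrame, design: pd.DataFrame) -> ModelResult:
    """OLS of AUC on three main effects, three 2-way interactions, plate.

    ``auc_table`` needs columns well and auc; ``design`` needs well,
    media, laminin, density, plate (levels as in REFERENCE_LEVELS /
    OTHER_LEVELS, or already coded 0/1).  Requires at least 2 plates.
    A rank-deficient design raises an error naming the collinear terms.
    """
    df = auc_table.merge(design, on="well", how="inner")
    if df.empty:
        raise ParameterError("auc_table: no wells match the design table")
    if df["plate"].nunique() < 2:
        raise ParameterError("plate: need >= 2 plates to estimate plate effects")
    if df[list(FACTORS)].dtypes.eq(object).any():
        df = code_design(df)

    x1, x2, x3 = (df[f].to_numpy(dtype=float) for f in FACTORS)
    X = pd.DataFrame(
        {
            "media": x1, "laminin": x2, "density": x3,
            "media:laminin": x1 * x2, "media:density": x1 * x3, "laminin:density": x2 * x3,
        }
    )
    plates = sorted(df["plate"].unique())
    for p in plates[1:]:  # treatment-coded plate dummies
        X[f"plate[{p}]"] = (df["plate"] == p).astype(float)
    X = sm.add_constant(X)

    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        collinear = _collinear_columns(X)
        raise ParameterError(f"design: rank-deficient model matrix; collinear terms: {collinear}")

    fit = sm.OLS(df["auc"].to_numpy(dtype=float), X).fit()
    terms = pd.DataFrame(
        {
            "term": X.columns,
            "beta": fit.params.to_numpy(),
            "se": fit.bse.to_numpy(),
            "t": fit.tvalues.to_numpy(),
            "p": fit.pvalues.to_numpy(),
        }
    )
    effect_mask = terms["term"].isin(EFFECT_TERMS)
    terms["p_adj"] = np.nan
    terms.loc[effect_mask, "p_adj"] = benjamini_hochberg(terms.loc[effect_mask, "p"].to_numpy())
    plate_effects = terms[terms["term"].str.startswith("plate[")].reset_index(drop=True)
    terms = terms[~terms["term"].str.startswith("plate[")].reset_index(drop=True)
    return ModelResult(terms=terms, plate_effects=plate_effects, n_obs=len(df))


def _collinear_columns(X: pd.DataFrame) -> list[str]:
    """Columns whose removal restores full rank (naive but explicit)."""
    full = np.linalg.matrix_rank(X.to_numpy())
    out = []
    for col in X.columns:
        if np.linalg.matrix_rank(X.drop(columns=[col]).to_numpy()) == full:
            out.append(col)
    return out


def benjamini_hochberg(pvalues: np.ndarray) -> np.ndarray:
    """Step-up false-discovery-rate adjustment with monotonicity.

    Standard BH: sort, multiply p_(i) by m/i, enforce monotone
    non-decreasing adjusted values, cap at 1.  Out-of-range p-values are
    an error.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ParameterError("pvalues: must lie in [0, 1]")
    _, p_adj, _, _ = multipletests(p, method="fdr_bh")
    return p_adj


def network_score(condition_means: pd.DataFrame) -> pd.DataFrame:
    """Summed-rank network score over the condition mean AUCs.

    ``condition_means`` needs columns condition, cdf_auc, coherency_auc
    (one row per condition).  Each metric's means are ranked ascending
    (1 = lowest mean, ties share the mean rank), the two ranks are summed
    per condition, and the summed rank is the overall network score —
    the highest-scoring conditions are the most network-mature.
    Conditions with a missing mean are excluded with a log message.
    """
    required = {"condition", "cdf_auc", "coherency_auc"}
    if not required <= set(condition_means.columns):
        raise ParameterError(f"condition_means: columns {sorted(required)} required")
    df = condition_means.copy()
    missing = df[df[["cdf_auc", "coherency_auc"]].isna().any(axis=1)]
    if len(missing):
        logger.info("network_score: excluding conditions with missing means: %s",
                    list(missing["condition"]))
        df = df.dropna(subset=["cdf_auc", "coherency_auc"]).reset_index(drop=True)
    df["rank_cdf"] = rankdata(df["cdf_auc"], method="average")
    df["rank_coherency"] = rankdata(df["coherency_auc"], method="average")
    df["summed_rank"] = df["rank_cdf"] + df["rank_coherency"]
    df["score"] = df["summed_rank"]
    return df.sort_values("score", ascending=False).reset_index(drop=True)
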