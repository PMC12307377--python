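"""Composite F-value scoring and ranking of accessions.

The comprehensive score of an accession is the contribution-rate-weighted
sum of its retained principal-component scores:

    w_i = rate_i / sum(rate_1..rate_k),      F = sum_i w_i * F_i

so the weights sum to 1 before any rounding (published formulas often round
them to 3 decimals, which makes the printed sum 0.999 - that is a feature of
the rounding, not an error). Accessions are ranked by descending F with
dense ranks; ties share the smaller rank and are ordered by accession id.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AlignmentError, ConfigurationError
from .pca import PCAResult, component_scores, pca, standardize
from .traits import PhenotypeTable, quantitative_abbrevs

logger = logging.getLogger(__name__)


@dataclass
class ScoringConfig:
    """Knobs for the end-to-end scoring pipeline.

    ``normalization``: "zscore" feeds z-scored traits to the component
    coefficients (the convention under which the coefficients are derived);
    "membership" instead feeds mean-centered membership-function values
    u = (x - min)/(max - min). ``weight_rounding`` optionally rounds weights
    to a fixed number of decimals to replicate published formulas.
    """

    normalization: str = "zscore"
    weight_rounding: int | None = None
    top_k: int = 10
    eigenvalue_threshold: float = 0.95
    max_components: int = 10

    def __post_init__(self) -> None:
        if self.normalization not in ("zscore", "membership"):
            raise ConfigurationError(
                f"unknown normalization {self.normalization!r}"
            )
        if self.top_k < 1:
            raise ConfigurationError("top_k must be positive")


def composite_weights(
    contribution_rates, rounding: int | None = None
) -> np.ndarray:
    """Normalize contribution rates (in %) of the retained components to
    weights summing to 1; optionally round."""
    rates = np.asarray(contribution_rates, dtype=float)
    if rates.size == 0:
        raise ConfigurationError("no contribution rates supplied")
    if (rates <= 0).any():
        raise ConfigurationError("contribution rates must be positive")
    w = rates / rates.sum()
    if rounding is not None:
        w = np.round(w, rounding)
    return w


def composite_f(scores, weights) -> np.ndarray:
    """Weighted sum of component scores per accession."""
    s = np.asarray(scores, dtype=float)
    w = np.asarray(weights, dtype=float)
    if s.ndim != 2 or s.shape[1] != w.size:
        raise AlignmentError(
            f"scores have {s.shape[1] if s.ndim == 2 else '?'} columns "
            f"but {w.size} weights were given"
        )
    return s @ w


def rank_accessions(
    f, ids, top_k: int | None = None, extra: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Rank accessions by descending F (dense ranks, id-ordered ties).

    ``extra`` columns (e.g. the quantitative trait values for the top-k
    report) are joined on accession id. ``top_k`` greater than n is clamped
    with a warning.
    """
    f = np.asarray(f, dtype=float)
    ids = list(map(str, ids))
    if len(f) != len(ids):
        raise AlignmentError("f and ids have different lengths")
    df = pd.DataFrame({"accession_id": ids, "F": f})
    df = df.sort_values(
        ["F", "accession_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    # dense ranking: tied F values share the smaller rank
    df["rank"] = df["F"].rank(method="dense", ascending=False).astype(int)
    if extra is not None:
        df = df.merge(extra, on="accession_id", how="left")
    if top_k is not None:
        if top_k > len(df):
            warnings.warn(
                f"top_k={top_k} exceeds n={len(df)}; clamped", stacklevel=2
            )
            top_k = len(df)
        df = df.head(top_k)
    return df


@dataclass
class CompositeScoreResult:
    """Full scoring output: per-accession component scores, weights, F and
    dense rank, plus the fitted PCA."""

    scores: pd.DataFrame  # accession x F1..Fk
    weights: np.ndarray
    composite: pd.Series  # accession -> F
    ranking: pd.DataFrame  # id, F, rank (all accessions, ordered)
    pca: PCAResult

    def top_table(self, table: PhenotypeTable, top_k: int) -> pd.DataFrame:
        """Top-k report carrying the quantitative trait values."""
        quants = quantitative_abbrevs(table.registry)
        extra = table.data[["accession_id", "accession_name", *quants]]
        ranked = rank_accessions(
            self.composite.to_numpy(),
            self.composite.index,
            top_k=top_k,
            extra=extra,
        )
        return ranked[["rank", "accession_id", "accession_name", "F", *quants]]


def _membership(df: pd.DataFrame) -> pd.DataFrame:
    span = df.max() - df.min()
    from .errors import DegenerateTraitError

    dead = span.index[(span == 0) | span.isna()]
    if len(dead):
        raise DegenerateTraitError(
            f"zero-range trait(s): {', '.join(map(str, dead))}"
        )
    u = (df - df.min()) / span
    return u - u.mean()  # centered so scores are comparable across traits


def score_pipeline(
    table: PhenotypeTable, config: ScoringConfig | None = None
) -> CompositeScoreResult:
    """Standardize -> PCA -> component scores -> weights -> F -> ranking.

    Accessions with any missing trait are excluded from scoring (logged);
    the PCA itself uses pairwise-complete correlations.
    """
    config = config or ScoringConfig()
    raw = table.values()
    res = pca(
        raw,
        eigenvalue_threshold=config.eigenvalue_threshold,
        max_components=config.max_components,
    )
    complete = raw.dropna()
    dropped = len(raw) - len(complete)
    if dropped:
        logger.info(
            "%d accession(s) with missing traits excluded from scoring", dropped
        )
    basis = (
        standardize(complete)
        if config.normalization == "zscore"
        else _membership(complete)
    )
    scores = component_scores(basis, res)
    k = res.retained
    weights = composite_weights(
        res.contribution_rates[:k], rounding=config.weight_rounding
    )
    f = composite_f(scores.to_numpy(), weights)
    composite = pd.Series(f, index=scores.index, name="F")
    ranking = rank_accessions(f, list(scores.index))
    return CompositeScoreResult(
        scores=scores,
        weights=weights,
        composite=composite,
        ranking=ranking,
        pca=res,
    )
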