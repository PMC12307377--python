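"""Correlation analysis and correlation-matrix PCA of the trait panel.

All 25 traits - quantitative measurements and integer-coded qualitative
characters alike - are z-scored and analyzed through the Pearson correlation
matrix. PCA is the eigendecomposition of that matrix: for component i with
eigenvalue lambda_i and unit eigenvector v_i,

* the component *loadings* are v_i * sqrt(lambda_i) (trait-component
  correlations),
* the *score coefficients* applied to standardized traits are the unit
  eigenvector elements themselves (loading / sqrt(lambda)), so a component
  score F_i = z . v_i has sample variance lambda_i on the fitting data,
* the *contribution rate* is 100 * lambda_i / p with p the number of traits
  (the trace of a correlation matrix equals p).

Components are retained while lambda exceeds a threshold (default 0.95),
capped at a maximum count (default 10). Eigenvector signs are fixed so the
trait with the largest |loading| in each component loads positively.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateTraitError, InsufficientDataError
from .traits import PhenotypeTable

MIN_PAIRS = 3


def _as_frame(data) -> pd.DataFrame:
    if isinstance(data, PhenotypeTable):
        return data.values()
    return pd.DataFrame(data).astype(float)


def standardize(data) -> pd.DataFrame:
    """Column z-scores: mean 0, sample SD 1 (NaN cells stay NaN).

    Raises DegenerateTraitError naming the first zero-variance trait.
    """
    df = _as_frame(data)
    sd = df.std(ddof=1)
    dead = sd.index[(sd == 0) | sd.isna()]
    if len(dead):
        raise DegenerateTraitError(
            f"zero-variance trait(s): {', '.join(map(str, dead))}"
        )
    return (df - df.mean()) / sd


@dataclass
class CorrelationResult:
    traits: list[str]
    r: pd.DataFrame
    p: pd.DataFrame
    n_pairs: pd.DataFrame

    def to_long(self) -> pd.DataFrame:
        """Long-format (trait_a, trait_b, r, p, n) over the upper triangle."""
        rows = []
        for i, a in enumerate(self.traits):
            for b in self.traits[i + 1 :]:
                rows.append(
                    {
                        "trait_a": a,
                        "trait_b": b,
                        "r": self.r.loc[a, b],
                        "p": self.p.loc[a, b],
                        "n": self.n_pairs.loc[a, b],
                    }
                )
        return pd.DataFrame(rows)


def correlation_matrix(
    data, bh_correct: bool = False
) -> CorrelationResult:
    """Pairwise-complete Pearson correlations with two-sided p-values.

    p-values come from the t transform t = r*sqrt((n-2)/(1-r^2)) with n-2
    degrees of freedom. Cells with fewer than 3 complete pairs are NaN.
    ``bh_correct`` optionally applies Benjamini-Hochberg across the upper
    triangle (off by default; raw p-values are the convention in descriptor
    surveys).
    """
    df = _as_frame(data)
    if len(df) < MIN_PAIRS:
        raise InsufficientDataError("need at least 3 rows for correlations")
    traits = list(df.columns)
    r = df.corr(min_periods=MIN_PAIRS)
    notna = df.notna().astype(int)
    n_pairs = notna.T @ notna
    n = n_pairs.to_numpy(dtype=float)
    rv = r.to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rv * np.sqrt((n - 2) / (1 - rv**2))
        p = 2 * stats.t.sf(np.abs(t), np.maximum(n - 2, 1))
    p = np.where(np.isclose(np.abs(rv), 1.0), 0.0, p)
    p = np.where(n < MIN_PAIRS, np.nan, p)
    np.fill_diagonal(p, 0.0)
    p = pd.DataFrame(p, index=traits, columns=traits)
    if bh_correct:
        from statsmodels.stats.multitest import multipletests

        iu = np.triu_indices(len(traits), k=1)
        raw = p.to_numpy()[iu]
        ok = ~np.isnan(raw)
        adj = raw.copy()
        adj[ok] = multipletests(raw[ok], method="fdr_bh")[1]
        out = p.to_numpy()
        out[iu] = adj
        out[(iu[1], iu[0])] = adj
        p = pd.DataFrame(out, index=traits, columns=traits)
    return CorrelationResult(traits=traits, r=r, p=p, n_pairs=n_pairs)


@dataclass
class PCAResult:
    """Eigenstructure of the trait correlation matrix.

    ``loadings`` and ``score_coefficients`` are trait x component frames
    over *all* p components; ``retained`` says how many pass the retention
    rule. Contribution and cumulative rates are in percent.
    """

    traits: list[str]
    eigenvalues: np.ndarray
    loadings: pd.DataFrame
    score_coefficients: pd.DataFrame
    contribution_rates: np.ndarray
    cumulative_rates: np.ndarray
    retained: int

    @property
    def retained_columns(self) -> list[str]:
        return list(self.loadings.columns[: self.retained])


def pca_from_correlation(
    corr: pd.DataFrame,
    eigenvalue_threshold: float = 0.95,
    max_components: int = 10,
) -> PCAResult:
    """Eigendecompose a trait correlation matrix (see module docstring)."""
    traits = list(corr.columns)
    c = corr.to_numpy(dtype=float)
    if not np.isfinite(c).all():
        raise InsufficientDataError(
            "correlation matrix contains non-finite entries"
        )
    evals, evecs = np.linalg.eigh(c)
    order = np.argsort(evals)[::-1]  # stable for ties: later index first is
    # irrelevant because eigh returns ascending and argsort is stable
    evals = evals[order]
    evecs = evecs[:, order]
    for j in range(len(traits)):
        k = int(np.argmax(np.abs(evecs[:, j])))
        if evecs[k, j] < 0:
            evecs[:, j] = -evecs[:, j]
    p = len(traits)
    cols = [f"PC{i}" for i in range(1, p + 1)]
    loadings = pd.DataFrame(
        evecs * np.sqrt(np.clip(evals, 0, None)), index=traits, columns=cols
    )
    coeffs = pd.DataFrame(evecs, index=traits, columns=cols)
    rates = 100.0 * evals / p
    retained = int(min(np.sum(evals > eigenvalue_threshold), max_components))
    return PCAResult(
        traits=traits,
        eigenvalues=evals,
        loadings=loadings,
        score_coefficients=coeffs,
        contribution_rates=rates,
        cumulative_rates=np.cumsum(rates),
        retained=max(retained, 1),
    )


def pca(
    data,
    eigenvalue_threshold: float = 0.95,
    max_components: int = 10,
) -> PCAResult:
    """PCA of the trait correlation matrix of ``data`` (table, frame or z)."""
    df = _as_frame(data)
    sd = df.std(ddof=1)
    dead = sd.index[(sd == 0) | sd.isna()]
    if len(dead):
        raise DegenerateTraitError(
            f"zero-variance trait(s): {', '.join(map(str, dead))}"
        )
    corr = df.corr(min_periods=MIN_PAIRS)
    return pca_from_correlation(
        corr,
        eigenvalue_threshold=eigenvalue_threshold,
        max_components=max_components,
    )


def component_scores(
    z: pd.DataFrame, result: PCAResult, n_components: int | None = None
) -> pd.DataFrame:
    """Component scores F_i = sum_j coefficient[j, i] * z[., j].

    ``z`` columns must match the PCA trait order exactly. On the fitting
    data each F_i has sample variance equal to its eigenvalue.
    """
    from .traits import align_traits

    align_traits(list(z.columns), result.traits)
    k = n_components if n_components is not None else result.retained
    coeffs = result.score_coefficients.iloc[:, :k]
    scores = z.to_numpy(dtype=float) @ coeffs.to_numpy()
    return pd.DataFrame(
        scores, index=z.index, columns=[f"F{i}" for i in range(1, k + 1)]
    )


def loadings_table(result: PCAResult) -> pd.DataFrame:
    """Retained-component loadings with eigenvalue/contribution/cumulative
    footer rows, mirroring the conventional published layout."""
    cols = result.retained_columns
    body = result.loadings[cols].round(2)
    k = result.retained
    footer = pd.DataFrame(
        [
            result.eigenvalues[:k].round(2),
            result.contribution_rates[:k].round(2),
            result.cumulative_rates[:k].round(2),
        ],
        index=["Eigenvalue", "Contribution rate (%)", "Cumulative (%)"],
        columns=cols,
    )
    return pd.concat([body, footer])
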