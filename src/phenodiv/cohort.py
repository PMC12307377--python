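"""Seedable synthetic accession panels.

Emulates the marginal phenotype distributions of the 1,558-accession
foxtail millet panel: quantitative traits are drawn from (optionally
correlated) normal distributions with the published means and SDs, hard
truncated to the published observed ranges; qualitative traits are drawn
categorically with the published class frequencies. The generator defines
the study conditions under which the downstream statistics are exercised -
it reproduces marginals (and any injected quantitative correlation), not
year effects, genotype structure, or quantitative-qualitative dependence.

Randomness is organized as one master seed with per-trait substreams
derived from a hash of the trait name, so adding or removing one trait
never perturbs the draws of another.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import reference
from .errors import ConfigurationError
from .traits import (
    MATERIAL_CLASSES,
    PhenotypeTable,
    TraitDescriptor,
    default_registry,
    qualitative_abbrevs,
    quantitative_abbrevs,
)

_MAX_RESAMPLE_ROUNDS = 1000


@dataclass(frozen=True)
class QuantitativeTarget:
    """Target moments and hard range for one quantitative trait."""

    mean: float
    sd: float
    minimum: float
    maximum: float

    def __post_init__(self) -> None:
        if not self.sd > 0:
            raise ConfigurationError(f"sd must be positive, got {self.sd}")
        if not self.minimum < self.maximum:
            raise ConfigurationError("minimum must be below maximum")


def table3_defaults() -> dict[str, QuantitativeTarget]:
    """Published mean/SD/min/max for the 11 quantitative traits."""
    return {
        abbr: QuantitativeTarget(
            row["mean"], row["sd"], row["min"], row["max"]
        )
        for abbr, row in reference.QUANTITATIVE_SUMMARY.items()
    }


def table4_defaults() -> dict[str, np.ndarray]:
    """Published category frequencies for the 14 qualitative traits.

    Counts are normalized by their column sum so every probability vector
    sums to exactly 1 (one published row accounts for 1,557 of the 1,558
    accessions).
    """
    return {
        abbr: np.asarray(counts, dtype=float) / sum(counts)
        for abbr, counts in reference.QUALITATIVE_COUNTS.items()
    }


@dataclass
class CohortSpec:
    """Recipe for one synthetic accession panel.

    ``correlation``, when given, is a symmetric positive semi-definite
    matrix with unit diagonal over the quantitative traits (ordered as in
    ``quantitative_targets``) that couples the underlying normal draws.
    """

    n_accessions: int = reference.PANEL_SIZE
    quantitative_targets: dict[str, QuantitativeTarget] = field(
        default_factory=table3_defaults
    )
    qualitative_targets: dict[str, np.ndarray] = field(
        default_factory=table4_defaults
    )
    correlation: np.ndarray | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_accessions < 1:
            raise ConfigurationError("n_accessions must be positive")
        for abbr, probs in self.qualitative_targets.items():
            p = np.asarray(probs, dtype=float)
            if abs(p.sum() - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"{abbr}: category probabilities sum to {p.sum():.12f}, not 1"
                )
            if (p < 0).any():
                raise ConfigurationError(f"{abbr}: negative category probability")
        if self.correlation is not None:
            c = np.asarray(self.correlation, dtype=float)
            q = len(self.quantitative_targets)
            if c.shape != (q, q):
                raise ConfigurationError(
                    f"correlation must be {q}x{q}, got {c.shape}"
                )
            if not np.allclose(c, c.T, atol=1e-10):
                raise ConfigurationError("correlation matrix is not symmetric")
            if not np.allclose(np.diag(c), 1.0, atol=1e-10):
                raise ConfigurationError("correlation diagonal must be 1")
            if np.linalg.eigvalsh(c).min() < -1e-10:
                raise ConfigurationError(
                    "correlation matrix is not positive semi-definite"
                )


def _matched_parent_params(tgt: QuantitativeTarget) -> tuple[float, float]:
    """Parent normal (mu, sigma) whose [min, max]-truncation has the target
    mean and SD.

    The published mean/SD describe data already confined to the observed
    range, so sampling a plain normal with those moments and truncating
    would systematically shrink the SD (and shift the mean when the range
    is asymmetric). Solving the two-moment system keeps the emitted panel's
    CV on target. Falls back to the naive parameters if the solver fails
    (e.g. a target SD too large to be attainable inside the range).
    """

    def residual(params):
        mu, log_sigma = params
        sigma = float(np.exp(log_sigma))
        a = (tgt.minimum - mu) / sigma
        b = (tgt.maximum - mu) / sigma
        m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
        return [float(m) - tgt.mean, float(np.sqrt(v)) - tgt.sd]

    try:
        sol = optimize.root(
            residual, x0=[tgt.mean, np.log(tgt.sd)], method="hybr"
        )
        mu, sigma = float(sol.x[0]), float(np.exp(sol.x[1]))
        if sol.success and np.max(np.abs(residual(sol.x))) < 1e-6 * tgt.sd:
            return mu, sigma
    except Exception:  # pragma: no cover - solver pathologies
        pass
    return tgt.mean, tgt.sd


def _substream(seed: int, label: str) -> np.random.Generator:
    digest = hashlib.sha256(label.encode()).digest()
    salt = int.from_bytes(digest[:8], "big")
    return np.random.default_rng(np.random.SeedSequence((seed, salt)))


def _truncated_normal(
    rng: np.random.Generator, tgt: QuantitativeTarget, n: int
) -> np.ndarray:
    mu, sigma = _matched_parent_params(tgt)
    x = rng.normal(mu, sigma, size=n)
    for _ in range(_MAX_RESAMPLE_ROUNDS):
        bad = (x < tgt.minimum) | (x > tgt.maximum)
        if not bad.any():
            break
        x[bad] = rng.normal(mu, sigma, size=int(bad.sum()))
    return np.clip(x, tgt.minimum, tgt.maximum)


def _correlated_quantitative(
    spec: CohortSpec, order: list[str]
) -> dict[str, np.ndarray]:
    c = np.asarray(spec.correlation, dtype=float)
    # tiny jitter tolerates PSD matrices that are singular to rounding
    chol = np.linalg.cholesky(c + 1e-12 * np.eye(len(c)))
    rng = _substream(spec.seed, "quantitative-joint")
    z = rng.standard_normal((spec.n_accessions, len(order))) @ chol.T
    out = {}
    for j, abbr in enumerate(order):
        tgt = spec.quantitative_targets[abbr]
        mu, sigma = _matched_parent_params(tgt)
        x = mu + sigma * z[:, j]
        # out-of-range cells are redrawn from the marginal, then clipped
        trait_rng = _substream(spec.seed, f"resample:{abbr}")
        for _ in range(_MAX_RESAMPLE_ROUNDS):
            bad = (x < tgt.minimum) | (x > tgt.maximum)
            if not bad.any():
                break
            x[bad] = trait_rng.normal(mu, sigma, size=int(bad.sum()))
        out[abbr] = np.clip(x, tgt.minimum, tgt.maximum)
    return out


def generate_cohort(
    spec: CohortSpec, registry: list[TraitDescriptor] | None = None
) -> PhenotypeTable:
    """Draw a synthetic panel; deterministic for a fixed spec and seed."""
    spec.validate()
    registry = registry if registry is not None else default_registry()
    n = spec.n_accessions
    quant_order = [
        a for a in quantitative_abbrevs(registry) if a in spec.quantitative_targets
    ]
    qual_order = [
        a for a in qualitative_abbrevs(registry) if a in spec.qualitative_targets
    ]
    used = [
        t
        for t in registry
        if t.abbreviation in spec.quantitative_targets
        or t.abbreviation in spec.qualitative_targets
    ]

    columns: dict[str, np.ndarray] = {}
    if spec.correlation is not None:
        columns.update(_correlated_quantitative(spec, quant_order))
    else:
        for abbr in quant_order:
            columns[abbr] = _truncated_normal(
                _substream(spec.seed, f"quant:{abbr}"),
                spec.quantitative_targets[abbr],
                n,
            )
    for abbr in qual_order:
        probs = np.asarray(spec.qualitative_targets[abbr], dtype=float)
        codes = np.arange(1, len(probs) + 1)
        columns[abbr] = _substream(spec.seed, f"qual:{abbr}").choice(
            codes, size=n, p=probs
        )

    class_probs = np.array(
        [reference.MATERIAL_CLASS_COUNTS[c] for c in MATERIAL_CLASSES], dtype=float
    )
    class_probs /= class_probs.sum()
    material = _substream(spec.seed, "material_class").choice(
        np.array(MATERIAL_CLASSES), size=n, p=class_probs
    )

    width = max(4, len(str(n)))
    ids = [f"ACC{i:0{width}d}" for i in range(1, n + 1)]
    df = pd.DataFrame(
        {
            "accession_id": ids,
            "accession_name": ids,
            "material_class": material,
        }
    )
    for t in used:
        df[t.abbreviation] = columns[t.abbreviation]
    return PhenotypeTable(
        registry=used, data=df, provenance={"seed": spec.seed, "synthetic": True}
    )


def injected_correlation(
    pairs: dict[tuple[str, str], float],
    order: list[str] | None = None,
) -> np.ndarray:
    """Identity correlation over the default quantitative traits with the
    given off-diagonal pairs injected (symmetrically).

    Raises ConfigurationError if the result is not positive semi-definite.
    """
    order = order or list(reference.QUANTITATIVE_SUMMARY)
    idx = {a: i for i, a in enumerate(order)}
    c = np.eye(len(order))
    for (a, b), r in pairs.items():
        c[idx[a], idx[b]] = c[idx[b], idx[a]] = r
    if np.linalg.eigvalsh(c).min() < -1e-10:
        raise ConfigurationError("injected correlations are not jointly PSD")
    return c
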