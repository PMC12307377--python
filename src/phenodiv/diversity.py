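"""Descriptive variability statistics and Shannon-Wiener diversity.

Quantitative traits are summarized by mean, sample SD (n-1 denominator),
range and the coefficient of variation CV = 100*S/mean, and stratified into
10 classes on the mean +/- SD grid before computing the Shannon-Wiener
index H' = -sum(p_i ln p_i). Class 1 collects values <= mean - 2S, class 10
values >= mean + 2S, and the eight interior classes are half-open
[lower, upper) intervals of width 0.5 S, so a value exactly at the mean
falls in class 6. Qualitative traits use their category frequencies
directly for both H' and CV (the CV of the integer codes is how coded
characters are conventionally summarized in germplasm descriptor tables).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, UndefinedStatisticError
from .traits import PhenotypeTable, TraitDescriptor

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DescriptiveStats:
    trait: str
    mean: float
    sd: float
    max: float
    min: float
    range: float
    cv_percent: float
    n: int


@dataclass(frozen=True)
class ClassFrequencyProfile:
    """Class counts, relative frequencies and H' for one trait."""

    trait: str
    class_labels: tuple[int, ...]
    counts: tuple[int, ...]
    relative_frequencies: tuple[float, ...]
    shannon_index: float
    boundaries: tuple[float, ...] = ()

    @property
    def n(self) -> int:
        return int(sum(self.counts))


def _clean(values) -> np.ndarray:
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    return x


def shannon_index(frequencies) -> float:
    """H' = -sum(p ln p) over occupied classes, with 0*ln(0) := 0."""
    p = np.asarray(frequencies, dtype=float)
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def descriptive_stats(values, trait: str = "") -> DescriptiveStats:
    """Mean, sample SD, range and CV (%) of one trait vector."""
    x = _clean(values)
    if x.size < 2:
        raise InsufficientDataError(
            f"{trait or 'trait'}: need >= 2 observations, got {x.size}"
        )
    mean = float(x.mean())
    if mean == 0:
        raise UndefinedStatisticError(f"{trait or 'trait'}: CV undefined at zero mean")
    sd = float(x.std(ddof=1))
    return DescriptiveStats(
        trait=trait,
        mean=mean,
        sd=sd,
        max=float(x.max()),
        min=float(x.min()),
        range=float(x.max() - x.min()),
        cv_percent=100.0 * sd / mean,
        n=int(x.size),
    )


def stratify_ten_classes(values, trait: str = "") -> ClassFrequencyProfile:
    """Bin a quantitative trait into the 10 mean/SD classes and compute H'.

    A zero-SD vector is degenerate: all mass is placed in class 6 (the class
    containing the mean), H' = 0, and a warning is emitted.
    """
    x = _clean(values)
    if x.size < 2:
        raise InsufficientDataError(
            f"{trait or 'trait'}: need >= 2 observations, got {x.size}"
        )
    mean = x.mean()
    sd = x.std(ddof=1)
    if sd == 0:
        warnings.warn(
            f"{trait or 'trait'}: zero SD, degenerate stratification (all mass in one class)",
            stacklevel=2,
        )
        counts = np.zeros(10, dtype=int)
        counts[5] = x.size
        freqs = counts / x.size
        return ClassFrequencyProfile(
            trait=trait,
            class_labels=tuple(range(1, 11)),
            counts=tuple(int(c) for c in counts),
            relative_frequencies=tuple(float(f) for f in freqs),
            shannon_index=0.0,
            boundaries=tuple([float(mean)] * 9),
        )
    boundaries = mean + sd * np.arange(-2.0, 2.01, 0.5)  # 9 cut points
    # interior classes are [lower, upper); the extreme classes are closed
    cls = np.searchsorted(boundaries, x, side="right") + 1
    cls[x <= boundaries[0]] = 1
    cls[x >= boundaries[-1]] = 10
    counts = np.bincount(cls, minlength=11)[1:]
    freqs = counts / x.size
    return ClassFrequencyProfile(
        trait=trait,
        class_labels=tuple(range(1, 11)),
        counts=tuple(int(c) for c in counts),
        relative_frequencies=tuple(float(f) for f in freqs),
        shannon_index=shannon_index(freqs),
        boundaries=tuple(float(b) for b in boundaries),
    )


def qualitative_profile(
    codes, descriptor: TraitDescriptor
) -> ClassFrequencyProfile:
    """Category counts, frequencies and H' for a coded qualitative trait."""
    x = _clean(codes)
    if x.size == 0:
        raise InsufficientDataError(f"{descriptor.abbreviation}: empty code vector")
    allowed = set(descriptor.category_codes)
    observed = set(np.unique(x).astype(int).tolist())
    if not observed <= allowed:
        raise UndefinedStatisticError(
            f"{descriptor.abbreviation}: codes {sorted(observed - allowed)} "
            f"outside allowed set {sorted(allowed)}"
        )
    counts = np.array(
        [int((x == c).sum()) for c in descriptor.category_codes], dtype=int
    )
    freqs = counts / x.size
    return ClassFrequencyProfile(
        trait=descriptor.abbreviation,
        class_labels=descriptor.category_codes,
        counts=tuple(int(c) for c in counts),
        relative_frequencies=tuple(float(f) for f in freqs),
        shannon_index=shannon_index(freqs),
    )


def qualitative_cv(codes, trait: str = "") -> float:
    """CV (%) of the integer codes, sample SD over mean."""
    return descriptive_stats(codes, trait=trait).cv_percent


def profile_from_counts(
    counts, descriptor: TraitDescriptor
) -> ClassFrequencyProfile:
    """Profile reconstructed from per-category counts (descriptor tables
    publish counts, not raw vectors)."""
    codes = np.repeat(descriptor.category_codes, np.asarray(counts, dtype=int))
    return qualitative_profile(codes, descriptor)


def codes_from_counts(counts, descriptor: TraitDescriptor) -> np.ndarray:
    """Expand per-category counts into the implied code vector."""
    return np.repeat(
        descriptor.category_codes, np.asarray(counts, dtype=int)
    ).astype(float)


def diversity_report(
    table: PhenotypeTable,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-trait summaries mirroring the two descriptor-table layouts.

    Returns ``(quantitative, qualitative)`` frames. The quantitative frame
    has one row per quantitative trait with mean/SD/max/min/range/CV/H'
    (H' from the 10-class stratification). The qualitative frame has CV, H'
    and one ``count (pct%)`` cell per category.

    Accessions missing a trait are dropped from that trait's statistics
    (pairwise deletion); the dropped count is logged.
    """
    if table.n == 0:
        raise InsufficientDataError("empty phenotype table")
    quant_rows = []
    qual_rows = []
    for t in table.registry:
        col = table.data[t.abbreviation].astype(float)
        n_missing = int(col.isna().sum())
        if n_missing:
            logger.info(
                "%s: %d accession(s) missing, excluded pairwise", t.abbreviation, n_missing
            )
        x = col.dropna().to_numpy()
        if t.kind == "quantitative":
            d = descriptive_stats(x, trait=t.abbreviation)
            prof = stratify_ten_classes(x, trait=t.abbreviation)
            quant_rows.append(
                {
                    "trait": t.name,
                    "abbreviation": t.abbreviation,
                    "mean": round(d.mean, 2),
                    "sd": round(d.sd, 2),
                    "max": round(d.max, 2),
                    "min": round(d.min, 2),
                    "range": round(d.range, 2),
                    "cv_percent": round(d.cv_percent, 2),
                    "shannon_index": round(prof.shannon_index, 2),
                    "n": d.n,
                }
            )
        else:
            prof = qualitative_profile(x, t)
            cv = qualitative_cv(x, trait=t.abbreviation)
            row = {
                "trait": t.name,
                "abbreviation": t.abbreviation,
                "cv_percent": round(cv, 2),
                "shannon_index": round(prof.shannon_index, 2),
            }
            for code, cnt, frq in zip(
                prof.class_labels, prof.counts, prof.relative_frequencies
            ):
                row[f"class_{code}"] = f"{cnt} ({100 * frq:.2f}%)"
            qual_rows.append(row)
    return pd.DataFrame(quant_rows), pd.DataFrame(qual_rows)
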