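"""Trait registry and accession phenotype table model.

The foxtail millet (*Setaria italica*) descriptor set used throughout the
package comprises 25 traits: 11 quantitative (phenology, plant architecture,
yield components, and CIELAB grain color) and 14 qualitative characters
recorded as small integer codes against a published descriptor list (e.g.
leaf sheath color 1=Green, 2=Red, 3=Violet). Qualitative codes are kept as
integers and treated as numeric downstream, which is the convention under
which coefficients of variation and component-score formulas for coded
traits are defined.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .errors import (
    AlignmentError,
    SchemaError,
    TableParseError,
    ValidationError,
)

logger = logging.getLogger(__name__)

MATERIAL_CLASSES = (
    "landrace",
    "breeding_line",
    "selected_cultivar",
    "genetic_stock",
    "other",
)

#: Non-trait columns of a phenotype table, in order.
META_COLUMNS = ("accession_id", "accession_name", "material_class")


@dataclass(frozen=True)
class TraitDescriptor:
    """Identity, typing and coding of a single phenotypic trait.

    ``category_codes`` must be consecutive positive integers starting at 1
    and is empty for quantitative traits. ``nonnegative`` marks quantitative
    traits whose units forbid negative values (lengths, weights, durations).
    """

    name: str
    abbreviation: str
    kind: str  # "quantitative" | "qualitative"
    units: str = ""
    category_codes: tuple[int, ...] = ()
    category_labels: tuple[str, ...] = ()
    nonnegative: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("quantitative", "qualitative"):
            raise ValidationError(f"unknown trait kind {self.kind!r}")
        if self.kind == "quantitative" and self.category_codes:
            raise ValidationError(
                f"quantitative trait {self.abbreviation} must not define category codes"
            )
        if self.kind == "qualitative":
            expected = tuple(range(1, len(self.category_codes) + 1))
            if self.category_codes != expected:
                raise ValidationError(
                    f"qualitative trait {self.abbreviation}: codes must be "
                    f"consecutive integers starting at 1, got {self.category_codes}"
                )

    @property
    def category_count(self) -> int:
        return len(self.category_codes)


def _quant(name: str, abbr: str, units: str) -> TraitDescriptor:
    return TraitDescriptor(name, abbr, "quantitative", units, nonnegative=True)


def _qual(name: str, abbr: str, labels: tuple[str, ...]) -> TraitDescriptor:
    return TraitDescriptor(
        name,
        abbr,
        "qualitative",
        units="code",
        category_codes=tuple(range(1, len(labels) + 1)),
        category_labels=labels,
    )


def default_registry() -> list[TraitDescriptor]:
    """The standard 25-trait foxtail millet descriptor registry.

    Grain color L*/a*/b* may in principle be negative (a*/b* are signed
    CIELAB axes), so only the length/weight/duration traits are flagged
    nonnegative. Hull color is coded 1-7 (the source descriptor list
    duplicates one code; it is renumbered here so the seven observed classes
    have distinct codes).
    """
    return [
        _quant("seedling-to-spike period", "STC", "d"),
        _quant("growth period", "GP", "d"),
        _quant("main spike length", "MPL", "cm"),
        _quant("main stem length", "MTL", "cm"),
        _quant("stem thickness", "ST", "mm"),
        _quant("single-spike weight", "SSW", "g"),
        _quant("single-spike grain weight", "SGW", "g"),
        _quant("1000-grain weight", "TGW", "g"),
        TraitDescriptor("grain L*", "L", "quantitative", ""),
        TraitDescriptor("grain a*", "a", "quantitative", ""),
        TraitDescriptor("grain b*", "b", "quantitative", ""),
        _qual("leaf sheath color", "LSC", ("Green", "Red", "Violet")),
        _qual("seedling leaf color", "SLC", ("Green", "Yellow-Green")),
        _qual("stargazer color", "SZ", ("Yellow", "Green", "Violet")),
        _qual(
            "spike shape",
            "SS",
            ("Fusiform", "Spikelet style", "Cat's paw style", "Cylindrical style"),
        ),
        _qual("spike elasticity", "SE", ("Compact", "Intermediate", "Relaxed")),
        _qual(
            "spike neck shape", "SNC", ("Erect", "Medium bend", "Hooked bend", "Curved")
        ),
        _qual("seta length", "SL", ("Short", "Very short", "Long", "Very long")),
        _qual("bristle color", "BC", ("Yellow", "Green", "Violet")),
        _qual("anther color", "AC", ("White", "Orange", "Yellow")),
        _qual(
            "hull color",
            "HC",
            ("White", "Orange", "Brown", "Black", "Red", "Yellow", "Cyan"),
        ),
        _qual(
            "seedling leaf shape",
            "SLS",
            ("Semi-erect", "Erect", "Horizontal", "Downslope"),
        ),
        _qual("flowering leaf shape", "FLS", ("Erect", "Horizontal", "Downslope")),
        _qual("tillering character", "TL", ("Strong", "Moderate", "Weak")),
        _qual(
            "lodging resistance",
            "LR",
            ("Weak", "Very weak", "Moderate", "Strong", "Very strong"),
        ),
    ]


def quantitative_abbrevs(registry: list[TraitDescriptor]) -> list[str]:
    return [t.abbreviation for t in registry if t.kind == "quantitative"]


def qualitative_abbrevs(registry: list[TraitDescriptor]) -> list[str]:
    return [t.abbreviation for t in registry if t.kind == "qualitative"]


@dataclass
class PhenotypeTable:
    """Accessions x traits matrix with the registry that validates it.

    ``data`` holds one row per accession with columns
    ``accession_id, accession_name, material_class`` followed by one column
    per registered trait abbreviation. Missing observations are NaN.
    """

    registry: list[TraitDescriptor]
    data: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def trait_abbrevs(self) -> list[str]:
        return [t.abbreviation for t in self.registry]

    def descriptor(self, abbreviation: str) -> TraitDescriptor:
        for t in self.registry:
            if t.abbreviation == abbreviation:
                return t
        raise KeyError(abbreviation)

    def values(self, traits: list[str] | None = None) -> pd.DataFrame:
        """Trait matrix indexed by accession_id."""
        traits = traits if traits is not None else self.trait_abbrevs
        return self.data.set_index("accession_id")[traits].astype(float)

    def validate(self) -> None:
        validate_frame(self.data, self.registry)

    def equals(self, other: "PhenotypeTable") -> bool:
        if [t.abbreviation for t in self.registry] != [
            t.abbreviation for t in other.registry
        ]:
            return False
        a = self.data.reset_index(drop=True)
        b = other.data.reset_index(drop=True)
        if list(a.columns) != list(b.columns) or len(a) != len(b):
            return False
        for c in a.columns:
            if c in META_COLUMNS:
                if not a[c].astype(str).equals(b[c].astype(str)):
                    return False
            else:
                if not np.allclose(
                    a[c].astype(float), b[c].astype(float), equal_nan=True
                ):
                    return False
        return True


def validate_frame(df: pd.DataFrame, registry: list[TraitDescriptor]) -> None:
    """Validate a raw frame against the registry; raise with cell locations."""
    abbrevs = [t.abbreviation for t in registry]
    missing = [c for c in (*META_COLUMNS, *abbrevs) if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    ids = df["accession_id"].astype(str)
    dupes = ids[ids.duplicated()].unique()
    if len(dupes):
        raise ValidationError(f"duplicate accession_id values: {list(dupes)[:5]}")
    bad_class = sorted(set(df["material_class"].astype(str)) - set(MATERIAL_CLASSES))
    if bad_class:
        raise ValidationError(f"unknown material_class values: {bad_class}")
    problems: list[str] = []
    for t in registry:
        col = pd.to_numeric(df[t.abbreviation], errors="coerce")
        raw_missing = df[t.abbreviation].isna()
        unparsed = col.isna() & ~raw_missing
        for idx in df.index[unparsed]:
            problems.append(
                f"row {idx} ({ids.loc[idx]}), column {t.abbreviation}: "
                f"non-numeric value {df.loc[idx, t.abbreviation]!r}"
            )
        present = col.dropna()
        if t.kind == "qualitative":
            allowed = set(t.category_codes)
            bad = present[~present.isin(allowed) | (present != present.round())]
            for idx in bad.index:
                problems.append(
                    f"row {idx} ({ids.loc[idx]}), column {t.abbreviation}: "
                    f"code {df.loc[idx, t.abbreviation]!r} outside allowed set "
                    f"{sorted(allowed)}"
                )
        else:
            if not np.isfinite(present.to_numpy()).all():
                problems.append(f"column {t.abbreviation}: non-finite value(s)")
            if t.nonnegative and (present < 0).any():
                idx = present.index[present < 0][0]
                problems.append(
                    f"row {idx} ({ids.loc[idx]}), column {t.abbreviation}: "
                    f"negative value for a nonnegative trait"
                )
    if problems:
        raise ValidationError("; ".join(problems))


def _resolve_columns(
    columns: list[str], registry: list[TraitDescriptor]
) -> dict[str, str]:
    """Case-insensitive mapping of file header names to canonical names."""
    canonical = {c.lower(): c for c in META_COLUMNS}
    canonical.update({t.abbreviation.lower(): t.abbreviation for t in registry})
    out = {}
    for col in columns:
        key = col.strip().lower()
        if key in canonical:
            out[col] = canonical[key]
    return out


def read_table(
    path,
    registry: list[TraitDescriptor] | None = None,
    delimiter: str | None = None,
) -> PhenotypeTable:
    """Read and validate a delimited phenotype table (comma default, tab accepted)."""
    registry = registry if registry is not None else default_registry()
    if delimiter is None:
        with open(path, "r", encoding="utf-8") as fh:
            header = fh.readline()
        delimiter = "\t" if header.count("\t") > header.count(",") else ","
    try:
        df = pd.read_csv(path, sep=delimiter, dtype=str, encoding="utf-8")
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise TableParseError(f"could not parse {path}: {exc}") from exc
    df = df.rename(columns=_resolve_columns(list(df.columns), registry))
    validate_frame(df, registry)
    abbrevs = [t.abbreviation for t in registry]
    out = df[list(META_COLUMNS)].copy()
    for c in META_COLUMNS:
        out[c] = out[c].astype(str)
    for c in abbrevs:
        out[c] = pd.to_numeric(df[c])
    return PhenotypeTable(registry=registry, data=out)


def write_table(table: PhenotypeTable, path, delimiter: str = ",") -> None:
    """Write a phenotype table as delimited text (UTF-8, header row)."""
    df = table.data.copy()
    for t in table.registry:
        if t.kind == "qualitative":
            df[t.abbreviation] = df[t.abbreviation].astype("Int64")
    df.to_csv(path, sep=delimiter, index=False, encoding="utf-8")


@dataclass
class YearlyObservation:
    """One accession's trait values from a single trial year."""

    accession_id: str
    year: int
    values: dict[str, float]
    accession_name: str | None = None
    material_class: str = "other"


def average_years(
    observations: list[YearlyObservation],
    registry: list[TraitDescriptor] | None = None,
) -> PhenotypeTable:
    """Aggregate multi-year observations into final trait values.

    Quantitative traits take the arithmetic mean over available years.
    Qualitative traits take the modal code; ties are broken by the value
    recorded in the earliest year, making the aggregation deterministic.
    Single-year input passes through unchanged.
    """
    registry = registry if registry is not None else default_registry()
    if not observations:
        raise SchemaError("no observations supplied")
    trait_sets = {frozenset(o.values) for o in observations}
    if len(trait_sets) > 1:
        raise SchemaError("conflicting trait sets across yearly observations")
    trait_set = trait_sets.pop()
    traits = [t for t in registry if t.abbreviation in trait_set]
    by_id: dict[str, list[YearlyObservation]] = {}
    for o in observations:
        by_id.setdefault(o.accession_id, []).append(o)
    rows = []
    for acc_id, obs in by_id.items():
        obs = sorted(obs, key=lambda o: o.year)
        row = {
            "accession_id": acc_id,
            "accession_name": obs[0].accession_name or acc_id,
            "material_class": obs[0].material_class,
        }
        for t in traits:
            vals = [o.values[t.abbreviation] for o in obs]
            if t.kind == "quantitative":
                row[t.abbreviation] = float(np.mean(vals))
            else:
                counts = Counter(vals)
                top = max(counts.values())
                # earliest-year value among the modal codes
                row[t.abbreviation] = next(
                    v for v in vals if counts[v] == top
                )
        rows.append(row)
    df = pd.DataFrame(rows)
    years = sorted({o.year for o in observations})
    return PhenotypeTable(
        registry=traits, data=df, provenance={"years": years}
    )


def save_registry(registry: list[TraitDescriptor], path) -> None:
    """Export a registry as a human-editable YAML document."""
    doc = [
        {
            "name": t.name,
            "abbreviation": t.abbreviation,
            "kind": t.kind,
            "units": t.units,
            "category_labels": list(t.category_labels),
            "nonnegative": t.nonnegative,
        }
        for t in registry
    ]
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False, allow_unicode=True)


def load_registry(path) -> list[TraitDescriptor]:
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    out = []
    for item in doc:
        labels = tuple(item.get("category_labels") or ())
        out.append(
            TraitDescriptor(
                name=item["name"],
                abbreviation=item["abbreviation"],
                kind=item["kind"],
                units=item.get("units", ""),
                category_codes=tuple(range(1, len(labels) + 1)),
                category_labels=labels,
                nonnegative=bool(item.get("nonnegative", False)),
            )
        )
    abbrevs = [t.abbreviation for t in out]
    if len(set(abbrevs)) != len(abbrevs):
        raise SchemaError("duplicate abbreviations in registry file")
    return out


def align_traits(columns: list[str], expected: list[str]) -> None:
    """Raise AlignmentError unless ``columns`` equals ``expected`` in order."""
    if list(columns) != list(expected):
        raise AlignmentError(
            f"trait order mismatch: expected {expected[:5]}..., got {list(columns)[:5]}..."
        )
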