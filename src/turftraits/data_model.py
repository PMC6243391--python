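"""Tabular data contracts for leaf-trait, community and experiment-design tables.

All tables are tidy (long-format) :class:`pandas.DataFrame` objects with a
fixed canonical column set.  The trait table holds one row per leaf x trait so
that leaves with partial trait panels (nutrients are typically measured on a
subset of leaves) need no sentinel values.

This module also applies the two per-row preprocessing steps that precede
every analysis stage: removal of physiologically impossible trait values
(dry-matter content above 1 g/g, specific leaf area outside 5-500 cm2/g,
nitrogen above 6.4 %) and natural-log transformation of the multiplicative
growth traits (leaf area, leaf thickness, leaf dry matter content).
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# --------------------------------------------------------------------------
# Vocabulary
# --------------------------------------------------------------------------

#: The 11 recognised leaf functional traits.  Units: LA cm2, LT mm, LDMC g/g,
#: SLA cm2/g, C/N/P %, CN and NP unitless ratios, d13C and d15N permil.
TRAITS: tuple[str, ...] = (
    "LA", "LT", "LDMC", "SLA", "C", "N", "P", "CN", "NP", "d13C", "d15N",
)

#: Multiplicative growth traits, analysed on the natural-log scale.
MULTIPLICATIVE_TRAITS: frozenset[str] = frozenset({"LA", "LT", "LDMC"})

TREATMENTS: tuple[str, ...] = (
    "control", "local_transplant", "warmed", "cooled", "wild",
)

#: Treatments considered "unmanipulated" for community trait pools and home
#: summaries: wild-collected leaves plus both control plot types (transplanted
#: and untransplanted controls behave identically and are pooled).
UNMANIPULATED_TREATMENTS: frozenset[str] = frozenset(
    {"wild", "control", "local_transplant"}
)

TRAIT_COLUMNS: tuple[str, ...] = (
    "leaf_id", "species", "genus", "family", "order", "site", "plot_id",
    "block", "treatment", "origin_site", "trait", "value",
)
COMMUNITY_COLUMNS: tuple[str, ...] = ("site", "plot_id", "species", "biomass")
DESIGN_COLUMNS: tuple[str, ...] = (
    "site", "block", "plot_id", "treatment", "origin_site",
)
TAXONOMY_COLUMNS: tuple[str, ...] = ("species", "genus", "family", "order")


# --------------------------------------------------------------------------
# Errors
# --------------------------------------------------------------------------

class SchemaError(ValueError):
    """A required column is missing or a table fails structural validation."""


class ParseError(ValueError):
    """A cell could not be parsed as the required type."""


class DomainError(ValueError):
    """A value violates a mathematical domain constraint (e.g. log of <= 0)."""


class DataError(ValueError):
    """The data are structurally valid but unusable for the requested step."""


class InsufficientDataError(DataError):
    """Too few observations for the requested estimate."""


class ConfigError(ValueError):
    """An invalid configuration value or combination."""


# --------------------------------------------------------------------------
# Cleaning rules
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CleaningRules:
    """Thresholds for removing physically unrealistic leaf measurements.

    The bounds are exclusive: a value exactly at a threshold is retained
    (LDMC of exactly 1 g/g, SLA of exactly 5 or 500 cm2/g, N of exactly
    6.4 % all pass).
    """

    ldmc_max: float = 1.0     # g/g
    sla_min: float = 5.0      # cm2/g
    sla_max: float = 500.0    # cm2/g
    n_max: float = 6.4        # %

    def __post_init__(self) -> None:
        if not (self.sla_min < self.sla_max):
            raise ConfigError("sla_min must be < sla_max")
        for name in ("ldmc_max", "sla_min", "sla_max", "n_max"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")


@dataclass(frozen=True)
class CleaningReport:
    n_input: int
    n_removed_by_rule: Mapping[str, int]
    n_retained: int

    def __post_init__(self) -> None:
        if self.n_input != self.n_retained + sum(self.n_removed_by_rule.values()):
            raise ValueError("cleaning report counts are inconsistent")

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_removed_by_rule": dict(self.n_removed_by_rule),
            "n_retained": self.n_retained,
        }


# --------------------------------------------------------------------------
# Validation
# --------------------------------------------------------------------------

def _require_columns(df: pd.DataFrame, required: Iterable[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing required column(s): {', '.join(missing)}")


def validate_trait_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a trait table in place and return it (row order preserved)."""
    _require_columns(df, TRAIT_COLUMNS, "trait table")
    unknown_traits = set(df["trait"]) - set(TRAITS)
    if unknown_traits:
        raise SchemaError(
            f"unknown trait name(s): {sorted(unknown_traits)}; expected one of {TRAITS}"
        )
    unknown_treat = set(df["treatment"]) - set(TREATMENTS)
    if unknown_treat:
        raise SchemaError(f"unknown treatment(s): {sorted(unknown_treat)}")
    values = pd.to_numeric(df["value"], errors="coerce")
    bad = ~np.isfinite(values.to_numpy(dtype=float, na_value=np.nan))
    if bad.any():
        idx = int(np.flatnonzero(bad)[0])
        raise ParseError(f"non-finite or non-numeric trait value in row {idx}")
    df = df.copy()
    df["value"] = values.astype(float)
    moved = df["treatment"].isin(["warmed", "cooled"])
    same = moved & (df["origin_site"] == df["site"])
    if same.any():
        idx = int(np.flatnonzero(same.to_numpy())[0])
        raise SchemaError(
            f"warmed/cooled row {idx} has origin_site equal to site; transplants must move"
        )
    return df


def validate_community_table(df: pd.DataFrame) -> pd.DataFrame:
    _require_columns(df, COMMUNITY_COLUMNS, "community table")
    df = df.copy()
    df["biomass"] = pd.to_numeric(df["biomass"], errors="raise").astype(float)
    if (df["biomass"] < 0).any():
        idx = int(np.flatnonzero((df["biomass"] < 0).to_numpy())[0])
        raise DomainError(f"negative biomass in row {idx}")
    dup = df.duplicated(subset=["site", "plot_id", "species"])
    if dup.any():
        idx = int(np.flatnonzero(dup.to_numpy())[0])
        raise SchemaError(f"duplicate (site, plot_id, species) in row {idx}")
    return df


def validate_design_table(df: pd.DataFrame) -> pd.DataFrame:
    _require_columns(df, DESIGN_COLUMNS, "design table")
    dup = df.duplicated(subset=["plot_id"])
    if dup.any():
        raise SchemaError(
            f"duplicate plot_id(s): {sorted(df.loc[dup, 'plot_id'].unique())}"
        )
    unknown = set(df["treatment"]) - set(TREATMENTS)
    if unknown:
        raise SchemaError(f"unknown treatment(s) in design table: {sorted(unknown)}")
    return df.copy()


# --------------------------------------------------------------------------
# I/O
# --------------------------------------------------------------------------

def _read_csv(path, schema: Mapping[str, str] | None) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if schema:
        df = df.rename(columns=dict(schema))
    return df


def read_trait_table(path, schema: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read and validate a leaf-level trait table from CSV.

    Parameters
    ----------
    path
        CSV file with a header row, UTF-8, "." decimal separator.
    schema
        Optional mapping from file column names to canonical column names
        (``leaf_id, species, genus, family, order, site, plot_id, block,
        treatment, origin_site, trait, value``).
    """
    df = _read_csv(path, schema)
    _require_columns(df, TRAIT_COLUMNS, "trait table")
    raw = df["value"]
    values = pd.to_numeric(raw, errors="coerce")
    bad = values.isna() & (raw.astype(str).str.len() > 0)
    if bad.any():
        idx = int(np.flatnonzero(bad.to_numpy())[0])
        raise ParseError(
            f"could not parse trait value {raw.iloc[idx]!r} in row {idx}"
        )
    df["value"] = values
    return validate_trait_table(df)


def write_trait_table(df: pd.DataFrame, path) -> None:
    df.loc[:, list(TRAIT_COLUMNS)].to_csv(path, index=False)


def read_community_table(path, schema: Mapping[str, str] | None = None) -> pd.DataFrame:
    return validate_community_table(_read_csv(path, schema))


def write_community_table(df: pd.DataFrame, path) -> None:
    df.loc[:, list(COMMUNITY_COLUMNS)].to_csv(path, index=False)


def read_design_table(path, schema: Mapping[str, str] | None = None) -> pd.DataFrame:
    return validate_design_table(_read_csv(path, schema))


def write_design_table(df: pd.DataFrame, path) -> None:
    df.loc[:, list(DESIGN_COLUMNS)].to_csv(path, index=False)


# --------------------------------------------------------------------------
# Cleaning and transformation
# --------------------------------------------------------------------------

def clean_traits(
    df: pd.DataFrame, rules: CleaningRules | None = None
) -> tuple[pd.DataFrame, CleaningReport]:
    """Remove rows with physically unrealistic trait values.

    Rules are applied in the fixed order LDMC, SLA, N; each removed row is
    attributed to the first rule it violates.  Rows of other traits are never
    touched.  Cleaning operates on the original measurement scale and must
    therefore run before :func:`log_transform_multiplicative`.
    """
    rules = rules or CleaningRules()
    trait = df["trait"]
    value = df["value"]
    removed = pd.Series(False, index=df.index)
    counts: dict[str, int] = {}
    rule_masks = [
        ("LDMC", (trait == "LDMC") & (value > rules.ldmc_max)),
        ("SLA", (trait == "SLA") & ((value < rules.sla_min) | (value > rules.sla_max))),
        ("N", (trait == "N") & (value > rules.n_max)),
    ]
    for name, mask in rule_masks:
        hit = mask & ~removed
        counts[name] = int(hit.sum())
        removed |= hit
    retained = df.loc[~removed].copy()
    report = CleaningReport(
        n_input=len(df), n_removed_by_rule=counts, n_retained=len(retained)
    )
    return retained, report


def log_transform_multiplicative(
    df: pd.DataFrame, traits: Iterable[str] = MULTIPLICATIVE_TRAITS
) -> pd.DataFrame:
    """Replace values of the named traits by their natural logarithm.

    The set of transformed traits is recorded in
    ``df.attrs["log_transformed_traits"]``.  Raises :class:`DomainError` if a
    targeted value is not strictly positive.
    """
    traits = set(traits)
    mask = df["trait"].isin(traits)
    nonpos = mask & (df["value"] <= 0)
    if nonpos.any():
        idx = int(np.flatnonzero(nonpos.to_numpy())[0])
        raise DomainError(
            f"non-positive value for multiplicative trait in row {idx}; cannot log transform"
        )
    out = df.copy()
    out.loc[mask, "value"] = np.log(out.loc[mask, "value"])
    already = set(df.attrs.get("log_transformed_traits", ()))
    out.attrs["log_transformed_traits"] = sorted(already | (traits & set(df["trait"])))
    return out


def unmanipulated(df: pd.DataFrame) -> pd.DataFrame:
    """Subset of a trait table under unmanipulated conditions."""
    return df.loc[df["treatment"].isin(UNMANIPULATED_TREATMENTS)]


def taxonomy_from_traits(df: pd.DataFrame) -> pd.DataFrame:
    """Derive a species-level taxonomy table from a trait table."""
    tax = df.loc[:, list(TAXONOMY_COLUMNS)].drop_duplicates("species")
    return tax.reset_index(drop=True)


def report_to_frame(report: CleaningReport) -> pd.DataFrame:
    rows = [("input", report.n_input)]
    rows += [(f"removed_{k}", v) for k, v in report.n_removed_by_rule.items()]
    rows.append(("retained", report.n_retained))
    return pd.DataFrame(rows, columns=["quantity", "count"])


def asdict(obj) -> dict:
    return dataclasses.asdict(obj)
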