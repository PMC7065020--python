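"""Phenotype tables: I/O, validation, standardization, and fitness relativization.

The experimental unit is a single plant grown in one of two environments
(here: soil-microbial treatments).  Four variables are recorded per plant:
day of first flower, plant size (summed leaf lengths), growth rate (height
change per day), and total flower count, the last serving as the fitness
proxy.  Selection analyses operate on variance-standardized traits ``z`` and
relative fitness ``w`` (flower count divided by mean flower count), so that
gradients are in per-standard-deviation units.

Standardization and relativization can be done pooled across the two
environments (the default, which keeps one common trait scale for
cross-environment comparisons) or within each environment (a sensitivity
option).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)

#: Measured traits, in the fixed analysis/reporting order.
TRAITS: tuple[str, ...] = ("flowering_day", "size", "growth")

#: The fitness proxy column.
FITNESS: str = "total_flowers"

#: All measured variables (traits + fitness proxy).
MEASURED: tuple[str, ...] = TRAITS + (FITNESS,)

REQUIRED_COLUMNS: tuple[str, ...] = ("plant_id", "genotype", "treatment") + MEASURED

#: Recognised standardization scopes.
SCOPES: tuple[str, ...] = ("pooled", "within_treatment")


class SchemaError(ValueError):
    """A required column is missing or mis-mapped."""


class ValidationError(ValueError):
    """Table content violates an invariant (e.g. >2 treatment levels)."""


class DegenerateTraitError(ValueError):
    """A trait has zero variance within a standardization group."""


class DegenerateFitnessError(ValueError):
    """All fitness values are zero within a relativization group."""


class TraitDomainError(ValueError):
    """A transform was requested outside its domain (e.g. sqrt of negative)."""


def _check_scope(scope: str) -> str:
    if scope not in SCOPES:
        raise ValueError(f"scope must be one of {SCOPES}, got {scope!r}")
    return scope


@dataclass
class PhenotypeTable:
    """Validated per-plant records with genotype and treatment labels.

    Parameters
    ----------
    df
        One row per plant with columns ``plant_id``, ``genotype``,
        ``treatment``, ``flowering_day``, ``size``, ``growth``,
        ``total_flowers``.  Missing measurements are NaN.
    treatment_levels
        The two treatment labels, in display order (first label is the
        non-reference level in interaction models).
    meta
        Provenance: transforms applied, seed if simulated, source path.
    """

    df: pd.DataFrame
    treatment_levels: tuple[str, str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.df.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {missing}")
        if self.df["plant_id"].duplicated().any():
            dupes = self.df.loc[self.df["plant_id"].duplicated(), "plant_id"]
            raise ValidationError(f"duplicate plant_id values: {sorted(set(dupes))[:5]}")
        levels = set(self.df["treatment"].dropna().unique())
        declared = set(self.treatment_levels)
        if len(self.treatment_levels) != 2 or len(declared) != 2:
            raise ValidationError("exactly two distinct treatment levels required")
        extra = levels - declared
        if extra:
            raise ValidationError(
                f"treatment column contains undeclared level(s): {sorted(extra)}; "
                f"declared levels are {self.treatment_levels}"
            )
        for col in MEASURED:
            vals = pd.to_numeric(self.df[col], errors="coerce")
            finite = vals.dropna()
            if not np.isfinite(finite).all():
                raise ValidationError(f"column {col!r} contains non-finite values")
        tf = self.df[FITNESS].dropna()
        if (tf < 0).any():
            raise ValidationError("total_flowers must be >= 0 when present")

    def __len__(self) -> int:
        return len(self.df)

    def copy(self) -> "PhenotypeTable":
        return PhenotypeTable(self.df.copy(), self.treatment_levels, dict(self.meta))

    def write_csv(self, path: str | Path) -> None:
        """Write the table as CSV; missing values rendered as ``NA``."""
        self.df.to_csv(path, index=False, na_rep="NA")


@dataclass
class AnalysisTable:
    """A :class:`PhenotypeTable` augmented with standardized traits and
    relative fitness.

    Adds columns ``z_<trait>`` for each trait and ``w`` for relative
    fitness.  ``scope`` records whether centering/scaling used the pooled
    population or each treatment group separately.
    """

    df: pd.DataFrame
    treatment_levels: tuple[str, str]
    scope: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_scope(self.scope)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def z_columns(self) -> list[str]:
        return [c for c in self.df.columns if c.startswith("z_")]

    def complete_cases(self, columns: Sequence[str]) -> pd.DataFrame:
        """Rows with no missing values in ``columns`` (listwise deletion)."""
        return self.df.dropna(subset=list(columns))


def read_phenotypes(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    treatment_levels: tuple[str, str] | None = None,
    strip: bool = True,
    casefold: bool = False,
) -> PhenotypeTable:
    """Read a phenotype CSV into a validated :class:`PhenotypeTable`.

    Parameters
    ----------
    path
        CSV file with a header row; ``NA`` or empty cells are missing.
    column_map
        Mapping from source column names to the canonical names
        (``plant_id``, ``genotype``, ``treatment``, ``flowering_day``,
        ``size``, ``growth``, ``total_flowers``).  Unmapped canonical names
        must already be present.
    treatment_levels
        The two expected treatment labels.  Defaults to the two labels found
        (sorted), erroring if there are more than two.
    strip, casefold
        Whether to trim whitespace / lowercase the treatment labels before
        validation.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, na_values=["NA", ""], keep_default_na=True, dtype=str)
    if column_map:
        raw = raw.rename(columns=dict(column_map))
    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"missing required column(s) after mapping: {missing}")
    df = raw.loc[:, list(REQUIRED_COLUMNS)].copy()
    if strip:
        df["treatment"] = df["treatment"].str.strip()
    if casefold:
        df["treatment"] = df["treatment"].str.casefold()
    for col in MEASURED:
        before = df[col].notna()
        df[col] = pd.to_numeric(df[col], errors="coerce")
        bad = before & df[col].isna()
        if bad.any():
            logger.warning(
                "column %r: %d unparseable value(s) set to missing (rows %s)",
                col, int(bad.sum()), df.index[bad][:5].tolist(),
            )
    found = sorted(df["treatment"].dropna().unique())
    if treatment_levels is None:
        if len(found) != 2:
            raise ValidationError(f"expected exactly two treatment levels, found {found}")
        treatment_levels = (found[0], found[1])
    return PhenotypeTable(df, tuple(treatment_levels), meta={"source": str(path)})


class TraitStandardizer(BaseEstimator, TransformerMixin):
    """Center traits to mean 0 and scale to unit sample variance.

    Scaling uses the n-1 (sample) denominator, matching regression-based
    selection analysis conventions.  With ``scope="within_treatment"`` the
    mean and SD are computed per treatment group, giving each group its own
    trait scale.

    Attributes
    ----------
    means_, sds_ : dict
        Per-group ``{group: {trait: value}}``; group is ``"__pooled__"`` for
        pooled scope.
    """

    def __init__(self, traits: Sequence[str] = TRAITS, scope: str = "pooled"):
        self.traits = traits
        self.scope = scope

    def _groups(self, df: pd.DataFrame) -> list[tuple[str, pd.Index]]:
        if self.scope == "pooled":
            return [("__pooled__", df.index)]
        return [(lvl, df.index[df["treatment"] == lvl])
                for lvl in df["treatment"].dropna().unique()]

    def fit(self, table: PhenotypeTable | pd.DataFrame, y=None) -> "TraitStandardizer":
        _check_scope(self.scope)
        df = table.df if isinstance(table, PhenotypeTable) else table
        self.means_: dict[str, dict[str, float]] = {}
        self.sds_: dict[str, dict[str, float]] = {}
        for gname, idx in self._groups(df):
            self.means_[gname] = {}
            self.sds_[gname] = {}
            for trait in self.traits:
                vals = df.loc[idx, trait].dropna()
                if len(vals) < 2 or vals.nunique() < 2:
                    raise DegenerateTraitError(
                        f"trait {trait!r} has <2 distinct values in group {gname!r}"
                    )
                self.means_[gname][trait] = float(vals.mean())
                self.sds_[gname][trait] = float(vals.std(ddof=1))
        return self

    def transform(self, table: PhenotypeTable | pd.DataFrame) -> pd.DataFrame:
        df = (table.df if isinstance(table, PhenotypeTable) else table).copy()
        for gname, idx in self._groups(df):
            for trait in self.traits:
                mu = self.means_[gname][trait]
                sd = self.sds_[gname][trait]
                df.loc[idx, f"z_{trait}"] = (df.loc[idx, trait] - mu) / sd
        return df

    def inverse_transform(self, df: pd.DataFrame) -> pd.DataFrame:
        """Recover raw trait values from z columns (z*sd + mean)."""
        df = df.copy()
        for gname, idx in self._groups(df):
            for trait in self.traits:
                mu = self.means_[gname][trait]
                sd = self.sds_[gname][trait]
                df.loc[idx, trait] = df.loc[idx, f"z_{trait}"] * sd + mu
        return df


class FitnessRelativizer(BaseEstimator, TransformerMixin):
    """Divide the fitness proxy by its group mean so that mean(w) = 1."""

    def __init__(self, fitness: str = FITNESS, scope: str = "pooled"):
        self.fitness = fitness
        self.scope = scope

    def fit(self, table: PhenotypeTable | pd.DataFrame, y=None) -> "FitnessRelativizer":
        _check_scope(self.scope)
        df = table.df if isinstance(table, PhenotypeTable) else table
        groups = ([("__pooled__", df.index)] if self.scope == "pooled" else
                  [(lvl, df.index[df["treatment"] == lvl])
                   for lvl in df["treatment"].dropna().unique()])
        self.mean_fitness_: dict[str, float] = {}
        for gname, idx in groups:
            vals = df.loc[idx, self.fitness].dropna()
            if len(vals) == 0 or float(vals.mean()) <= 0:
                raise DegenerateFitnessError(
                    f"mean fitness not positive in group {gname!r}"
                )
            self.mean_fitness_[gname] = float(vals.mean())
        return self

    def transform(self, table: PhenotypeTable | pd.DataFrame) -> pd.DataFrame:
        df = (table.df if isinstance(table, PhenotypeTable) else table).copy()
        if self.scope == "pooled":
            df["w"] = df[self.fitness] / self.mean_fitness_["__pooled__"]
        else:
            for gname, mf in self.mean_fitness_.items():
                idx = df.index[df["treatment"] == gname]
                df.loc[idx, "w"] = df.loc[idx, self.fitness] / mf
        return df


def standardize_traits(
    table: PhenotypeTable,
    scope: str = "pooled",
    traits: Sequence[str] = TRAITS,
    relativize: bool = True,
) -> AnalysisTable:
    """Build the analysis table: standardized traits and relative fitness.

    Convenience wrapper chaining :class:`TraitStandardizer` and (optionally)
    :class:`FitnessRelativizer` with a common scope.
    """
    std = TraitStandardizer(traits=traits, scope=scope).fit(table)
    df = std.transform(table)
    meta = dict(table.meta)
    meta["standardization"] = {"scope": scope, "means": std.means_, "sds": std.sds_}
    if relativize:
        rel = FitnessRelativizer(scope=scope).fit(table)
        df = rel.transform(df)
        meta["relativization"] = {"scope": scope, "mean_fitness": rel.mean_fitness_}
    return AnalysisTable(df, table.treatment_levels, scope, meta)


def relativize_fitness(table: PhenotypeTable, scope: str = "pooled") -> AnalysisTable:
    """Relative fitness only (no trait standardization)."""
    rel = FitnessRelativizer(scope=scope).fit(table)
    df = rel.transform(table)
    meta = dict(table.meta)
    meta["relativization"] = {"scope": scope, "mean_fitness": rel.mean_fitness_}
    return AnalysisTable(df, table.treatment_levels, scope, meta)


def transform_trait(
    table: PhenotypeTable, trait: str, kind: str = "none"
) -> PhenotypeTable:
    """Apply a variance-stabilizing transform to one trait column.

    ``kind="sqrt"`` replaces the column with its square root (used for the
    left-skewed flowering-day residuals in the mixed-model stage);
    ``kind="none"`` returns the table unchanged.
    """
    if kind == "none":
        return table
    if kind != "sqrt":
        raise ValueError(f"unknown transform kind {kind!r}")
    out = table.copy()
    vals = out.df[trait]
    neg = vals.dropna() < 0
    if neg.any():
        rows = out.df.loc[neg.index[neg], "plant_id"].tolist()[:5]
        raise TraitDomainError(f"sqrt of negative {trait!r} values at plant_id {rows}")
    out.df[trait] = np.sqrt(vals)
    out.meta.setdefault("transforms", {})[trait] = "sqrt"
    return out


def summarize_by_treatment(
    table: PhenotypeTable, variables: Sequence[str] = MEASURED
) -> pd.DataFrame:
    """Per-treatment mean, SE of the mean and n for each measured variable.

    Also reports the percent difference of the first declared treatment
    relative to the second, 100*(mean_1 - mean_2)/mean_2 — the headline
    "how much larger / more / faster" contrast.
    """
    lvl1, lvl2 = table.treatment_levels
    rows = []
    for var in variables:
        entry: dict = {"variable": var}
        means = {}
        for lvl in (lvl1, lvl2):
            vals = table.df.loc[table.df["treatment"] == lvl, var].dropna()
            n = len(vals)
            mean = float(vals.mean()) if n else np.nan
            se = float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan
            if n == 0:
                logger.warning("no observations for %r in treatment %r", var, lvl)
            entry[f"mean_{lvl}"] = mean
            entry[f"se_{lvl}"] = se
            entry[f"n_{lvl}"] = n
            means[lvl] = mean
        entry["percent_difference"] = percent_difference(means[lvl1], means[lvl2])
        rows.append(entry)
    return pd.DataFrame(rows)


def percent_difference(value: float, reference: float) -> float:
    """100 * (value - reference) / reference."""
    if reference == 0 or not np.isfinite(reference):
        return np.nan
    return 100.0 * (value - reference) / reference


def percent_change(old: float, new: float) -> float:
    """100 * (new - old) / old — the relative change from ``old`` to ``new``."""
    if old == 0 or not np.isfinite(old):
        return np.nan
    return 100.0 * (new - old) / old


def write_summary(summary: pd.DataFrame, path: str | Path, meta: dict | None = None) -> None:
    """Write a trait summary as CSV plus a JSON sidecar with metadata."""
    path = Path(path)
    summary.to_csv(path, index=False, na_rep="NA")
    sidecar = path.with_suffix(".json")
    payload = {"table": summary.to_dict(orient="records"), "meta": meta or {}}
    sidecar.write_text(json.dumps(payload, indent=2, default=float))
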