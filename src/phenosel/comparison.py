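"""Does the environment alter selection?  Trait-by-treatment ANCOVA tests.

An environmental factor is an *agent of selection* on a trait if the
strength or form of selection differs between environments.  With treatment
coded as a 0/1 indicator T (reference = the second declared level), the
model

    w ~ z + T + z:T

makes the z:T coefficient the between-treatment difference in the selection
differential, and its 1-df F test (the squared t) is the heterogeneity test.
The same construction extends to the multivariate linear-gradient model and
to the full second-order model, where quadratic-by-treatment and
cross-product-by-treatment terms test for heterogeneous stabilizing and
correlational selection.

All tests run on pooled-scope standardized data (one common z scale), so
slope differences are not conflated with scale differences; the per-group
slopes implied by the interaction model are then algebraically the
within-group OLS slopes.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .data import TRAITS, AnalysisTable
from .selection import (
    CollinearityError,
    UnderdeterminedModelError,
    _check_rank,
    quadratic_design,
    significance_stars,
)


class GroupingError(ValueError):
    """One treatment group is empty or degenerate for the requested model."""


@dataclass
class InteractionTest:
    """One trait-by-treatment heterogeneity test.

    ``estimates`` maps each treatment label to the slope/coefficient being
    compared; ``difference`` is first-level minus reference-level.
    """

    target: str
    level: str  # differential | linear_gradient | quadratic | correlational
    F: float
    df1: int
    df2: float
    p: float
    estimates: dict[str, float]
    difference: float

    @property
    def stars(self) -> str:
        return significance_stars(self.p)


def _coded_frame(table: AnalysisTable, columns: Sequence[str]) -> tuple[pd.DataFrame, str, str]:
    """Complete cases with the 0/1 treatment indicator ``T`` added."""
    lvl1, ref = table.treatment_levels
    df = table.df.dropna(subset=list(columns)).copy()
    for lvl in (lvl1, ref):
        if (df["treatment"] == lvl).sum() == 0:
            raise GroupingError(f"treatment group {lvl!r} empty on complete cases")
    df["T"] = (df["treatment"] == lvl1).astype(float)
    return df, lvl1, ref


def _fit(df: pd.DataFrame, X: pd.DataFrame, w: np.ndarray):
    Xd = sm.add_constant(X, has_constant="add")
    if len(w) <= Xd.shape[1]:
        raise UnderdeterminedModelError(f"{len(w)} cases for {Xd.shape[1]} terms")
    _check_rank(np.asarray(Xd, float), list(Xd.columns))
    return sm.OLS(w, Xd).fit()


def _term_test(res, term: str, level: str, target: str,
               base: float, diff: float, lvl1: str, ref: str) -> InteractionTest:
    t = float(res.tvalues[term])
    return InteractionTest(
        target=target, level=level, F=t * t, df1=1,
        df2=float(res.df_resid), p=float(res.pvalues[term]),
        estimates={ref: base, lvl1: base + diff}, difference=diff)


def differential_interaction(table: AnalysisTable, trait: str) -> InteractionTest:
    """Heterogeneity of the selection differential: w ~ z + T + z:T."""
    zc = f"z_{trait}"
    df, lvl1, ref = _coded_frame(table, [zc, "w"])
    X = pd.DataFrame({zc: df[zc], "T": df["T"], f"{zc}:T": df[zc] * df["T"]})
    res = _fit(df, X, df["w"].to_numpy())
    return _term_test(res, f"{zc}:T", "differential", trait,
                      float(res.params[zc]), float(res.params[f"{zc}:T"]),
                      lvl1, ref)


def gradient_interaction(
    table: AnalysisTable, traits: Sequence[str] = TRAITS, level: str = "linear"
) -> list[InteractionTest]:
    """Heterogeneity of selection gradients.

    ``level="linear"``: w ~ sum z_j + T + sum z_j:T, one test per trait's
    linear gradient.  ``level="full"``: adds quadratic and cross-product
    terms and their T interactions; reports tests for quadratic-by-T and
    pair-by-T terms.
    """
    if level not in ("linear", "full"):
        raise ValueError("level must be 'linear' or 'full'")
    zcols = [f"z_{t}" for t in traits]
    df, lvl1, ref = _coded_frame(table, zcols + ["w"])
    base = df[zcols] if level == "linear" else quadratic_design(df, traits)
    X = base.copy()
    X["T"] = df["T"]
    for c in base.columns:
        X[f"{c}:T"] = base[c] * df["T"]
    res = _fit(df, X, df["w"].to_numpy())
    tests: list[InteractionTest] = []
    if level == "linear":
        for t in traits:
            c = f"z_{t}"
            tests.append(_term_test(res, f"{c}:T", "linear_gradient", t,
                                    float(res.params[c]),
                                    float(res.params[f"{c}:T"]), lvl1, ref))
    else:
        for t in traits:
            c = f"z_{t}^2"
            # doubled, matching the gamma_jj = 2q convention
            tests.append(_term_test(res, f"{c}:T", "quadratic", f"{t}^2",
                                    2.0 * float(res.params[c]),
                                    2.0 * float(res.params[f"{c}:T"]), lvl1, ref))
        for a, b in combinations(traits, 2):
            c = f"z_{a}:z_{b}"
            tests.append(_term_test(res, f"{c}:T", "correlational", f"{a}:{b}",
                                    float(res.params[c]),
                                    float(res.params[f"{c}:T"]), lvl1, ref))
    return tests


def correlational_interaction(
    table: AnalysisTable, pair: tuple[str, str], traits: Sequence[str] = TRAITS
) -> InteractionTest:
    """Heterogeneity of one correlational gradient gamma_ij within the full
    second-order interaction model."""
    a, b = pair
    if (a, b) not in set(combinations(traits, 2)):
        if (b, a) in set(combinations(traits, 2)):
            a, b = b, a
        else:
            raise KeyError(f"pair {pair!r} not among traits {tuple(traits)}")
    for test in gradient_interaction(table, traits, level="full"):
        if test.level == "correlational" and test.target == f"{a}:{b}":
            return test
    raise RuntimeError("unreachable: pair term missing from full model")


def interaction_table(
    table: AnalysisTable, traits: Sequence[str] = TRAITS,
    levels: Sequence[str] = ("differential", "linear", "full"),
) -> pd.DataFrame:
    """All heterogeneity tests as one tidy frame, with Holm-adjusted p-values
    alongside the raw ones (no correction is applied to the raw column)."""
    tests: list[InteractionTest] = []
    if "differential" in levels:
        tests += [differential_interaction(table, t) for t in traits]
    if "linear" in levels:
        tests += gradient_interaction(table, traits, "linear")
    if "full" in levels:
        tests += gradient_interaction(table, traits, "full")
    lvl1, ref = table.treatment_levels
    out = pd.DataFrame([{
        "target": t.target, "level": t.level, "F": t.F, "df1": t.df1,
        "df2": t.df2, "p": t.p, "stars": t.stars,
        f"estimate_{lvl1}": t.estimates[lvl1], f"estimate_{ref}": t.estimates[ref],
        "difference": t.difference,
    } for t in tests])
    out["p_holm"] = multipletests(out["p"], method="holm")[1]
    return out
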