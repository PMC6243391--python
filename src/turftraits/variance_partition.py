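"""Nested variance partitioning of leaf traits across taxonomic levels.

Decomposes trait variance into components attributable to order, family,
genus, species, population (species x site) and within-population residual,
using taxonomy as a proxy phylogeny.  The model is the fully nested
random-effects decomposition

    y = mu + b_order + b_family + b_genus + b_species + b_population + eps

with each effect zero-mean Gaussian.  Two estimators are provided:

``reml``
    restricted maximum likelihood via a mixed linear model (default; robust
    to the strong imbalance of field data, where leaf numbers differ by site
    and many species are observed at a single site);
``moments``
    the hierarchical method of moments for nested classifications
    (Henderson-style equating of nested sums of squares of group means to
    their expectations), which is exactly unbiased and serves as an
    independent cross-check — on balanced designs with interior estimates the
    two coincide.

Negative moment estimates are truncated to zero before normalisation;
proportions are components divided by their (post-truncation) sum.
Multiplicative traits must already be log transformed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import InsufficientDataError, SchemaError

#: Levels outermost-first; "within" is the residual.
LEVELS: tuple[str, ...] = (
    "order", "family", "genus", "species", "population", "within",
)

#: Columns whose combination defines the grouping cells of each random level.
_LEVEL_KEYS: dict[str, list[str]] = {
    "order": ["order"],
    "family": ["order", "family"],
    "genus": ["order", "family", "genus"],
    "species": ["order", "family", "genus", "species"],
    "population": ["order", "family", "genus", "species", "site"],
}


@dataclass
class VariancePartition:
    trait: str
    components: dict[str, float]
    proportions: dict[str, float]
    n_leaves: int
    estimator: str
    degenerate_levels: tuple[str, ...] = ()
    warnings: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        total = sum(self.proportions.values())
        if self.components and abs(total - 1.0) > 1e-9:
            raise ValueError(f"proportions sum to {total}, not 1")


def _cell_labels(df: pd.DataFrame, level: str) -> pd.Series:
    keys = _LEVEL_KEYS[level]
    lab = df[keys[0]].astype(str)
    for k in keys[1:]:
        lab = lab + "\x1f" + df[k].astype(str)
    return lab


def _degenerate_levels(df: pd.DataFrame) -> list[str]:
    """Levels whose cells do not subdivide the parent level's cells."""
    out = []
    n_parent = 1
    for level in LEVELS[:-1]:
        n_cells = _cell_labels(df, level).nunique()
        if n_cells == n_parent:
            out.append(level)
        n_parent = n_cells
    n = len(df)
    if n == n_parent:  # no replication within populations
        out.append("within")
    return out


# --------------------------------------------------------------------------
# Method of moments (nested ANOVA, unbalanced-capable)
# --------------------------------------------------------------------------

def _moments_components(df: pd.DataFrame) -> dict[str, float]:
    """Equate nested sums of squares to their expectations and solve.

    Uses the identity E[T_l] = mu^2 N + sum_m sigma2_m c(l, m) + sigma2_e G_l
    where T_l = sum over level-l groups g of (group total)^2 / n_g, and for a
    level m nested at or below l, c(l, m) = sum over level-m cells of
    n_cell^2 / n_parent_group.  Differences T_l - T_{l-1} eliminate mu and all
    levels above l, giving a triangular system in the sigma^2.
    """
    y = df["value"].to_numpy(dtype=float)
    n = len(y)
    random_levels = list(LEVELS[:-1])

    # group sizes and totals per level, plus parent-group map
    labels = {lvl: _cell_labels(df, lvl) for lvl in random_levels}
    sums, sizes = {}, {}
    for lvl in random_levels:
        g = pd.DataFrame({"y": y, "g": labels[lvl].to_numpy()}).groupby("g")["y"]
        sums[lvl] = g.sum()
        sizes[lvl] = g.size()

    def T(lvl: str | None) -> float:
        if lvl is None:
            return float(y.sum() ** 2 / n)
        return float((sums[lvl] ** 2 / sizes[lvl]).sum())

    def n_groups(lvl: str | None) -> int:
        return 1 if lvl is None else int(sizes[lvl].size)

    def coef(grouping: str | None, m: str) -> float:
        """c(grouping, m) for level m nested at or below `grouping`."""
        cells = sizes[m]
        if grouping is None:
            return float((cells**2).sum() / n)
        # parent group of each level-m cell: truncate the composite label
        k = len(_LEVEL_KEYS[grouping])
        parents = cells.index.to_series().str.split("\x1f").str[:k].str.join("\x1f")
        parent_sizes = sizes[grouping].reindex(parents.to_numpy()).to_numpy()
        return float((cells.to_numpy() ** 2 / parent_sizes).sum())

    # build triangular system over non-degenerate random levels
    usable = [
        lvl for lvl in random_levels
        if n_groups(lvl) > n_groups(_parent_of(lvl))
    ]
    k = len(usable)
    A = np.zeros((k + 1, k + 1))
    b = np.zeros(k + 1)
    for i, lvl in enumerate(usable):
        parent = _parent_of_usable(lvl, usable)
        b[i] = T(lvl) - T(parent)
        for j, m in enumerate(usable):
            if _depth(m) >= _depth(lvl):
                A[i, j] = coef(lvl, m) - coef(parent, m)
        A[i, k] = n_groups(lvl) - n_groups(parent)
    # residual equation
    deepest = usable[-1] if usable else None
    b[k] = float((y**2).sum()) - T(deepest)
    A[k, k] = n - n_groups(deepest)
    if A[k, k] == 0:
        # no within-cell replication: residual unidentifiable
        A[k, k] = 1.0
        b[k] = 0.0
    sigma2 = np.linalg.solve(A, b)
    out = {lvl: 0.0 for lvl in LEVELS}
    for lvl, v in zip(usable, sigma2[:k]):
        out[lvl] = float(v)
    out["within"] = float(sigma2[k])
    return out


def _depth(level: str) -> int:
    return LEVELS.index(level)


def _parent_of(level: str) -> str | None:
    i = LEVELS.index(level)
    return LEVELS[i - 1] if i > 0 else None


def _parent_of_usable(level: str, usable: list[str]) -> str | None:
    """Nearest shallower usable level (degenerate levels are transparent)."""
    i = usable.index(level)
    return usable[i - 1] if i > 0 else None


# --------------------------------------------------------------------------
# REML via mixed linear model
# --------------------------------------------------------------------------

def _reml_components(df: pd.DataFrame) -> tuple[dict[str, float], list[str]]:
    from statsmodels.regression.mixed_linear_model import MixedLM

    notes: list[str] = []
    work = df.copy()
    random_levels = list(LEVELS[:-1])
    usable = [
        lvl for lvl in random_levels
        if _cell_labels(work, lvl).nunique()
        > (1 if _parent_of(lvl) is None else _cell_labels(work, _parent_of(lvl)).nunique())
    ]
    out = {lvl: 0.0 for lvl in LEVELS}
    if not usable:
        out["within"] = float(np.var(work["value"].to_numpy(), ddof=1))
        return out, notes

    for lvl in usable:
        work[f"_{lvl}"] = _cell_labels(work, lvl).to_numpy()
    top, rest = usable[0], usable[1:]
    vc = {lvl: f"0 + C(Q('_{lvl}'))" for lvl in rest}
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        md = MixedLM.from_formula(
            "value ~ 1",
            groups=f"_{top}",
            re_formula="1",
            vc_formula=vc or None,
            data=work,
        )
        res = md.fit(reml=True)
    for w in caught:
        if "Converge" in str(w.category.__name__) or "converge" in str(w.message).lower():
            notes.append(str(w.message))
            break

    out[top] = max(float(np.asarray(res.cov_re)[0, 0]), 0.0)
    if rest:
        for name, v in zip(md.exog_vc.names, np.asarray(res.vcomp)):
            out[name.lstrip("_")] = max(float(v), 0.0)
    out["within"] = float(res.scale)
    return out, notes


# --------------------------------------------------------------------------
# Public API
# --------------------------------------------------------------------------

def partition_variance(
    df: pd.DataFrame, trait: str, estimator: str = "reml"
) -> VariancePartition:
    """Estimate nested variance components and proportions for one trait.

    `df` should contain unmanipulated leaves only, with complete taxonomy
    columns, and multiplicative traits already log transformed.  Degenerate
    levels (a single realised group, or no subdivision of the parent level)
    are reported with proportion 0 and flagged rather than raising.
    """
    if estimator not in ("reml", "moments"):
        raise ValueError(f"unknown estimator {estimator!r}")
    for col in ("order", "family", "genus", "species", "site", "value", "trait"):
        if col not in df.columns:
            raise SchemaError(f"trait table is missing column {col!r}")
    sub = df.loc[df["trait"] == trait]
    if len(sub) < 2:
        raise InsufficientDataError(
            f"need >= 2 leaves for trait {trait!r}, got {len(sub)}"
        )
    degenerate = _degenerate_levels(sub)
    notes: list[str] = []
    if degenerate:
        notes.append(f"degenerate level(s) reported as 0: {', '.join(degenerate)}")

    if estimator == "moments":
        components = _moments_components(sub)
    else:
        components, reml_notes = _reml_components(sub)
        notes.extend(reml_notes)

    components = {k: max(v, 0.0) for k, v in components.items()}
    total = sum(components.values())
    if total <= 0:
        proportions = {k: 0.0 for k in LEVELS}
        proportions["within"] = 1.0
        notes.append("all components zero; defaulting proportions to within = 1")
    else:
        proportions = {k: v / total for k, v in components.items()}
    return VariancePartition(
        trait=trait,
        components=components,
        proportions=proportions,
        n_leaves=len(sub),
        estimator=estimator,
        degenerate_levels=tuple(degenerate),
        warnings=tuple(notes),
    )


def partition_all(
    df: pd.DataFrame, traits: list[str] | None = None, estimator: str = "reml"
) -> pd.DataFrame:
    """Variance partitions for several traits as a long table.

    One row per trait x level with the component variance and its proportion
    of the total (the stacked-bar representation of the decomposition).
    """
    traits = traits if traits is not None else sorted(df["trait"].unique())
    rows = []
    for trait in traits:
        vp = partition_variance(df, trait, estimator=estimator)
        for level in LEVELS:
            rows.append(
                (trait, level, vp.components[level], vp.proportions[level],
                 vp.n_leaves, vp.estimator)
            )
    return pd.DataFrame(
        rows, columns=["trait", "level", "variance", "proportion", "n_leaves", "estimator"]
    )
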