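"""Biomass-weighted, bootstrapped community trait distributions per site.

Each bootstrap replicate resamples every species' trait pool with
replacement, takes the per-species mean of the resampled leaves, and
combines the species means into a community value weighted by relative site
biomass (renormalised over species with available trait data).  By default
each species is resampled at its own pool size — the classic nonparametric
bootstrap of the biomass-weighted mean, whose percentile interval is then
asymptotically calibrated; ``n_draws`` can instead fix a common per-species
resample size (the replicate mean is invariant to this choice, the interval
width is not).  ``B`` replicates form the community trait distribution,
summarised by its mean and a percentile confidence interval.

Trait pools follow a four-rung priority hierarchy: (1) focal species under
unmanipulated conditions at the focal site, (2) focal genus at the focal
site, (3) focal species anywhere, (4) focal genus anywhere.  When a genus
rung is used, sampling is rarefied so that each congener is equally likely to
be drawn regardless of how many leaves it contributed.

The fraction of site biomass belonging to species with no pool at all is
reported as ``1 - coverage`` rather than silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import DataError, unmanipulated

SOURCE_LEVELS: tuple[str, ...] = (
    "species_at_site", "genus_at_site", "species_anywhere", "genus_anywhere",
)


@dataclass
class TraitPool:
    species: str
    site: str
    trait: str
    values: np.ndarray
    source_level: str
    #: per-congener value arrays; present only for genus-level sources
    congener_groups: list[np.ndarray] | None = None


@dataclass
class BootstrapResult:
    site: str
    trait: str
    replicate_means: np.ndarray
    n_draws_per_replicate: int
    weighted: bool
    coverage: float
    seed: int | None = None

    @property
    def B(self) -> int:
        return len(self.replicate_means)


@dataclass
class CommunityTraitSummary:
    site: str
    trait: str
    mean: float
    ci_low: float
    ci_high: float
    level: float = 0.95


# --------------------------------------------------------------------------
# Trait pools
# --------------------------------------------------------------------------

def select_trait_pool(
    species: str,
    site: str,
    trait: str,
    trait_table: pd.DataFrame,
    taxonomy: pd.DataFrame,
) -> TraitPool | None:
    """Return the first non-empty rung of the trait-data priority hierarchy.

    ``trait_table`` must already be restricted to unmanipulated conditions
    (use :func:`turftraits.data_model.unmanipulated`).  Returns ``None`` when
    all four rungs are empty; the species is then excluded from bootstrapping
    and accounted for in the coverage fraction.
    """
    sub = trait_table.loc[trait_table["trait"] == trait]
    row = taxonomy.loc[taxonomy["species"] == species]
    genus = row["genus"].iloc[0] if len(row) else None

    def pool(mask, source):
        vals = sub.loc[mask, "value"].to_numpy(dtype=float)
        if vals.size == 0:
            return None
        if source.startswith("genus"):
            groups = [
                g["value"].to_numpy(dtype=float)
                for _, g in sub.loc[mask].groupby("species", sort=True)
            ]
            return TraitPool(species, site, trait, vals, source, groups)
        return TraitPool(species, site, trait, vals, source)

    candidates = [
        ((sub["species"] == species) & (sub["site"] == site), "species_at_site"),
    ]
    if genus is not None:
        candidates.append(
            ((sub["genus"] == genus) & (sub["site"] == site), "genus_at_site")
        )
    candidates.append((sub["species"] == species, "species_anywhere"))
    if genus is not None:
        candidates.append((sub["genus"] == genus, "genus_anywhere"))

    for mask, source in candidates:
        p = pool(mask, source)
        if p is not None:
            return p
    return None


def draw_individual(pool: TraitPool, rng: np.random.Generator) -> float:
    """Draw one leaf value from a pool.

    Species-level pools: uniform with replacement.  Genus-level pools: first
    a congener uniformly, then a leaf uniformly within it (rarefied
    sampling).
    """
    if pool.congener_groups is not None:
        group = pool.congener_groups[rng.integers(len(pool.congener_groups))]
        return float(group[rng.integers(group.size)])
    return float(pool.values[rng.integers(pool.values.size)])


def _draw_many(pool: TraitPool, m: int, rng: np.random.Generator) -> np.ndarray:
    """Vectorised equivalent of ``m`` calls to :func:`draw_individual`."""
    if pool.congener_groups is not None:
        groups = pool.congener_groups
        lens = np.array([g.size for g in groups])
        offsets = np.concatenate([[0], np.cumsum(lens[:-1])])
        flat = np.concatenate(groups)
        cong = rng.integers(len(groups), size=m)
        within = (rng.random(m) * lens[cong]).astype(np.int64)
        return flat[offsets[cong] + within]
    return pool.values[rng.integers(pool.values.size, size=m)]


# --------------------------------------------------------------------------
# Bootstrap
# --------------------------------------------------------------------------

def bootstrap_community_distribution(
    site: str,
    trait: str,
    community: pd.DataFrame,
    trait_table: pd.DataFrame,
    taxonomy: pd.DataFrame,
    B: int = 1000,
    n_draws: int | None = None,
    seed: int | None = None,
    weighted: bool = True,
    rng: np.random.Generator | None = None,
) -> BootstrapResult:
    """Bootstrap the biomass-weighted community trait distribution of a site.

    ``community`` biomass is pooled over plots within the site.  Each
    replicate resamples every covered species' pool with replacement (at its
    own pool size, or at ``n_draws`` leaves per species if given) and takes
    the biomass-weighted mean of the per-species means.  With
    ``weighted=False`` species are weighted equally instead (sensitivity
    option).  Deterministic given ``seed``.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    unmanip = unmanipulated(trait_table)
    comm = community.loc[community["site"] == site]
    biomass = comm.groupby("species")["biomass"].sum()
    biomass = biomass[biomass > 0]
    if biomass.empty:
        raise DataError(f"no species with positive biomass at site {site!r}")

    pools: list[TraitPool] = []
    weights: list[float] = []
    covered_biomass = 0.0
    for sp, b in biomass.sort_index().items():
        p = select_trait_pool(sp, site, trait, unmanip, taxonomy)
        if p is None:
            continue
        pools.append(p)
        weights.append(float(b))
        covered_biomass += float(b)
    total_biomass = float(biomass.sum())
    coverage = covered_biomass / total_biomass
    if not pools:
        raise DataError(
            f"no trait data for any species at site {site!r}, trait {trait!r}"
        )
    w = np.asarray(weights)
    w = w / w.sum() if weighted else np.full(len(pools), 1.0 / len(pools))

    means = np.zeros(B)
    total_draws = 0
    for weight, pool in zip(w, pools):
        m = int(n_draws) if n_draws is not None else int(pool.values.size)
        total_draws += m
        draws = _draw_many(pool, B * m, rng).reshape(B, m)
        means += weight * draws.mean(axis=1)
    return BootstrapResult(
        site=site,
        trait=trait,
        replicate_means=means,
        n_draws_per_replicate=total_draws,
        weighted=weighted,
        coverage=coverage,
        seed=seed,
    )


def summarize_bootstrap(
    result: BootstrapResult, level: float = 0.95
) -> CommunityTraitSummary:
    """Mean of replicate means and central percentile interval.

    Quantiles use linear interpolation; ``level=0`` degenerates to a
    zero-width interval at the median.
    """
    reps = np.asarray(result.replicate_means, dtype=float)
    if reps.size == 0:
        raise DataError("empty replicate_means")
    lo, hi = np.quantile(reps, [(1 - level) / 2, 1 - (1 - level) / 2])
    return CommunityTraitSummary(
        site=result.site,
        trait=result.trait,
        mean=float(reps.mean()),
        ci_low=float(lo),
        ci_high=float(hi),
        level=level,
    )


def bootstrap_all(
    community: pd.DataFrame,
    trait_table: pd.DataFrame,
    taxonomy: pd.DataFrame,
    traits: list[str] | None = None,
    B: int = 1000,
    n_draws: int | None = None,
    seed: int | None = None,
    level: float = 0.95,
    weighted: bool = True,
) -> pd.DataFrame:
    """Bootstrap summaries for every site x trait combination.

    Returns one row per combination with mean, percentile CI, coverage and
    the sampling parameters — the plottable community-gradient table.
    Sub-streams per combination are derived from ``seed`` in a fixed order,
    so results are reproducible and independent of which combinations exist.
    """
    traits = traits if traits is not None else sorted(trait_table["trait"].unique())
    sites = sorted(community["site"].unique())
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(sites) * len(traits))
    rows = []
    for i, site in enumerate(sites):
        for j, trait in enumerate(traits):
            rng = np.random.default_rng(children[i * len(traits) + j])
            res = bootstrap_community_distribution(
                site, trait, community, trait_table, taxonomy,
                B=B, n_draws=n_draws, weighted=weighted, rng=rng,
            )
            s = summarize_bootstrap(res, level=level)
            rows.append(
                (site, trait, s.mean, s.ci_low, s.ci_high, B, n_draws,
                 res.coverage, seed)
            )
    return pd.DataFrame(
        rows,
        columns=[
            "site", "trait", "mean", "ci_low", "ci_high", "B", "n_draws",
            "coverage", "seed",
        ],
    )
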