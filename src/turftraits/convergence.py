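"""Convergence/divergence classification of plastic responses and G-tests.

A transplanted species x trait observation is classified against the
destination community's trait mean:

* ``no_change`` — the transplanted mean lies inside the 99% t-distribution
  confidence interval of the species' mean under unmanipulated conditions at
  its home site (no significant plastic response);
* ``converging`` — a significant shift that lands closer to the destination
  community mean than the home mean was;
* ``diverging`` — a significant shift further from the destination community
  mean.

Each observation also carries a ``start_group``: whether the home mean was
closer to the home or destination community mean before transplantation, and
its transplant type (warming/cooling).  Dependence of the outcome on either
grouping is tested with log-likelihood ratio (G) tests of independence on
3 x 2 contingency tables (df = 2): G = 2 sum O ln(O/E) against the upper tail
of the chi-square distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import DataError, InsufficientDataError, unmanipulated

logger = logging.getLogger(__name__)

OUTCOMES: tuple[str, ...] = ("converging", "diverging", "no_change")
START_GROUPS: tuple[str, ...] = ("home", "destination")
TREATMENT_LEVELS: tuple[str, ...] = ("warming", "cooling")

RECORD_COLUMNS = [
    "species", "trait", "turf", "treatment", "start_group", "outcome",
    "T_mean", "H_mean", "home_comm_mean", "dest_comm_mean",
    "ci99_low", "ci99_high", "n_home", "n_transplant",
]


@dataclass(frozen=True)
class HomeSummary:
    """Mean, SD and central t-interval of a species' trait at its home site
    under unmanipulated conditions."""

    species: str
    site: str
    trait: str
    mean: float
    sd: float
    n: int
    ci_low: float
    ci_high: float
    level: float = 0.99


@dataclass
class ContingencyTable:
    rows: tuple[str, ...]
    columns: tuple[str, ...]
    counts: np.ndarray  # shape (len(rows), len(columns)), int

    @property
    def expected(self) -> np.ndarray:
        o = self.counts.astype(float)
        total = o.sum()
        return np.outer(o.sum(axis=1), o.sum(axis=0)) / total

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.rows), columns=list(self.columns))


@dataclass(frozen=True)
class GTestResult:
    G: float
    df: int
    p: float


# --------------------------------------------------------------------------
# Home summaries
# --------------------------------------------------------------------------

def summarize_home(
    trait_table: pd.DataFrame,
    species: str,
    site: str,
    trait: str,
    level: float = 0.99,
) -> HomeSummary:
    """Summary of one species x site x trait under unmanipulated conditions.

    Uses the sample SD (n-1 denominator) and the exact central t interval,
    mean +/- t(1 - (1-level)/2, n-1) * sd / sqrt(n).  Requires n >= 2.
    """
    sub = unmanipulated(trait_table)
    vals = sub.loc[
        (sub["species"] == species) & (sub["site"] == site) & (sub["trait"] == trait),
        "value",
    ].to_numpy(dtype=float)
    return _summary_from_values(vals, species, site, trait, level)


def _summary_from_values(vals, species, site, trait, level) -> HomeSummary:
    n = vals.size
    if n < 2:
        raise InsufficientDataError(
            f"need >= 2 leaves for home summary of {species}/{site}/{trait}, got {n}"
        )
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1))
    half = float(stats.t.ppf(1 - (1 - level) / 2, n - 1)) * sd / np.sqrt(n)
    return HomeSummary(
        species=species, site=site, trait=trait, mean=mean, sd=sd, n=n,
        ci_low=mean - half, ci_high=mean + half, level=level,
    )


def summarize_homes(trait_table: pd.DataFrame, level: float = 0.99) -> dict:
    """All usable home summaries, keyed by (species, site, trait).

    Species x site x trait cells with fewer than two leaves are skipped and
    counted in the returned dict's ``"_n_insufficient"`` entry.
    """
    sub = unmanipulated(trait_table)
    out: dict = {}
    skipped = 0
    for (species, site, trait), g in sub.groupby(["species", "site", "trait"]):
        vals = g["value"].to_numpy(dtype=float)
        if vals.size < 2:
            skipped += 1
            continue
        out[(species, site, trait)] = _summary_from_values(
            vals, species, site, trait, level
        )
    out["_n_insufficient"] = skipped
    return out


# --------------------------------------------------------------------------
# Classification
# --------------------------------------------------------------------------

def classify_transplant(
    T_mean: float,
    home: HomeSummary,
    home_comm_mean: float,
    dest_comm_mean: float,
) -> tuple[str, str]:
    """Classify one transplant observation: (outcome, start_group).

    ``no_change`` if the transplanted mean lies inside the home CI; otherwise
    converging iff it is strictly closer to the destination community mean
    than the home mean was (distance ties count as diverging).  The start
    group is ``destination`` iff the home mean is strictly closer to the
    destination community mean than to the home community mean (ties count
    as home).
    """
    if home.ci_low <= T_mean <= home.ci_high:
        outcome = "no_change"
    elif abs(T_mean - dest_comm_mean) < abs(home.mean - dest_comm_mean):
        outcome = "converging"
    else:
        outcome = "diverging"
    start_group = (
        "destination"
        if abs(home.mean - dest_comm_mean) < abs(home.mean - home_comm_mean)
        else "home"
    )
    return outcome, start_group


def build_convergence_records(
    trait_table: pd.DataFrame,
    design: pd.DataFrame,
    community_means: pd.DataFrame,
    home_summaries: dict | None = None,
    ci_level: float = 0.99,
) -> pd.DataFrame:
    """Classify every transplanted turf x species x trait observation.

    ``community_means`` must provide one row per site x trait with a ``mean``
    column (typically the bootstrapped biomass-weighted means from
    :mod:`turftraits.community_bootstrap`).  Observations without a usable
    home summary or a community mean on either side are skipped with a
    warning count.
    """
    if home_summaries is None:
        home_summaries = summarize_homes(trait_table, level=ci_level)
    comm = community_means.set_index(["site", "trait"])["mean"]
    transplant_type = {"warmed": "warming", "cooled": "cooling"}

    turfs = design[design["treatment"].isin(transplant_type)]
    leaves = trait_table[trait_table["plot_id"].isin(turfs["plot_id"])]
    t_means = (
        leaves.groupby(["plot_id", "species", "trait"])["value"]
        .agg(["mean", "size"])
        .reset_index()
    )
    turf_info = turfs.set_index("plot_id")
    records, skipped = [], 0
    for row in t_means.itertuples(index=False):
        info = turf_info.loc[row.plot_id]
        origin, dest = info["origin_site"], info["site"]
        home = home_summaries.get((row.species, origin, row.trait))
        if home is None:
            skipped += 1
            continue
        try:
            home_comm = float(comm[(origin, row.trait)])
            dest_comm = float(comm[(dest, row.trait)])
        except KeyError:
            skipped += 1
            continue
        outcome, start_group = classify_transplant(row.mean, home, home_comm, dest_comm)
        records.append(
            (
                row.species, row.trait, row.plot_id,
                transplant_type[info["treatment"]], start_group, outcome,
                float(row.mean), home.mean, home_comm, dest_comm,
                home.ci_low, home.ci_high, home.n, int(row.size),
            )
        )
    if skipped:
        logger.warning(
            "%d transplant observations skipped (no home summary or community mean)",
            skipped,
        )
    return pd.DataFrame(records, columns=RECORD_COLUMNS)


# --------------------------------------------------------------------------
# Contingency tables and G-tests
# --------------------------------------------------------------------------

def tabulate_outcomes(records: pd.DataFrame, column_factor: str) -> ContingencyTable:
    """3 x 2 outcome table against ``start_group`` or ``treatment``.

    All outcome rows and factor levels are retained even when empty.
    """
    if column_factor == "start_group":
        columns = START_GROUPS
    elif column_factor == "treatment":
        columns = TREATMENT_LEVELS
    else:
        raise ValueError(f"unknown column factor {column_factor!r}")
    if records.empty:
        raise DataError("no convergence records to tabulate")
    counts = np.zeros((len(OUTCOMES), len(columns)), dtype=int)
    grouped = records.groupby(["outcome", column_factor]).size()
    for (outcome, col), n in grouped.items():
        counts[OUTCOMES.index(outcome), columns.index(col)] = int(n)
    return ContingencyTable(rows=OUTCOMES, columns=columns, counts=counts)


def g_test(table: ContingencyTable) -> GTestResult:
    """Log-likelihood ratio test of independence.

    G = 2 sum O ln(O/E) with 0 ln 0 = 0; df = (rows-1)(cols-1); p is the
    upper-tail chi-square probability.  All-zero rows or columns are dropped
    (with a warning) before computing expectations and df.
    """
    counts = np.asarray(table.counts)
    if counts.sum() == 0:
        raise DataError("empty contingency table")
    keep_r = counts.sum(axis=1) > 0
    keep_c = counts.sum(axis=0) > 0
    if not (keep_r.all() and keep_c.all()):
        logger.warning("dropping all-zero row(s)/column(s) from contingency table")
    o = counts[np.ix_(keep_r, keep_c)].astype(float)
    if o.shape[0] < 2 or o.shape[1] < 2:
        raise DataError("independence test undefined for a 1 x k table")
    e = np.outer(o.sum(axis=1), o.sum(axis=0)) / o.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(o > 0, o * np.log(o / e), 0.0)
    G = float(2 * terms.sum())
    df = (o.shape[0] - 1) * (o.shape[1] - 1)
    return GTestResult(G=G, df=df, p=float(stats.chi2.sf(G, df)))


def outcome_proportions(records: pd.DataFrame) -> pd.DataFrame:
    """Outcome proportions per treatment x start_group cell (figure-style
    summary of convergence/divergence rates)."""
    counts = (
        records.groupby(["treatment", "start_group", "outcome"])
        .size()
        .rename("count")
        .reset_index()
    )
    totals = counts.groupby(["treatment", "start_group"])["count"].transform("sum")
    counts["proportion"] = counts["count"] / totals
    return counts
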