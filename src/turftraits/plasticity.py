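"""Relative plasticity of transplanted populations and warming/cooling tests.

For each transplanted turf, each species' plot-mean trait value ``T`` is
compared with the mean ``H`` of its conspecifics in the control-type plots of
the same origin block, via the simplified relative distance plasticity index

    P_R = | |H - T| / H |

The inner absolute value standardises the direction of the shift; the outer
one handles traits with negative values (delta 13C).  ``P_R`` is invariant to
positive rescaling of the trait (unit changes) but, intrinsically, not to
additive shifts.

Whether plasticity differs between warming and cooling transplants is tested
per trait with a stratified permutation test: treatment labels are permuted
within species x origin-site strata (mirroring the random-effect structure a
mixed model would use), and the observed difference of arm means is compared
with its permutation null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import SchemaError

logger = logging.getLogger(__name__)

#: plot treatment -> transplant-type label
TRANSPLANT_TYPE = {"warmed": "warming", "cooled": "cooling"}
CONTROL_TREATMENTS = ("control", "local_transplant")

RECORD_COLUMNS = [
    "species", "trait", "block", "origin_site", "destination_site",
    "treatment", "H", "T", "P_R", "n_home", "n_transplant", "undefined",
]


@dataclass(frozen=True)
class PlotPair:
    """One transplanted turf paired with the control-type plots of its
    origin block (both control plot types serve as the home reference)."""

    home_plots: tuple[str, ...]
    transplant_plot: str
    block: str
    origin_site: str
    destination_site: str
    treatment: str  # "warming" | "cooling"


def pair_plots(design: pd.DataFrame) -> list[PlotPair]:
    """Pair each warmed/cooled plot with its origin block's control plots.

    Transplant plots whose block has no control-type plot are dropped with a
    warning.  Duplicate plot ids raise a validation error.
    """
    if design["plot_id"].duplicated().any():
        dups = design.loc[design["plot_id"].duplicated(), "plot_id"].tolist()
        raise SchemaError(f"duplicate plot id(s) in design table: {dups}")
    controls = design[design["treatment"].isin(CONTROL_TREATMENTS)]
    home_by_block: dict[str, tuple[str, ...]] = {
        block: tuple(sub["plot_id"]) for block, sub in controls.groupby("block")
    }
    pairs: list[PlotPair] = []
    transplants = design[design["treatment"].isin(TRANSPLANT_TYPE)]
    for row in transplants.itertuples(index=False):
        home = home_by_block.get(row.block)
        if not home:
            logger.warning(
                "transplant plot %s (block %s) has no control plot; dropped",
                row.plot_id, row.block,
            )
            continue
        pairs.append(
            PlotPair(
                home_plots=home,
                transplant_plot=row.plot_id,
                block=row.block,
                origin_site=row.origin_site,
                destination_site=row.site,
                treatment=TRANSPLANT_TYPE[row.treatment],
            )
        )
    return pairs


def compute_plasticity(trait_table: pd.DataFrame, pairs: list[PlotPair]) -> pd.DataFrame:
    """P_R records for every species x trait x plot pair with data on both sides.

    Leaves are first averaged to plot-level species means; ``H`` is the mean
    of the home plots' means, ``T`` the transplanted plot's mean.  ``H = 0``
    yields an undefined-flagged record (excluded from tests) rather than an
    error.
    """
    plot_means = (
        trait_table.groupby(["plot_id", "species", "trait"])["value"]
        .agg(["mean", "size"])
        .reset_index()
    )
    by_plot = {pid: sub for pid, sub in plot_means.groupby("plot_id")}
    records = []
    for pair in pairs:
        homes = [by_plot[p] for p in pair.home_plots if p in by_plot]
        if not homes:
            continue
        home = pd.concat(homes)
        home_stats = home.groupby(["species", "trait"]).agg(
            H=("mean", "mean"), n_home=("size", "sum")
        )
        trans = by_plot.get(pair.transplant_plot)
        if trans is None:
            continue
        merged = trans.set_index(["species", "trait"]).join(home_stats, how="inner")
        for (species, trait), row in merged.iterrows():
            H, T = float(row["H"]), float(row["mean"])
            undefined = H == 0.0
            pr = np.nan if undefined else abs(abs(H - T) / H)
            records.append(
                (
                    species, trait, pair.block, pair.origin_site,
                    pair.destination_site, pair.treatment, H, T, pr,
                    int(row["n_home"]), int(row["size"]), undefined,
                )
            )
    return pd.DataFrame(records, columns=RECORD_COLUMNS)


def compare_plasticity(
    records: pd.DataFrame, n_perm: int = 999, seed: int | None = None
) -> pd.DataFrame:
    """Per-trait permutation test of mean P_R: cooling vs warming.

    Statistic: mean(P_R | cooling) - mean(P_R | warming).  The null is built
    by permuting treatment labels within species x origin-site strata;
    p = (1 + #{|null| >= |observed|}) / (1 + n_perm).  Traits with fewer than
    two records in either arm are skipped with a warning.
    """
    rng = np.random.default_rng(seed)
    rows = []
    usable = records.loc[~records["undefined"] & records["P_R"].notna()]
    for trait, sub in usable.groupby("trait", sort=True):
        is_cool = (sub["treatment"] == "cooling").to_numpy()
        pr = sub["P_R"].to_numpy(dtype=float)
        if is_cool.sum() < 2 or (~is_cool).sum() < 2:
            logger.warning("trait %s: fewer than 2 records in an arm; skipped", trait)
            continue
        mean_cool = pr[is_cool].mean()
        mean_warm = pr[~is_cool].mean()
        obs = mean_cool - mean_warm

        strata = (sub["species"] + "\x1f" + sub["origin_site"]).to_numpy()
        groups = [np.flatnonzero(strata == s) for s in np.unique(strata)]
        labels = is_cool.copy()
        n_cool = is_cool.sum()
        n_warm = (~is_cool).sum()
        hits = 0
        for _ in range(n_perm):
            for idx in groups:
                labels[idx] = labels[idx][rng.permutation(idx.size)]
            s_cool = pr[labels].sum()
            stat = s_cool / n_cool - (pr.sum() - s_cool) / n_warm
            if abs(stat) >= abs(obs) - 1e-12:
                hits += 1
        p = (1 + hits) / (1 + n_perm)
        rows.append((trait, mean_warm, mean_cool, obs, p, n_perm, seed))
    return pd.DataFrame(
        rows,
        columns=[
            "trait", "mean_PR_warming", "mean_PR_cooling", "statistic",
            "p_value", "n_perm", "seed",
        ],
    )


def log_plasticity(records: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Natural-log P_R for display; exact zeros are dropped and counted."""
    usable = records.loc[~records["undefined"]]
    zeros = int((usable["P_R"] == 0).sum())
    kept = usable.loc[usable["P_R"] > 0].copy()
    kept["log_P_R"] = np.log(kept["P_R"])
    return kept, zeros
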