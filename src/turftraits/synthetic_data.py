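"""Synthetic gradient + transplant datasets with known ground truth.

The generator emulates the structure of a reciprocal whole-community turf
transplant experiment along an elevation gradient:

* a balanced taxonomy (orders / families / genera / species);
* leaf trait values built from nested zero-mean Gaussian effects at the
  order, family, genus, species and population (species x site) levels plus
  within-population noise, with an optional directional trend along the
  gradient; multiplicative traits are generated on the log scale and
  exponentiated;
* biomass-structured communities per site (symmetric Dirichlet shares);
* transplanted turfs whose leaf expectation is linearly interpolated between
  the origin population mean and the destination community mean with a
  plasticity weight ``pi`` chosen by how far the population starts from the
  destination community mean (in community standard deviations).

Every output is a pure function of ``(config, seed)``; sub-streams are derived
deterministically so partial regeneration is stable.  The returned
:class:`SimulationTruth` records the exact population means, community
moments, variance proportions and per-transplant ``pi`` used, so each
downstream stage can be verified against known truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import (
    COMMUNITY_COLUMNS,
    DESIGN_COLUMNS,
    MULTIPLICATIVE_TRAITS,
    TRAIT_COLUMNS,
    TRAITS,
    ConfigError,
)

#: Variance-component levels, outermost first.
LEVELS: tuple[str, ...] = (
    "order", "family", "genus", "species", "population", "within",
)

#: Per-trait (grand mean, total SD) on the analysis scale, i.e. the natural-log
#: scale for the multiplicative traits LA/LT/LDMC and the measurement scale
#: otherwise.  Chosen to give realistic alpine-grassland values: e.g. SLA
#: around 150 cm2/g, LDMC around exp(-1.4) ~ 0.25 g/g, leaf N around 2.5 %.
TRAIT_SCALES: dict[str, tuple[float, float]] = {
    "LA": (1.6, 0.6),
    "LT": (-1.2, 0.4),
    "LDMC": (-1.4, 0.35),
    "SLA": (150.0, 40.0),
    "C": (45.0, 3.0),
    "N": (2.5, 0.8),
    "P": (0.2, 0.06),
    "CN": (20.0, 5.0),
    "NP": (12.0, 3.0),
    "d13C": (-28.0, 1.5),
    "d15N": (0.0, 2.0),
}

_DEFAULT_COMPONENTS = {
    "order": 0.1, "family": 0.1, "genus": 0.2,
    "species": 0.3, "population": 0.1, "within": 0.2,
}


@dataclass
class SimulationConfig:
    """Configuration of a synthetic gradient + transplant dataset.

    ``variance_components`` are variances on a standardised scale summing (by
    default) to one; per trait they are multiplied by the squared total SD
    from :data:`TRAIT_SCALES`.  ``plasticity_pi`` maps the start-distance
    class (``"near"``/``"far"``, thresholded at ``distance_threshold_sd``
    community standard deviations from the destination community mean) to the
    interpolation weight toward that mean; 0 means no plasticity, 1 full
    convergence, negative values model divergence.
    """

    n_orders: int = 4
    families_per_order: int = 3
    genera_per_family: int = 3
    species_per_genus: int = 3
    n_sites: int = 4
    leaves_per_species_site: int = 5
    variance_components: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_COMPONENTS)
    )
    trait_grand_mean: float | None = None  # override TRAIT_SCALES mean if set
    site_trend: float = 0.0                # standardised shift per site step
    dirichlet_alpha: float = 1.0           # community evenness
    plasticity_pi: dict[str, float] = field(
        default_factory=lambda: {"near": 0.0, "far": 0.8}
    )
    distance_threshold_sd: float = 1.0
    n_blocks: int = 7
    leaves_per_species_plot: int = 5
    n_focal_species: int = 10
    occupancy: float = 0.8                 # P(species occurs at a site)
    plot_total_biomass: float = 100.0      # g per plot
    traits: tuple[str, ...] = ("SLA",)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_orders", "families_per_order", "genera_per_family",
            "species_per_genus", "n_sites", "leaves_per_species_site",
            "n_blocks", "leaves_per_species_plot", "n_focal_species",
        ):
            if int(getattr(self, name)) < 1:
                raise ConfigError(f"{name} must be >= 1")
        missing = set(LEVELS) - set(self.variance_components)
        if missing:
            raise ConfigError(f"variance_components missing level(s): {sorted(missing)}")
        if any(v < 0 for v in self.variance_components.values()):
            raise ConfigError("variance components must be >= 0")
        if not 0 < self.occupancy <= 1:
            raise ConfigError("occupancy must be in (0, 1]")
        if self.dirichlet_alpha <= 0:
            raise ConfigError("dirichlet_alpha must be > 0")
        unknown = set(self.traits) - set(TRAITS)
        if unknown:
            raise ConfigError(f"unknown trait(s): {sorted(unknown)}")

    @property
    def sites(self) -> list[str]:
        """Site labels ordered by elevation (S1 lowest / warmest)."""
        return [f"S{i + 1}" for i in range(self.n_sites)]

    def trait_scale(self, trait: str) -> tuple[float, float]:
        mean, sd = TRAIT_SCALES[trait]
        if self.trait_grand_mean is not None:
            mean = self.trait_grand_mean
        return mean, sd

    def true_proportions(self) -> dict[str, float]:
        total = sum(self.variance_components.values())
        if total == 0:  # degenerate noise-free configuration
            return {k: 0.0 for k in self.variance_components}
        return {k: v / total for k, v in self.variance_components.items()}


@dataclass
class SimulationTruth:
    """Ground truth recorded while generating a dataset."""

    variance_proportions: dict[str, float]
    #: per (species, site, trait) analysis-scale population mean; `occupied`
    #: marks (species, site) pairs actually present in the community.
    population_means: pd.DataFrame
    #: per (site, trait) biomass-weighted community mean and SD (analysis scale)
    community_means: pd.DataFrame = field(default_factory=pd.DataFrame)
    #: per transplanted species x turf: start class and pi used
    pi: pd.DataFrame = field(default_factory=pd.DataFrame)

    def community_mean(self, site: str, trait: str) -> float:
        df = self.community_means
        row = df[(df["site"] == site) & (df["trait"] == trait)]
        return float(row["mean"].iloc[0])


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    taxonomy: pd.DataFrame
    traits: pd.DataFrame      # wild + experimental leaves, long format
    community: pd.DataFrame
    design: pd.DataFrame
    truth: SimulationTruth


# --------------------------------------------------------------------------
# RNG streams
# --------------------------------------------------------------------------

_STREAM = {"occupancy": 0, "community": 1, "experiment": 2, "traits": 10}


def _rng(cfg: SimulationConfig, purpose: str, index: int = 0) -> np.random.Generator:
    key = _STREAM[purpose] + index
    return np.random.default_rng(np.random.SeedSequence(entropy=cfg.seed, spawn_key=(key,)))


# --------------------------------------------------------------------------
# Taxonomy
# --------------------------------------------------------------------------

def simulate_taxonomy(cfg: SimulationConfig) -> pd.DataFrame:
    """Balanced taxonomy table with columns species/genus/family/order."""
    rows = []
    for o in range(cfg.n_orders):
        order = f"O{o + 1}"
        for f in range(cfg.families_per_order):
            fam = f"{order}F{f + 1}"
            for g in range(cfg.genera_per_family):
                gen = f"{fam}G{g + 1}"
                for s in range(cfg.species_per_genus):
                    rows.append((f"{gen}sp{s + 1}", gen, fam, order))
    return pd.DataFrame(rows, columns=["species", "genus", "family", "order"])


def _occupancy(cfg: SimulationConfig, n_species: int) -> np.ndarray:
    """Boolean (site x species) occurrence matrix; every site hosts >= 1 species."""
    rng = _rng(cfg, "occupancy")
    occ = rng.random((cfg.n_sites, n_species)) < cfg.occupancy
    for i in range(cfg.n_sites):
        if not occ[i].any():
            occ[i, rng.integers(n_species)] = True
    return occ


# --------------------------------------------------------------------------
# Wild trait data
# --------------------------------------------------------------------------

def simulate_trait_data(
    cfg: SimulationConfig, taxonomy: pd.DataFrame
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Generate wild-collected leaves and the associated ground truth.

    Each leaf value is ``grand_mean + b_order + b_family + b_genus + b_species
    + b_population + site_trend * site_index + eps`` on the analysis scale,
    each effect drawn from a zero-mean Gaussian with its configured variance
    (scaled by the trait's total SD).  Multiplicative traits are exponentiated
    afterwards.
    """
    n_species = len(taxonomy)
    occ = _occupancy(cfg, n_species)
    sites = cfg.sites
    sigma = {k: np.sqrt(v) for k, v in cfg.variance_components.items()}

    order_codes = taxonomy["order"].astype("category").cat.codes.to_numpy()
    family_codes = taxonomy["family"].astype("category").cat.codes.to_numpy()
    genus_codes = taxonomy["genus"].astype("category").cat.codes.to_numpy()

    all_rows: list[pd.DataFrame] = []
    truth_rows: list[pd.DataFrame] = []
    for t_index, trait in enumerate(cfg.traits):
        rng = _rng(cfg, "traits", t_index)
        grand, scale = cfg.trait_scale(trait)
        b_order = rng.normal(0, sigma["order"], order_codes.max() + 1)
        b_family = rng.normal(0, sigma["family"], family_codes.max() + 1)
        b_genus = rng.normal(0, sigma["genus"], genus_codes.max() + 1)
        b_species = rng.normal(0, sigma["species"], n_species)
        b_pop = rng.normal(0, sigma["population"], (cfg.n_sites, n_species))
        base = (
            b_order[order_codes] + b_family[family_codes]
            + b_genus[genus_codes] + b_species
        )
        # mu[site, species] on the analysis scale
        mu = grand + scale * (
            base[None, :] + b_pop + cfg.site_trend * np.arange(cfg.n_sites)[:, None]
        )

        n_leaves = cfg.leaves_per_species_site
        for si, site in enumerate(sites):
            present = np.flatnonzero(occ[si])
            eps = rng.normal(0, scale * sigma["within"], (present.size, n_leaves))
            values = mu[si, present][:, None] + eps
            if trait in MULTIPLICATIVE_TRAITS:
                values = np.exp(values)
            sp = taxonomy["species"].to_numpy()[present]
            frame = pd.DataFrame(
                {
                    "leaf_id": [
                        f"W.{site}.{s}.{trait}.{j + 1}"
                        for s in sp
                        for j in range(n_leaves)
                    ],
                    "species": np.repeat(sp, n_leaves),
                    "genus": np.repeat(taxonomy["genus"].to_numpy()[present], n_leaves),
                    "family": np.repeat(taxonomy["family"].to_numpy()[present], n_leaves),
                    "order": np.repeat(taxonomy["order"].to_numpy()[present], n_leaves),
                    "site": site,
                    "plot_id": f"{site}-wild",
                    "block": "",
                    "treatment": "wild",
                    "origin_site": site,
                    "trait": trait,
                    "value": values.ravel(),
                }
            )
            all_rows.append(frame)

        truth_rows.append(
            pd.DataFrame(
                {
                    "species": np.tile(taxonomy["species"].to_numpy(), cfg.n_sites),
                    "site": np.repeat(sites, n_species),
                    "trait": trait,
                    "mu": mu.ravel(),
                    "occupied": occ.ravel(),
                }
            )
        )

    traits_df = pd.concat(all_rows, ignore_index=True)[list(TRAIT_COLUMNS)]
    truth = SimulationTruth(
        variance_proportions=cfg.true_proportions(),
        population_means=pd.concat(truth_rows, ignore_index=True),
    )
    return traits_df, truth


# --------------------------------------------------------------------------
# Communities
# --------------------------------------------------------------------------

def simulate_communities(cfg: SimulationConfig, taxonomy: pd.DataFrame) -> pd.DataFrame:
    """Per-site species biomass from a symmetric Dirichlet, fixed plot total."""
    occ = _occupancy(cfg, len(taxonomy))
    rng = _rng(cfg, "community")
    rows = []
    for si, site in enumerate(cfg.sites):
        present = np.flatnonzero(occ[si])
        shares = rng.dirichlet(np.full(present.size, cfg.dirichlet_alpha))
        for idx, share in zip(present, shares):
            rows.append(
                (site, f"{site}-community", taxonomy["species"].iloc[idx],
                 share * cfg.plot_total_biomass)
            )
    return pd.DataFrame(rows, columns=list(COMMUNITY_COLUMNS))


def true_community_moments(
    cfg: SimulationConfig, truth: SimulationTruth, community: pd.DataFrame
) -> pd.DataFrame:
    """Biomass-weighted community mean and SD per site x trait (analysis scale).

    The SD is that of the leaf-level community distribution: biomass-weighted
    spread of population means plus within-population noise.
    """
    rows = []
    pop = truth.population_means
    for trait in cfg.traits:
        _, scale = cfg.trait_scale(trait)
        within_var = cfg.variance_components["within"] * scale**2
        sub = pop[pop["trait"] == trait]
        for site in cfg.sites:
            comm = community[community["site"] == site]
            merged = comm.merge(
                sub[sub["site"] == site], on="species", how="inner"
            )
            w = merged["biomass"].to_numpy()
            w = w / w.sum()
            mu = merged["mu"].to_numpy()
            mean = float(w @ mu)
            var = float(w @ (mu - mean) ** 2) + within_var
            rows.append((site, trait, mean, np.sqrt(var)))
    return pd.DataFrame(rows, columns=["site", "trait", "mean", "sd"])


# --------------------------------------------------------------------------
# Transplant experiment
# --------------------------------------------------------------------------

def simulate_transplant_experiment(
    cfg: SimulationConfig,
    taxonomy: pd.DataFrame,
    truth: SimulationTruth,
    community: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame, SimulationTruth]:
    """Generate experimental-plot leaves and the design table.

    Per origin site and block: a control and a local-transplant plot at the
    origin (distributionally identical), a "warmed" turf moved one site down
    the gradient and a "cooled" turf moved one site up (edge sites lack one of
    the two).  Transplanted leaf expectation is ``(1 - pi) * mu_origin + pi *
    destination community mean`` with within-population noise; ``pi`` depends
    on the start-distance class of the species at its origin.
    """
    if cfg.n_sites < 2:
        raise ConfigError("transplant experiment requires n_sites >= 2")
    if truth.community_means.empty:
        truth.community_means = true_community_moments(cfg, truth, community)

    rng = _rng(cfg, "experiment")
    sites = cfg.sites
    tax = taxonomy.set_index("species")
    pop = truth.population_means.set_index(["species", "site", "trait"])["mu"]
    comm_mean = truth.community_means.set_index(["site", "trait"])

    # focal species: most abundant occupants of each origin site
    focal: dict[str, list[str]] = {}
    for site in sites:
        comm = community[community["site"] == site]
        top = comm.sort_values("biomass", ascending=False)["species"]
        focal[site] = top.head(cfg.n_focal_species).tolist()

    design_rows: list[tuple] = []
    leaf_frames: list[pd.DataFrame] = []
    pi_rows: list[tuple] = []

    def emit_leaves(plot_id, site, block, treatment, origin_site, species, means):
        """Draw leaves for every focal species x trait in one plot."""
        n = cfg.leaves_per_species_plot
        for trait, mu_by_sp in means.items():
            _, scale = cfg.trait_scale(trait)
            noise_sd = scale * np.sqrt(cfg.variance_components["within"])
            vals = rng.normal(
                np.repeat(mu_by_sp, n), noise_sd, len(species) * n
            )
            if trait in MULTIPLICATIVE_TRAITS:
                vals = np.exp(vals)
            leaf_frames.append(
                pd.DataFrame(
                    {
                        "leaf_id": [
                            f"E.{plot_id}.{s}.{trait}.{j + 1}"
                            for s in species
                            for j in range(n)
                        ],
                        "species": np.repeat(species, n),
                        "genus": np.repeat(tax.loc[species, "genus"].to_numpy(), n),
                        "family": np.repeat(tax.loc[species, "family"].to_numpy(), n),
                        "order": np.repeat(tax.loc[species, "order"].to_numpy(), n),
                        "site": site,
                        "plot_id": plot_id,
                        "block": block,
                        "treatment": treatment,
                        "origin_site": origin_site,
                        "trait": trait,
                        "value": vals,
                    }
                )
            )

    for oi, origin in enumerate(sites):
        species = focal[origin]
        if not species:
            continue
        origin_means = {
            trait: np.array([pop[(s, origin, trait)] for s in species])
            for trait in cfg.traits
        }
        for b in range(1, cfg.n_blocks + 1):
            block = f"{origin}.B{b}"
            for treatment, suffix in (("control", "C"), ("local_transplant", "LT")):
                plot_id = f"{block}-{suffix}"
                design_rows.append((origin, block, plot_id, treatment, origin))
                emit_leaves(plot_id, origin, block, treatment, origin, species, origin_means)
            for treatment, step in (("warmed", -1), ("cooled", +1)):
                di = oi + step
                if not 0 <= di < cfg.n_sites:
                    continue
                dest = sites[di]
                plot_id = f"{block}-{'W' if step < 0 else 'K'}"
                design_rows.append((dest, block, plot_id, treatment, origin))
                shifted = {}
                for trait in cfg.traits:
                    row = comm_mean.loc[(dest, trait)]
                    dest_mu, dest_sd = float(row["mean"]), float(row["sd"])
                    mu0 = origin_means[trait]
                    dist = np.abs(mu0 - dest_mu) / dest_sd
                    classes = np.where(
                        dist > cfg.distance_threshold_sd, "far", "near"
                    )
                    pis = np.array([cfg.plasticity_pi[c] for c in classes])
                    shifted[trait] = (1 - pis) * mu0 + pis * dest_mu
                    if b == 1:  # pi depends only on (species, origin, dest, trait)
                        for s, c, p in zip(species, classes, pis):
                            pi_rows.append((s, trait, origin, dest, treatment, c, p))
                emit_leaves(plot_id, dest, block, treatment, origin, species, shifted)

    design = pd.DataFrame(design_rows, columns=list(DESIGN_COLUMNS))
    exp_traits = pd.concat(leaf_frames, ignore_index=True)[list(TRAIT_COLUMNS)]
    truth.pi = pd.DataFrame(
        pi_rows,
        columns=[
            "species", "trait", "origin_site", "destination_site",
            "treatment", "start_class", "pi",
        ],
    )
    return exp_traits, design, truth


# --------------------------------------------------------------------------
# One-call dataset
# --------------------------------------------------------------------------

def simulate_dataset(cfg: SimulationConfig) -> SimulatedDataset:
    """Generate a complete dataset (wild + experimental leaves, community,
    design, truth) from one configuration."""
    taxonomy = simulate_taxonomy(cfg)
    wild, truth = simulate_trait_data(cfg, taxonomy)
    community = simulate_communities(cfg, taxonomy)
    truth.community_means = true_community_moments(cfg, truth, community)
    exp, design, truth = simulate_transplant_experiment(cfg, taxonomy, truth, community)
    traits = pd.concat([wild, exp], ignore_index=True)
    return SimulatedDataset(
        config=cfg, taxonomy=taxonomy, traits=traits,
        community=community, design=design, truth=truth,
    )


def config_from_dict(d: dict) -> SimulationConfig:
    known = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(d) - known
    if unknown:
        raise ConfigError(f"unknown simulate key(s): {sorted(unknown)}")
    d = dict(d)
    if "traits" in d:
        d["traits"] = tuple(d["traits"])
    return SimulationConfig(**d)
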