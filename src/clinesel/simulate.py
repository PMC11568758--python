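"""Synthetic cohorts with the statistical structure the pipeline assumes.

Four generators:

* a forward discrete-generation Wright-Fisher haplotype simulator with
  additive selection at one focal site, uniform recombination, population
  splits and optional island-model migration — feeds the F_ST, LD and
  EHH/iHS analyses;
* a phylogenetic cline generator: logit allele frequencies = intercept +
  slope x latitude + Brownian motion on a population tree — feeds PGLS;
* a negative-binomial single-nucleus expression cohort in which a designated
  trans gene set is shifted in carriers of a risk allele — feeds the marker /
  differential-expression / module-score analyses;
* a BMI-discordant twin cohort where a Gaussian copula ties one gene's
  expression to adipocyte diameter at a target Spearman correlation.

Everything is seeded and deterministic; identical seeds give identical
output byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .haplotypes import HaplotypePanel

__all__ = [
    "PopulationSpec",
    "SimulationConfig",
    "PanelSet",
    "simulate_haplotype_panel",
    "simulate_cline",
    "simulate_expression_cohort",
    "simulate_twin_cohort",
]


@dataclass
class PopulationSpec:
    """One population in the haplotype simulation.

    ``split_parent``/``split_generation`` describe a tree of population
    splits: a population with a parent comes into existence at the stated
    generation by Wright-Fisher sampling from the parent's haplotype pool.
    """

    name: str
    diploid_size: int
    latitude: float = 0.0
    mean_annual_temp: float = 10.0
    split_parent: str | None = None
    split_generation: int = 0

    def __post_init__(self) -> None:
        if self.diploid_size < 2:
            raise ValueError(f"{self.name}: diploid_size must be >= 2")
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"{self.name}: latitude must lie in [-90, 90]")


@dataclass
class SimulationConfig:
    n_sites: int = 1000
    focal_site_index: int = 500
    selection_coefficient: float = 0.0      # additive advantage per derived allele
    recombination_rate: float = 1e-8        # per bp per generation
    generations: int = 100
    seed: int = 0
    bp_per_site: int = 1000
    cm_per_mb: float = 1.0                  # uniform genetic map
    initial_freqs: np.ndarray | None = None
    init_freq_range: tuple[float, float] = (0.05, 0.95)
    initial_focal_freq: float | None = None
    focal_single_origin: bool = False       # seed all derived focal copies on one founder haplotype
    sweep_start_generation: int | None = None  # selection (and single-origin re-seeding) begins here
    migration_rate: float = 0.0             # island-model fraction of migrant gametes per generation

    def __post_init__(self) -> None:
        if not 0 <= self.focal_site_index < self.n_sites:
            raise ValueError("focal_site_index out of range")
        per_interval = self.recombination_rate * self.bp_per_site
        if not 0.0 <= per_interval <= 0.5:
            raise ValueError(
                f"recombination_rate x bp_per_site = {per_interval} per interval; "
                "must lie in [0, 0.5]"
            )
        if not 0.0 <= self.migration_rate < 1.0:
            raise ValueError("migration_rate must lie in [0, 1)")

    @property
    def positions_bp(self) -> np.ndarray:
        return 1 + np.arange(self.n_sites, dtype=np.int64) * self.bp_per_site

    @property
    def positions_cm(self) -> np.ndarray:
        return self.positions_bp * 1e-6 * self.cm_per_mb

    @property
    def total_morgans(self) -> float:
        return self.recombination_rate * self.bp_per_site * (self.n_sites - 1)


@dataclass
class PanelSet:
    panels: dict[str, HaplotypePanel]
    config: SimulationConfig
    populations: list[PopulationSpec]
    focal_lost: dict[str, bool] = field(default_factory=dict)

    def site_frequency_table(self):
        from .popgen import SiteFrequencyTable

        return SiteFrequencyTable.from_panels(self.panels)


def _founder_pool(cfg: SimulationConfig, n_hap: int, rng: np.random.Generator) -> np.ndarray:
    """Initial haplotypes at linkage equilibrium given per-site derived freqs."""
    if cfg.initial_freqs is not None:
        freqs = np.asarray(cfg.initial_freqs, dtype=float)
        if freqs.shape != (cfg.n_sites,):
            raise ValueError("initial_freqs must have one entry per site")
    else:
        lo, hi = cfg.init_freq_range
        freqs = rng.uniform(lo, hi, size=cfg.n_sites)
    if cfg.initial_focal_freq is not None:
        freqs = freqs.copy()
        freqs[cfg.focal_site_index] = cfg.initial_focal_freq
    H = (rng.random((n_hap, cfg.n_sites)) < freqs).astype(np.int8)
    if cfg.focal_single_origin and cfg.sweep_start_generation is None:
        # emulate a variant that arose once: all derived copies share one
        # founder background
        k = int(round(freqs[cfg.focal_site_index] * n_hap))
        k = max(k, 1)
        origin = int(rng.integers(n_hap))
        H[:, cfg.focal_site_index] = 0
        background = H[origin].copy()
        carriers = rng.choice(n_hap, size=k, replace=False)
        H[carriers] = background
        H[carriers, cfg.focal_site_index] = 1
    return H


def _reproduce(
    pool: np.ndarray,
    n_offspring_hap: int,
    s: float,
    focal: int,
    lam: float,
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """One Wright-Fisher generation: fitness-weighted parent sampling plus
    recombinant gamete formation (Poisson crossovers, uniform in genetic
    distance since the map is uniform)."""
    n_par_hap = pool.shape[0]
    n_par_ind = n_par_hap // 2
    dosage = pool[0::2, focal].astype(float) + pool[1::2, focal]
    w = 1.0 + s * dosage
    w = np.clip(w, 0.0, None)
    if w.sum() <= 0:
        w = np.ones_like(w)
    p = w / w.sum()
    parents = rng.choice(n_par_ind, size=n_offspring_hap, p=p)
    start = rng.integers(0, 2, size=n_offspring_hap)
    hap_a = 2 * parents + start
    hap_b = 2 * parents + (1 - start)
    offspring = pool[hap_a].copy()
    n_xo = rng.poisson(lam, size=n_offspring_hap)
    for i in np.flatnonzero(n_xo):
        # crossover points uniform over the (uniform-rate) map
        cuts = np.sort(rng.integers(1, cfg.n_sites, size=n_xo[i]))
        src = (np.searchsorted(cuts, np.arange(cfg.n_sites), side="right") % 2).astype(bool)
        offspring[i, src] = pool[hap_b[i], src]
    return offspring


def simulate_haplotype_panel(
    populations: list[PopulationSpec], config: SimulationConfig
) -> PanelSet:
    """Forward Wright-Fisher simulation of phased haplotype panels.

    Root populations (no ``split_parent``) are founded at generation 0 from
    independent linkage-equilibrium pools; daughter populations are founded
    at their split generation by sampling gametes from the parent pool, so
    drift after the split generates F_ST between them.  Loss of the focal
    derived allele is flagged per population, never raised.
    """
    if not populations:
        raise ValueError("at least one population required")
    names = [p.name for p in populations]
    if len(set(names)) != len(names):
        raise ValueError("population names must be unique")
    by_name = {p.name: p for p in populations}
    for p in populations:
        if p.split_parent is not None and p.split_parent not in by_name:
            raise ValueError(f"{p.name}: unknown split_parent {p.split_parent!r}")
    # reject cycles by walking each lineage to a root
    for p in populations:
        seen, cur = set(), p
        while cur.split_parent is not None:
            if cur.name in seen:
                raise ValueError("split graph contains a cycle")
            seen.add(cur.name)
            cur = by_name[cur.split_parent]

    rng = np.random.default_rng(config.seed)
    lam = config.total_morgans
    focal = config.focal_site_index
    pools: dict[str, np.ndarray] = {}
    shared_founder: np.ndarray | None = None
    roots = [p for p in populations if p.split_parent is None]
    if roots:
        # all root populations sample from one ancestral founder pool so that
        # "split at generation 0" has its textbook meaning
        n_founder = 2 * max(p.diploid_size for p in roots)
        shared_founder = _founder_pool(config, n_founder, rng)
    for p in roots:
        pools[p.name] = _reproduce(
            shared_founder, 2 * p.diploid_size, 0.0, focal, lam, config, rng
        ) if len(roots) > 1 else shared_founder[: 2 * p.diploid_size].copy()

    def seed_single_origin(pool: np.ndarray) -> np.ndarray:
        """Re-seed the focal derived allele as identical copies of one
        resident haplotype — a variant that arose once and has just reached
        its starting frequency."""
        n_hap = pool.shape[0]
        p0 = config.initial_focal_freq if config.initial_focal_freq is not None else 0.05
        k = max(int(round(p0 * n_hap)), 1)
        pool = pool.copy()
        origin = int(rng.integers(n_hap))
        background = pool[origin].copy()
        pool[:, focal] = 0
        rows = rng.choice(n_hap, size=k, replace=False)
        pool[rows] = background
        pool[rows, focal] = 1
        return pool

    s_full = config.selection_coefficient
    sweep_start = config.sweep_start_generation
    for gen in range(config.generations):
        s = s_full if (sweep_start is None or gen >= sweep_start) else 0.0
        if sweep_start is not None and gen == sweep_start and config.focal_single_origin:
            for name in list(pools):
                pools[name] = seed_single_origin(pools[name])
        for p in populations:
            if p.split_parent is not None and p.split_generation == gen and p.name not in pools:
                parent_pool = pools.get(p.split_parent)
                if parent_pool is None:
                    raise ValueError(
                        f"{p.name} splits from {p.split_parent} before the parent exists"
                    )
                pools[p.name] = _reproduce(
                    parent_pool, 2 * p.diploid_size, s, focal, lam, config, rng
                )
        new_pools = {}
        extant = list(pools)
        for name in extant:
            pool = pools[name]
            if config.migration_rate > 0 and len(extant) > 1:
                n_mig = rng.binomial(pool.shape[0], config.migration_rate)
                if n_mig > 0:
                    others = [pools[o] for o in extant if o != name]
                    donor = np.vstack(others)
                    idx = rng.choice(donor.shape[0], size=n_mig, replace=donor.shape[0] < n_mig)
                    pool = pool.copy()
                    rows = rng.choice(pool.shape[0], size=n_mig, replace=False)
                    pool[rows] = donor[idx]
            new_pools[name] = _reproduce(
                pool, pool.shape[0], s, focal, lam, config, rng
            )
        pools.update(new_pools)

    missing = [p.name for p in populations if p.name not in pools]
    if missing:
        raise ValueError(f"populations never founded (split_generation beyond run): {missing}")

    panels = {}
    focal_lost = {}
    site_ids = [f"s{i}" for i in range(config.n_sites)]
    for p in populations:
        panels[p.name] = HaplotypePanel(
            alleles=pools[p.name],
            positions_bp=config.positions_bp,
            positions_cm=config.positions_cm,
            site_ids=list(site_ids),
        )
        focal_lost[p.name] = bool(pools[p.name][:, focal].sum() == 0)
    return PanelSet(panels=panels, config=config, populations=list(populations),
                    focal_lost=focal_lost)


def simulate_cline(
    tree,
    latitudes: dict[str, float] | pd.Series,
    slope: float,
    bm_sigma2: float,
    intercept: float,
    seed: int,
    temperatures: dict[str, float] | pd.Series | None = None,
) -> pd.DataFrame:
    """Allele frequencies on a latitudinal cline with phylogenetic noise.

    frequency_i = inverse-logit(intercept + slope * latitude_i + b_i) with
    b ~ MVN(0, bm_sigma2 * C) and C the Brownian-motion covariance of the
    tree (shared root-to-tip branch length).  Frequencies are strictly
    inside (0, 1) because the logistic link never saturates.

    If no temperatures are given, a lapse-rate surrogate
    temp = 25 - 0.45 * |latitude| + N(0, 2) is drawn (degrees C).
    """
    from .cline import bm_covariance

    if bm_sigma2 < 0:
        raise ValueError("bm_sigma2 must be >= 0")
    lat = pd.Series(latitudes, dtype=float)
    tips = sorted(t.name for t in tree.tips())
    if sorted(lat.index) != tips:
        raise ValueError("latitude labels do not match tree tip labels")
    rng = np.random.default_rng(seed)
    cov = bm_covariance(tree).loc[lat.index, lat.index].to_numpy()
    if bm_sigma2 > 0:
        L = np.linalg.cholesky(bm_sigma2 * cov + 1e-12 * np.eye(len(lat)))
        b = L @ rng.standard_normal(len(lat))
    else:
        b = np.zeros(len(lat))
    z = intercept + slope * lat.to_numpy() + b
    freq = expit(z)
    if temperatures is None:
        temp = 25.0 - 0.45 * np.abs(lat.to_numpy()) + rng.normal(0.0, 2.0, len(lat))
    else:
        temp = pd.Series(temperatures, dtype=float).loc[lat.index].to_numpy()
    return pd.DataFrame(
        {
            "population": lat.index,
            "frequency": freq,
            "latitude_deg": lat.to_numpy(),
            "temp_c": temp,
        }
    ).set_index("population")


def _nb_counts(mean: np.ndarray, dispersion: float, rng: np.random.Generator) -> np.ndarray:
    """Gamma-Poisson negative binomial with size (inverse-dispersion) theta:
    var = mu + mu^2 / theta."""
    lam = rng.gamma(shape=dispersion, scale=np.maximum(mean, 1e-12) / dispersion)
    return rng.poisson(lam)


def simulate_expression_cohort(
    n_donors: int = 60,
    cells_per_donor: int = 200,
    n_genes: int = 300,
    trans_set: list[str] | None = None,
    effect: float = 2.0,
    risk_maf: float = 0.3,
    dispersion: float = 2.0,
    seed: int = 0,
    cell_type_props: dict[str, float] | None = None,
    marker_spec: dict[str, dict[str, float]] | None = None,
    trans_cell_type: str = "adipocyte",
    base_mean: float = 0.5,
    donor_sd: float = 0.1,
    female_prop: float = 0.5,
    max_retries: int = 100,
    sex_specific_effect: dict[str, float] | None = None,
):
    """Donor-structured single-nucleus counts with a planted trans effect.

    Donor genotypes at the risk variant are drawn under Hardy-Weinberg at
    ``risk_maf``; carriers (>= 1 risk allele) have the mean expression of
    every ``trans_set`` gene multiplied by ``effect`` in cells of
    ``trans_cell_type``.  ``marker_spec`` plants cell-type markers:
    {cell_type: {gene: fold}} multiplies that gene's mean in that type.
    A mild lognormal per-donor scaling (sd ``donor_sd`` on the log scale)
    induces within-donor correlation, which is why permutation tests must
    shuffle labels at the donor level.  ``sex_specific_effect`` optionally
    overrides ``effect`` per sex ({"F": fold, "M": fold}).
    """
    from .trans_expr import CellExpressionMatrix

    if effect <= 0:
        raise ValueError("effect must be > 0")
    if not 0 < risk_maf < 1:
        raise ValueError("risk_maf must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    genes = [f"g{i:04d}" for i in range(n_genes)]
    if trans_set is None:
        trans_set = genes[:12]
    missing = set(trans_set) - set(genes)
    if missing:
        raise ValueError(f"trans_set genes not in panel: {sorted(missing)}")
    if cell_type_props is None:
        cell_type_props = {"adipocyte": 1.0}
    types = list(cell_type_props)
    props = np.array([cell_type_props[t] for t in types], dtype=float)
    props = props / props.sum()

    hw = np.array([(1 - risk_maf) ** 2, 2 * risk_maf * (1 - risk_maf), risk_maf**2])
    for attempt in range(max_retries):
        genotypes = rng.choice(3, size=n_donors, p=hw)
        carrier = genotypes >= 1
        if carrier.any() and (~carrier).any():
            break
    else:
        raise RuntimeError(
            f"degenerate cohort after {max_retries} genotype draws "
            "(all carriers or all non-carriers)"
        )

    sex = np.where(rng.random(n_donors) < female_prop, "F", "M")
    age = rng.integers(30, 61, size=n_donors)
    donor_ids = [f"d{i:03d}" for i in range(n_donors)]
    donors = pd.DataFrame(
        {"risk_carrier": carrier, "sex": sex, "age": age}, index=pd.Index(donor_ids, name="donor_id")
    )

    gene_means = base_mean * rng.lognormal(0.0, 1.0, size=n_genes)
    donor_scale = rng.lognormal(0.0, donor_sd, size=n_donors)
    trans_idx = np.array([genes.index(g) for g in trans_set], dtype=int)

    n_cells = n_donors * cells_per_donor
    counts = np.empty((n_cells, n_genes), dtype=np.int64)
    cell_type = np.empty(n_cells, dtype=object)
    cell_donor = np.empty(n_cells, dtype=object)
    row = 0
    for d in range(n_donors):
        t_idx = rng.choice(len(types), size=cells_per_donor, p=props)
        for ti, t in enumerate(types):
            n_t = int((t_idx == ti).sum())
            if n_t == 0:
                continue
            mu = gene_means * donor_scale[d]
            if marker_spec and t in marker_spec:
                mu = mu.copy()
                for g, fold in marker_spec[t].items():
                    mu[genes.index(g)] *= fold
            if carrier[d] and (t == trans_cell_type or trans_cell_type not in types):
                eff = effect
                if sex_specific_effect is not None:
                    eff = sex_specific_effect.get(sex[d], effect)
                mu = mu.copy()
                mu[trans_idx] *= eff
            block = _nb_counts(np.broadcast_to(mu, (n_t, n_genes)), dispersion, rng)
            counts[row : row + n_t] = block
            cell_type[row : row + n_t] = t
            cell_donor[row : row + n_t] = donor_ids[d]
            row += n_t
    cells = pd.DataFrame(
        {"cell_type": cell_type, "donor_id": cell_donor},
        index=pd.Index([f"c{i:06d}" for i in range(n_cells)], name="cell_id"),
    )
    # drop empty droplets, as nucleus QC would
    keep = counts.sum(axis=1) > 0
    return CellExpressionMatrix(
        counts=counts[keep], genes=genes, cells=cells.loc[keep], donors=donors
    )


def simulate_twin_cohort(
    n_pairs: int = 44,
    target_rho: float = 0.55,
    seed: int = 0,
    n_genes: int = 10,
    focal_gene: str = "g0000",
    rho_by_group: dict[str, float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """BMI-discordant twin pairs with one gene copula-linked to adipocyte size.

    Returns ``(expression, samples)``: expression is individuals x genes
    (TPM-like, lognormal margins); samples carries pair_id, group
    (higher-BMI | lower-BMI) and adipocyte diameter (um).  The focal gene's
    rank correlation with diameter targets ``target_rho`` via the Gaussian
    copula identity rho_S = (6/pi) asin(r/2); other genes are independent of
    diameter.  ``rho_by_group`` plants group-specific correlations instead.
    """
    if n_pairs < 3:
        raise ValueError("n_pairs must be >= 3 for a usable correlation")
    if not -1 < target_rho < 1:
        raise ValueError("target_rho must lie in (-1, 1)")
    rng = np.random.default_rng(seed)
    genes = [f"g{i:04d}" for i in range(n_genes)]
    if focal_gene not in genes:
        raise ValueError(f"focal_gene {focal_gene!r} not among generated genes")
    n_ind = 2 * n_pairs
    pair_id = np.repeat([f"pair{i:03d}" for i in range(n_pairs)], 2)
    group = np.tile(["higher-BMI", "lower-BMI"], n_pairs)
    ind_id = [f"t{i:03d}" for i in range(n_ind)]

    def pearson_for(rho_s: float) -> float:
        return 2.0 * np.sin(np.pi * rho_s / 6.0)

    z_genes = rng.standard_normal((n_ind, n_genes))
    z_diam = rng.standard_normal(n_ind)
    zg = z_genes[:, genes.index(focal_gene)]
    if rho_by_group is None:
        r = pearson_for(target_rho)
        z_diam = r * zg + np.sqrt(1 - r**2) * z_diam
    else:
        for g_name, rho_s in rho_by_group.items():
            mask = group == g_name
            r = pearson_for(rho_s)
            z_diam[mask] = r * zg[mask] + np.sqrt(1 - r**2) * z_diam[mask]
    expr = pd.DataFrame(
        np.exp(2.0 + 0.8 * z_genes),  # TPM-like positive scale
        index=pd.Index(ind_id, name="individual"),
        columns=genes,
    )
    samples = pd.DataFrame(
        {
            "pair_id": pair_id,
            "group": group,
            "diameter_um": 85.0 + 12.0 * z_diam,
        },
        index=pd.Index(ind_id, name="individual"),
    )
    return expr, samples
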