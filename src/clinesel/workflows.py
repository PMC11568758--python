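"""End-to-end study workflows on synthetic cohorts.

Each function wires the generators to one analysis arm at the problem sizes
used throughout the project (documented in docs/methods.md) and returns the
summary quantities a study report would print.  The numbered scripts under
``analysis/`` and ``scripts/acceptance.py`` are thin wrappers around these.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import adipose, cline, haplotypes, popgen, simulate, trans_expr

__all__ = [
    "neutral_ihs_calibration",
    "sweep_detection_trial",
    "sweep_detection_power",
    "fst_matched_null_trial",
    "random_population_tree",
    "cline_slope_recovery",
    "lrt_type_one_error",
    "cline_full_analysis",
    "trans_expression_analysis",
    "twin_size_analysis",
]

# Scaled-down study conditions for selection runs: one population of 300
# diploids, a ~3 Mb / 3,000-SNP region at 2 cM/Mb, 600 neutral generations of
# pedigree depth, then a 50-generation partial sweep of a single-origin
# derived allele.
SWEEP = dict(n_sites=3000, diploids=300, burn_in=600, sweep_generations=50,
             recombination_rate=2e-8, s=0.05, initial_freq=0.05)


def neutral_ihs_calibration(
    seed: int,
    n_sites: int = 12_000,
    diploids: int = 100,
    generations: int = 300,
    n_bins: int = 50,
) -> dict:
    """Genome-scan calibration under neutrality.

    Simulates one neutral Wright-Fisher panel, scans every site with
    MAF >= 0.05, standardizes iHS in derived-frequency bins and summarizes
    the pooled standardized distribution (mean, SD, fraction |iHS| >= 2).
    """
    cfg = simulate.SimulationConfig(
        n_sites=n_sites, focal_site_index=n_sites // 2, generations=generations,
        seed=seed,
    )
    ps = simulate.simulate_haplotype_panel(
        [simulate.PopulationSpec("NEU", diploids)], cfg
    )
    panel = ps.panels["NEU"]
    records = haplotypes.ihs_scan(panel)
    haplotypes.standardize_ihs(records, n_bins=n_bins)
    std = np.array([r.ihs_std for r in records if r.ihs_std is not None])
    return {
        "n_sites_scanned": len(records),
        "n_standardized": len(std),
        "mean": float(std.mean()),
        "sd": float(std.std(ddof=0)),
        "tail_fraction": float(np.mean(np.abs(std) >= 2.0)),
    }


def _sweep_config(seed: int, s: float, single_origin: bool, sweep_start, **kw):
    p = {**SWEEP, **kw}
    return simulate.SimulationConfig(
        n_sites=p["n_sites"],
        focal_site_index=p["n_sites"] // 2,
        generations=p["burn_in"] + p["sweep_generations"],
        seed=seed,
        selection_coefficient=s,
        initial_focal_freq=p["initial_freq"],
        focal_single_origin=single_origin,
        sweep_start_generation=sweep_start,
        recombination_rate=p["recombination_rate"],
        cm_per_mb=p["recombination_rate"] * 1e8,
    )


def neutral_background_records(
    seed: int, n_replicates: int = 6, scan_step: int = 2
) -> list:
    """Pooled iHS records from neutral replicate panels — the scaled-down
    analogue of the chromosome-wide SNP background used for frequency-bin
    standardization and percentile ranking."""
    L = SWEEP["n_sites"]
    records = []
    for j in range(n_replicates):
        cfg = _sweep_config(7_000_000 + 1_000 * seed + j, 0.0, False, None)
        pn = simulate.simulate_haplotype_panel(
            [simulate.PopulationSpec("NEU", SWEEP["diploids"])], cfg
        ).panels["NEU"]
        records += haplotypes.ihs_scan(pn, sites=np.arange(0, L, scan_step))
    return records


def sweep_detection_trial(
    seed: int,
    background_records: list | None = None,
    n_bins: int = 8,
    freq_window: tuple[float, float] = (0.35, 0.85),
    max_retries: int = 12,
    decay_threshold: float = 0.25,
) -> dict | None:
    """One selection-scan trial: a partial sweep ranked against a neutral
    background.

    A single-origin derived allele sweeps (s = 0.05) for the last 50
    generations after 600 generations of neutral history; trials are retried
    (seed-offset) until the focal frequency lands in ``freq_window``, since
    iHS is undefined for lost or near-fixed alleles.  The focal iHS is
    standardized within derived-frequency bins of the neutral background and
    ranked against it.  EHH decay distances use ``decay_threshold`` = 0.25
    because in these shallow panels the EHH floor sits well above the 0.05
    used on real data (see docs/methods.md).
    """
    L = SWEEP["n_sites"]
    burn = SWEEP["burn_in"]
    if background_records is None:
        background_records = neutral_background_records(seed)

    panel = None
    for k in range(max_retries):
        cfg = _sweep_config(seed + 100_000 * k, SWEEP["s"], True, burn)
        cand = simulate.simulate_haplotype_panel(
            [simulate.PopulationSpec("SEL", SWEEP["diploids"])], cfg
        ).panels["SEL"]
        f0 = cand.derived_frequency(L // 2)
        if freq_window[0] <= f0 <= freq_window[1]:
            panel = cand
            break
    if panel is None:
        return None

    focal = haplotypes.unstandardized_ihs(panel, L // 2)
    haplotypes.standardize_ihs(list(background_records) + [focal], n_bins=n_bins)
    if focal.ihs_std is None:
        return None
    background = np.array(
        [r.ihs_std for r in background_records if r.ihs_std is not None]
    )
    decay = {}
    for allele, name in ((haplotypes.DERIVED, "derived"), (haplotypes.ANCESTRAL, "ancestral")):
        curve = haplotypes.ehh(panel, L // 2, allele, stop_below=decay_threshold)
        d = haplotypes.ehh_decay_distance(curve, threshold=decay_threshold)
        decay[name] = d["left"][0] + d["right"][0]
    return {
        "focal_freq": focal.derived_freq,
        "ihs_unstd": focal.ihs_unstd,
        "ihs_std": focal.ihs_std,
        "percentile": haplotypes.ihs_percentile(focal.ihs_std, background),
        "decay_bp_derived": decay["derived"],
        "decay_bp_ancestral": decay["ancestral"],
    }


def sweep_detection_power(seed: int, n_seeds: int = 20) -> dict:
    """Fraction of sweep trials ranking above the 90th |iHS| percentile with
    negative sign, and fraction with longer derived-allele EHH decay.  One
    pooled neutral background reference is shared by all trials."""
    background = neutral_background_records(seed)
    trials = []
    for i in range(n_seeds):
        t = sweep_detection_trial(seed * 1_000 + i, background_records=background)
        if t is not None:
            trials.append(t)
    n = len(trials)
    detected = sum(1 for t in trials if t["ihs_std"] < 0 and t["percentile"] > 90)
    longer = sum(1 for t in trials if t["decay_bp_derived"] > t["decay_bp_ancestral"])
    return {
        "n_trials": n,
        "detection_rate": detected / n if n else float("nan"),
        "derived_decay_longer_rate": longer / n if n else float("nan"),
        "mean_ihs_std": float(np.mean([t["ihs_std"] for t in trials])) if n else float("nan"),
        "trials": trials,
    }


def fst_matched_null_trial(
    seed: int,
    n_candidates: int = 2_000,
    k: int = 1_000,
    diploids: int = 60,
    split_generations: int = 60,
) -> dict:
    """Two drifting populations; F_ST of a focal site ranked against its
    frequency-matched empirical null."""
    cfg = simulate.SimulationConfig(
        n_sites=n_candidates + 1, focal_site_index=0, generations=split_generations,
        seed=seed, bp_per_site=100, init_freq_range=(0.1, 0.9),
    )
    ps = simulate.simulate_haplotype_panel(
        [simulate.PopulationSpec("FIN", diploids), simulate.PopulationSpec("OTH", diploids)],
        cfg,
    )
    g1 = popgen.genotypes_from_panel(ps.panels["FIN"])
    g2 = popgen.genotypes_from_panel(ps.panels["OTH"])
    fst = popgen.weir_cockerham_fst(g1, g2)
    sft = ps.site_frequency_table()
    pooled_freq = ((sft.df["FIN_freq"] + sft.df["OTH_freq"]) / 2.0).to_numpy()
    # focal = first site still segregating at mid frequency with a defined F_ST
    ok = np.flatnonzero(
        np.isfinite(fst["fst"].to_numpy()) & (pooled_freq > 0.2) & (pooled_freq < 0.8)
    )
    if ok.size == 0:
        raise RuntimeError("no usable focal site in this draw")
    focal_idx = int(ok[0])
    others = np.setdiff1d(np.arange(len(pooled_freq)), [focal_idx])
    cand = pd.DataFrame(
        {"freq": pooled_freq[others], "fst": fst["fst"].to_numpy()[others]},
        index=sft.df.index[others],
    )
    null = popgen.matched_empirical_p(
        float(fst["fst"].iloc[focal_idx]), float(pooled_freq[focal_idx]), cand, k=k,
        focal_site=str(sft.df.index[focal_idx]),
    )
    return {"focal_fst": null.focal_fst, "empirical_p": null.p, "k": null.k}


def random_population_tree(seed: int, n_pops: int = 22) -> "cline.TreeNode":
    """A neighbor-joining tree over random-geometry population distances,
    standing in for an F_ST-derived population tree."""
    rng = np.random.default_rng(seed)
    pts = rng.normal(size=(n_pops, 3))
    D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
    labels = [f"P{i}" for i in range(n_pops)]
    return cline.neighbor_joining(pd.DataFrame(D, index=labels, columns=labels))


def _latitudes(tree) -> dict[str, float]:
    tips = sorted(t.name for t in tree.tips())
    return {t: float(v) for t, v in zip(tips, np.linspace(0.0, 65.0, len(tips)))}


def cline_slope_recovery(
    seed: int,
    slope: float = 0.08,
    bm_sigma2: float = 0.1,
    n_replicates: int = 500,
) -> dict:
    """PGLS latitude-slope recovery over replicate cline simulations."""
    tree = random_population_tree(seed)
    lat = _latitudes(tree)
    slopes = []
    for i in range(n_replicates):
        ds = simulate.simulate_cline(
            tree, lat, slope=slope, bm_sigma2=bm_sigma2, intercept=-2.0,
            seed=seed * 10_000 + i,
        )
        fits = cline.fit_cline_models(ds, tree, logit_scale=True)
        slopes.append(float(fits["full"].params["latitude"]))
    slopes = np.array(slopes)
    return {
        "true_slope": slope,
        "mean_slope": float(slopes.mean()),
        "sd_slope": float(slopes.std(ddof=1)),
        "n": n_replicates,
        "sign_recovery_rate": float(np.mean(np.sign(slopes) == np.sign(slope))),
    }


def lrt_type_one_error(
    seed: int, bm_sigma2: float = 0.1, n_replicates: int = 2_000, alpha: float = 0.05
) -> dict:
    """Rejection rate of the full-vs-null PGLS comparison under a flat cline."""
    tree = random_population_tree(seed)
    lat = _latitudes(tree)
    rej = 0
    for i in range(n_replicates):
        ds = simulate.simulate_cline(
            tree, lat, slope=0.0, bm_sigma2=bm_sigma2, intercept=-1.0,
            seed=seed * 10_000 + i,
        )
        fits = cline.fit_cline_models(ds, tree, logit_scale=True)
        rej += cline.likelihood_ratio_test(fits["null"], fits["full"])["p"] < alpha
    return {"rejection_rate": rej / n_replicates, "n": n_replicates, "alpha": alpha}


def cline_full_analysis(seed: int, slope: float = 0.08, bm_sigma2: float = 0.1) -> dict:
    """One full cline workup: PGLS fits, LRT, Akaike weights, leave-one-out."""
    tree = random_population_tree(seed)
    lat = _latitudes(tree)
    ds = simulate.simulate_cline(tree, lat, slope=slope, bm_sigma2=bm_sigma2,
                                 intercept=-2.0, seed=seed)
    fits = cline.fit_cline_models(ds, tree, logit_scale=True)
    lrt = cline.likelihood_ratio_test(fits["null"], fits["full"])
    aw = cline.akaike_model_average(fits)
    loo = cline.leave_one_out_stability(ds, tree, logit_scale=True)
    return {
        "dataset": ds,
        "fits": fits,
        "lrt": lrt,
        "model_weights": aw["model_weights"],
        "predictor_weights": aw["predictor_weights"],
        "loo": loo,
        "latitude_slope": float(fits["full"].params["latitude"]),
    }


TRANS_GENES = [f"g{i:04d}" for i in range(12)]


def trans_expression_analysis(
    seed: int,
    effect: float = 2.0,
    n_donors: int = 60,
    cells_per_donor: int = 200,
    n_genes: int = 100,
    n_permutations: int = 1_000,
    flip_replication: bool = False,
) -> dict:
    """Discovery + replication of a planted trans gene set, with module
    scores and a donor-level permutation test in the replication cohort."""
    disc = simulate.simulate_expression_cohort(
        n_donors=n_donors, cells_per_donor=cells_per_donor, n_genes=n_genes,
        trans_set=TRANS_GENES, effect=effect, seed=seed,
    )
    rep_effect = 1.0 / effect if flip_replication else effect
    rep = simulate.simulate_expression_cohort(
        n_donors=n_donors, cells_per_donor=cells_per_donor, n_genes=n_genes,
        trans_set=TRANS_GENES, effect=rep_effect, seed=seed + 500_000,
    )
    de, _ = trans_expr.risk_allele_de(disc, "adipocyte", TRANS_GENES)
    replicated = trans_expr.replicate(de, rep, "adipocyte")
    scores = trans_expr.module_score(rep, TRANS_GENES, seed=seed)
    group = trans_expr.module_group_test(scores, rep.cells, rep.donors)
    perm = trans_expr.permutation_module_test(
        rep, TRANS_GENES, B=n_permutations, seed=seed
    )
    return {
        "discovery": de,
        "n_discovered": int(de["significant"].sum()),
        "n_replicated": int(replicated["replicated"].sum()) if len(replicated) else 0,
        "module_p": group["p"],
        "perm_p": perm["perm_p"],
        "perm_p_raw": perm["perm_p_raw"],
        "perm_B": perm["B"],
    }


def twin_size_analysis(seed: int, target_rho: float = 0.55, n_pairs: int = 44) -> dict:
    """Twin-cohort size correlation of the planted gene, per BMI group."""
    expr, samples = simulate.simulate_twin_cohort(
        n_pairs=n_pairs, target_rho=target_rho, seed=seed
    )
    res = adipose.size_correlations(expr, samples, gene_list=["g0000"])
    res = res.set_index("group")
    return {
        "rho_higher": float(res.loc["higher-BMI", "rho"]),
        "rho_lower": float(res.loc["lower-BMI", "rho"]),
        "table": res,
    }
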