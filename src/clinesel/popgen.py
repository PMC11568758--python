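"""Population differentiation and linkage disequilibrium.

Per-site Weir & Cockerham (1984) F_ST between two populations, an
allele-frequency-matched empirical null for a focal site's F_ST, phased
haplotype r-squared, and a rank-sum comparison of regional LD between two
populations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .haplotypes import HaplotypePanel

__all__ = [
    "SiteFrequencyTable",
    "EmpiricalNull",
    "genotypes_from_panel",
    "weir_cockerham_fst",
    "weighted_fst",
    "matched_empirical_p",
    "haplotype_r2",
    "regional_r2",
    "compare_regional_ld",
]


@dataclass
class SiteFrequencyTable:
    """Per-site, per-population allele counts and frequencies.

    ``df`` is indexed by site id with, per population P, columns
    ``P_n`` (diploid sample size), ``P_count`` (derived-allele count) and
    ``P_freq`` (= count / 2n).
    """

    df: pd.DataFrame
    populations: list[str]

    @classmethod
    def from_panels(cls, panels: dict[str, HaplotypePanel]) -> "SiteFrequencyTable":
        first = next(iter(panels.values()))
        data = {"pos_bp": first.positions_bp}
        for name, panel in panels.items():
            counts = panel.alleles.sum(axis=0)
            n_hap = panel.n_haplotypes
            data[f"{name}_n"] = n_hap // 2
            data[f"{name}_count"] = counts
            data[f"{name}_freq"] = counts / n_hap
        df = pd.DataFrame(data, index=pd.Index(first.site_ids, name="site"))
        return cls(df=df, populations=list(panels))

    def freq(self, population: str) -> pd.Series:
        return self.df[f"{population}_freq"]

    def maf(self, population: str) -> pd.Series:
        f = self.freq(population)
        return np.minimum(f, 1.0 - f)


def genotypes_from_panel(panel: HaplotypePanel) -> np.ndarray:
    """Collapse phased haplotypes into diploid dosages (individuals x sites)."""
    return panel.alleles[0::2] + panel.alleles[1::2]


def weir_cockerham_fst(
    genotypes_pop1: np.ndarray, genotypes_pop2: np.ndarray
) -> pd.DataFrame:
    """Per-site Weir & Cockerham (1984) theta-hat between two populations.

    Inputs are diploid dosage matrices (individuals x sites, values 0/1/2,
    -1 for missing).  For each site the among-population (a), among-
    individual-within-population (b) and within-individual (c) variance
    components are formed from sample sizes, allele frequencies and observed
    heterozygosities; theta-hat = a / (a + b + c).  Sites monomorphic in the
    pooled sample, or with fewer than two non-missing individuals in either
    population, are emitted as missing.  Returns a DataFrame with columns
    ``fst_raw`` (unclipped) and ``fst`` (clipped to [0, 1]).
    """
    g1 = np.asarray(genotypes_pop1)
    g2 = np.asarray(genotypes_pop2)
    if g1.ndim != 2 or g2.ndim != 2 or g1.shape[1] != g2.shape[1]:
        raise ValueError("genotype matrices must be 2-D with matching site counts")
    r = 2.0
    stats_per_pop = []
    for g in (g1, g2):
        valid = g >= 0
        n = valid.sum(axis=0).astype(float)                       # individuals
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(valid, g, 0).sum(axis=0) / (2.0 * n)     # derived freq
            h = np.where(valid, g == 1, False).sum(axis=0) / n    # observed het
        stats_per_pop.append((n, p, h))
    n1, p1, h1 = stats_per_pop[0]
    n2, p2, h2 = stats_per_pop[1]
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1.0) / r * s2 - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar) - (r - 1.0) / r * s2 - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
        )
        c = hbar / 2.0
        denom = a + b + c
        raw = np.where(denom != 0, a / denom, np.nan)
    bad = (n1 < 2) | (n2 < 2) | (pbar <= 0) | (pbar >= 1)
    raw = np.where(bad, np.nan, raw)
    return pd.DataFrame(
        {
            "fst_raw": raw,
            "fst": np.clip(raw, 0.0, 1.0),
            "a": np.where(bad, np.nan, a),
            "b": np.where(bad, np.nan, b),
            "c": np.where(bad, np.nan, c),
        }
    )


def weighted_fst(fst_table: pd.DataFrame) -> float:
    """Multi-site Weir-Cockerham estimate: sum(a) / sum(a + b + c).

    The ratio of summed variance components (the "weighted" F_ST of the
    cited command-line tool) is the right summary when averaging over
    sites; the mean of per-site ratios is biased downward."""
    ok = fst_table[["a", "b", "c"]].dropna()
    denom = (ok["a"] + ok["b"] + ok["c"]).sum()
    if denom == 0:
        raise ValueError("no informative sites")
    return float(ok["a"].sum() / denom)


@dataclass
class EmpiricalNull:
    focal_site: str
    focal_fst: float
    matched_sites: list[str]
    matched_fst: np.ndarray
    p: float
    k: int
    p_add_one: float


def matched_empirical_p(
    focal_fst: float,
    focal_freq: float,
    candidates: pd.DataFrame,
    k: int = 10000,
    focal_site: str = "focal",
) -> EmpiricalNull:
    """Empirical significance of a focal F_ST against frequency-matched sites.

    ``candidates`` must carry columns ``freq`` and ``fst`` (same population
    pair as the focal value; the focal site itself excluded) and be ordered
    in site order (chromosome, position) — ties in |freq - focal_freq| are
    broken by that order, which makes the selection deterministic.  The
    empirical p is the proportion of the k matched sites whose F_ST is
    strictly greater than the focal F_ST; an add-one variant
    (#greater + 1)/(k + 1) is reported alongside.
    """
    cand = candidates.dropna(subset=["freq", "fst"])
    if len(cand) == 0:
        raise ValueError("no candidate sites with defined frequency and F_ST")
    delta = (cand["freq"] - focal_freq).abs().to_numpy()
    order = np.argsort(delta, kind="stable")  # stable => ties broken by site order
    k_used = min(k, len(cand))
    sel = order[:k_used]
    matched = cand.iloc[sel]
    n_greater = int((matched["fst"].to_numpy() > focal_fst).sum())
    return EmpiricalNull(
        focal_site=focal_site,
        focal_fst=float(focal_fst),
        matched_sites=list(matched.index.astype(str)),
        matched_fst=matched["fst"].to_numpy(),
        p=n_greater / k_used,
        k=k_used,
        p_add_one=(n_greater + 1) / (k_used + 1),
    )


def haplotype_r2(panel: HaplotypePanel, site_a: int, site_b: int) -> float:
    """Squared haplotype correlation between two phased sites.

    r^2 = (p_AB - p_A p_B)^2 / (p_A (1 - p_A) p_B (1 - p_B)) from direct
    haplotype counts (phase known, no EM).  Monomorphic sites give NaN.
    """
    a = panel.alleles[:, site_a].astype(float)
    b = panel.alleles[:, site_b].astype(float)
    p_a, p_b = a.mean(), b.mean()
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        return float("nan")
    p_ab = (a * b).mean()
    d = p_ab - p_a * p_b
    return float(d * d / (p_a * (1 - p_a) * p_b * (1 - p_b)))


def regional_r2(
    panel: HaplotypePanel,
    focal_site: int,
    window_bp: int = 1_000_000,
    maf_min: float = 0.05,
) -> pd.Series:
    """r^2 between a focal site and every other site within +/- window_bp
    passing the MAF filter, indexed by site id."""
    pos = panel.positions_bp
    center = pos[focal_site]
    freqs = panel.alleles.mean(axis=0)
    maf = np.minimum(freqs, 1 - freqs)
    in_window = (np.abs(pos - center) <= window_bp) & (maf >= maf_min)
    in_window[focal_site] = False
    out = {}
    for j in np.flatnonzero(in_window):
        out[panel.site_ids[j]] = haplotype_r2(panel, focal_site, int(j))
    return pd.Series(out, dtype=float)


def compare_regional_ld(
    r2_values_pop_a: np.ndarray, r2_values_pop_b: np.ndarray
) -> dict:
    """Two-sided Wilcoxon rank-sum comparison of two r^2 collections.

    Returns the rank-sum statistic, p value, and which population has the
    larger median r^2.
    """
    a = np.asarray(r2_values_pop_a, dtype=float)
    b = np.asarray(r2_values_pop_b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError("both r^2 collections must be non-empty")
    res = stats.ranksums(a, b)
    med_a, med_b = float(np.median(a)), float(np.median(b))
    if med_a > med_b:
        direction = "pop_a"
    elif med_b > med_a:
        direction = "pop_b"
    else:
        direction = "tie"
    return {
        "statistic": float(res.statistic),
        "p": float(res.pvalue),
        "median_a": med_a,
        "median_b": med_b,
        "larger_median": direction,
    }
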