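"""Pseudobulk correlation analyses.

Donor-level pseudobulk (per-donor sums of single-nucleus counts within a
cell type) is TMM-normalized, adjusted for nuclei count / age / sex by
linear regression, and inverse-normal transformed; pairwise Spearman
correlations are then computed among genes in a +/- 1 Mb window around an
anchor gene, and between gene expression and adipocyte diameter within
higher- and lower-BMI twin groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "PseudobulkMatrix",
    "RegionSpec",
    "pseudobulk",
    "tmm_normalize",
    "inverse_normal_transform",
    "adjust_and_int",
    "regional_correlations",
    "size_correlations",
]


@dataclass
class PseudobulkMatrix:
    counts: pd.DataFrame            # donors x genes summed counts
    covariates: pd.DataFrame        # donors x {n_nuclei, age, sex, ...}
    dropped_donors: list[str] = field(default_factory=list)
    norm_factors: pd.Series | None = None
    normalized: pd.DataFrame | None = None
    transformed: pd.DataFrame | None = None


def pseudobulk(matrix, cell_type: str) -> PseudobulkMatrix:
    """Per-donor gene sums over cells of one type, with nuclei counts.

    Donors contributing zero cells of the type are dropped and listed.
    ``matrix`` is a :class:`~clinesel.trans_expr.CellExpressionMatrix`.
    """
    mask = (matrix.cells["cell_type"] == cell_type).to_numpy()
    if mask.sum() == 0:
        raise ValueError(f"no cells of type {cell_type!r}")
    sub_cells = matrix.cells.loc[mask]
    counts = pd.DataFrame(matrix.counts[mask], index=sub_cells.index, columns=matrix.genes)
    sums = counts.groupby(sub_cells["donor_id"].to_numpy()).sum()
    nuclei = sub_cells.groupby("donor_id").size()
    dropped = sorted(set(matrix.donors.index) - set(sums.index))
    if dropped:
        logger.info("pseudobulk: dropped donors with zero %s cells: %s", cell_type, dropped)
    donors = sums.index
    cov = pd.DataFrame(
        {
            "n_nuclei": nuclei.loc[donors].astype(float),
            "age": matrix.donors.loc[donors, "age"].astype(float),
            "sex": (matrix.donors.loc[donors, "sex"] == "F").astype(float),
        },
        index=donors,
    )
    return PseudobulkMatrix(counts=sums, covariates=cov, dropped_donors=list(dropped))


def _tmm_factor_pair(
    x: np.ndarray, ref: np.ndarray, lib_x: float, lib_ref: float,
    logratio_trim: float, sum_trim: float,
) -> float:
    keep = (x > 0) & (ref > 0)
    if keep.sum() == 0:
        return 1.0
    xs, rs = x[keep], ref[keep]
    M = np.log2((xs / lib_x) / (rs / lib_ref))
    A = 0.5 * np.log2((xs / lib_x) * (rs / lib_ref))
    w = (lib_x - xs) / (lib_x * xs) + (lib_ref - rs) / (lib_ref * rs)
    if np.max(np.abs(M)) < 1e-6:
        return 1.0
    n = len(M)
    lo_m = np.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * sum_trim) + 1
    hi_a = n + 1 - lo_a
    rank_m = stats.rankdata(M)
    rank_a = stats.rankdata(A)
    sel = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if sel.sum() == 0 or np.sum(1.0 / w[sel]) == 0:
        return 1.0
    f = np.sum(M[sel] / w[sel]) / np.sum(1.0 / w[sel])
    if not np.isfinite(f):
        return 1.0
    return float(2.0**f)


def tmm_normalize(
    pb: PseudobulkMatrix | pd.DataFrame,
    logratio_trim: float = 0.3,
    sum_trim: float = 0.05,
) -> tuple[pd.Series, pd.DataFrame]:
    """Trimmed-mean-of-M-values scaling factors and normalized values.

    The reference sample is the one whose 75th-percentile expression
    fraction is closest to the mean across samples; per-sample factors are
    precision-weighted means of log2 ratios after trimming 30% of the M
    values and 5% of the A values from each tail, and are rescaled to
    geometric mean 1.  Normalized value = count / (library size x factor).
    """
    counts = pb.counts if isinstance(pb, PseudobulkMatrix) else pb
    if len(counts) < 2:
        raise ValueError("TMM needs at least 2 samples")
    lib = counts.sum(axis=1).astype(float)
    if (lib == 0).any():
        raise ValueError(f"samples with all-zero counts: {list(counts.index[lib == 0])}")
    frac = counts.div(lib, axis=0)
    f75 = frac.quantile(0.75, axis=1)
    ref_label = (f75 - f75.mean()).abs().idxmin()
    ref = counts.loc[ref_label].to_numpy(dtype=float)
    lib_ref = float(lib.loc[ref_label])
    factors = pd.Series(1.0, index=counts.index)
    for s in counts.index:
        if s == ref_label:
            factors.loc[s] = 1.0
        else:
            factors.loc[s] = _tmm_factor_pair(
                counts.loc[s].to_numpy(dtype=float), ref, float(lib.loc[s]), lib_ref,
                logratio_trim, sum_trim,
            )
    factors = factors / np.exp(np.log(factors).mean())
    normalized = counts.div(lib * factors, axis=0)
    if isinstance(pb, PseudobulkMatrix):
        pb.norm_factors = factors
        pb.normalized = normalized
    return factors, normalized


def inverse_normal_transform(x: np.ndarray) -> np.ndarray:
    """Rank-based inverse normal with the Blom offset:
    Phi^-1((rank - 3/8) / (n + 1/4)), ties averaged."""
    x = np.asarray(x, dtype=float)
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf((ranks - 0.375) / (len(x) + 0.25))


def adjust_and_int(normalized: pd.DataFrame, covariates: pd.DataFrame) -> pd.DataFrame:
    """Per-gene covariate adjustment followed by inverse normal transform.

    Each gene is regressed (OLS with intercept) on the covariates; the
    residuals are mapped to Blom-offset normal quantiles.  Requires at
    least #covariates + 2 samples.
    """
    if list(normalized.index) != list(covariates.index):
        covariates = covariates.loc[normalized.index]
    n, k = len(normalized), covariates.shape[1]
    if n < k + 2:
        raise ValueError(f"n = {n} too small for {k} covariates")
    X = np.column_stack([np.ones(n), covariates.to_numpy(dtype=float)])
    Y = normalized.to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    out = np.apply_along_axis(inverse_normal_transform, 0, resid)
    return pd.DataFrame(out, index=normalized.index, columns=normalized.columns)


@dataclass
class RegionSpec:
    """Genes within a window around an anchor gene.

    ``gene_coords`` maps gene -> (start, stop), 1-based inclusive; a member
    gene qualifies when its body overlaps
    [anchor start - half-width, anchor stop + half-width].
    """

    anchor_gene: str
    gene_coords: pd.DataFrame       # index gene; columns start, stop
    window_bp: int = 1_000_000

    def members(self) -> list[str]:
        if self.anchor_gene not in self.gene_coords.index:
            raise ValueError(f"anchor {self.anchor_gene!r} has no coordinates")
        a = self.gene_coords.loc[self.anchor_gene]
        lo, hi = a["start"] - self.window_bp, a["stop"] + self.window_bp
        sel = (self.gene_coords["stop"] >= lo) & (self.gene_coords["start"] <= hi)
        return list(self.gene_coords.index[sel])


def regional_correlations(
    transformed: pd.DataFrame,
    region: RegionSpec | list[str],
    alpha_nominal: float = 0.05,
) -> pd.DataFrame:
    """All pairwise Spearman correlations among a region's genes.

    Returns a long-format table (gene_a, gene_b, rho, p, nominally_significant);
    pairs involving a constant gene are emitted with missing rho/p.
    """
    genes = region.members() if isinstance(region, RegionSpec) else list(region)
    genes = [g for g in genes if g in transformed.columns]
    if len(genes) < 2:
        raise ValueError("need at least 2 region genes present in the matrix")
    if len(transformed) < 3:
        raise ValueError("need at least 3 donors")
    rows = []
    for i, ga in enumerate(genes):
        for gb in genes[i + 1 :]:
            xa, xb = transformed[ga].to_numpy(), transformed[gb].to_numpy()
            if np.ptp(xa) == 0 or np.ptp(xb) == 0:
                rho, p = np.nan, np.nan
            else:
                rho, p = stats.spearmanr(xa, xb)
            rows.append(
                {
                    "gene_a": ga,
                    "gene_b": gb,
                    "rho": rho,
                    "p": p,
                    "nominally_significant": bool(p < alpha_nominal) if np.isfinite(p) else False,
                }
            )
    return pd.DataFrame(rows)


def size_correlations(
    expression: pd.DataFrame,
    samples: pd.DataFrame,
    gene_list: list[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Spearman correlation of gene expression with adipocyte diameter,
    separately within each twin group.

    ``expression`` is individuals x genes; ``samples`` carries ``group`` and
    ``diameter_um`` per individual.  Diameters are inverse-normal
    transformed within group before correlating; Bonferroni correction uses
    the number of gene x group tests in this run.  Groups with fewer than 3
    members are skipped.
    """
    genes = list(expression.columns) if gene_list is None else [
        g for g in gene_list if g in expression.columns
    ]
    if not genes:
        raise ValueError("no requested genes present in the expression table")
    groups = [g for g in samples["group"].unique()]
    rows = []
    for grp in groups:
        members = samples.index[samples["group"] == grp]
        if len(members) < 3:
            logger.warning("group %s has <3 members; skipped", grp)
            continue
        diam = inverse_normal_transform(samples.loc[members, "diameter_um"].to_numpy())
        for gene in genes:
            rho, p = stats.spearmanr(expression.loc[members, gene].to_numpy(), diam)
            rows.append({"gene": gene, "group": grp, "rho": rho, "p": p})
    out = pd.DataFrame(rows)
    n_tests = len(out)
    out["p_adj"] = np.minimum(out["p"] * n_tests, 1.0)
    out["significant"] = out["p_adj"] < alpha
    return out
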