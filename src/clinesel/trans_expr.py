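"""Cell-type markers, risk-allele differential expression, and module scores.

The question driving this module: do carriers of a risk allele express a
designated gene set differently in adipocytes?  The workflow mirrors the
standard single-nucleus toolkit conventions: log-normalization with a
fixed scale factor, one-vs-rest Wilcoxon marker tests with a log2
fold-change threshold, Bonferroni correction over the genes tested,
replication requiring significance plus concordant direction, module
scores against expression-matched control genes, and a donor-level
permutation null for the module-score group comparison.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats, special

logger = logging.getLogger(__name__)

__all__ = [
    "CellExpressionMatrix",
    "log_normalize",
    "find_cell_type_markers",
    "unique_markers",
    "risk_allele_de",
    "replicate",
    "module_score",
    "module_group_test",
    "permutation_module_test",
    "sex_stratified_de",
]


@dataclass
class CellExpressionMatrix:
    """Cell x gene counts with cell -> donor and donor -> phenotype maps."""

    counts: np.ndarray                 # (n_cells, n_genes) non-negative ints
    genes: list[str]
    cells: pd.DataFrame                # index cell_id; columns cell_type, donor_id
    donors: pd.DataFrame               # index donor_id; columns risk_carrier, sex, age
    normalized: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.counts.shape != (len(self.cells), len(self.genes)):
            raise ValueError("counts shape does not match cell/gene annotations")
        unknown = set(self.cells["donor_id"]) - set(self.donors.index)
        if unknown:
            raise ValueError(f"cells reference unknown donors: {sorted(unknown)}")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    def gene_index(self, gene: str) -> int:
        return self.genes.index(gene)

    def carrier_mask(self) -> np.ndarray:
        """Per-cell boolean: does this cell's donor carry the risk allele?"""
        status = self.donors["risk_carrier"].astype(bool)
        return status.loc[self.cells["donor_id"]].to_numpy()

    def subset_cells(self, mask: np.ndarray) -> "CellExpressionMatrix":
        return replace(
            self,
            counts=self.counts[mask],
            cells=self.cells.loc[mask],
            normalized=None if self.normalized is None else self.normalized[mask],
        )

    def require_normalized(self) -> np.ndarray:
        if self.normalized is None:
            log_normalize(self)
        return self.normalized


def log_normalize(matrix: CellExpressionMatrix, scale_factor: float = 10000.0) -> np.ndarray:
    """Per-cell log normalization: ln(1 + scale_factor * count / cell_total)."""
    totals = matrix.counts.sum(axis=1, dtype=float)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        ids = list(matrix.cells.index[zero[:10]])
        raise ValueError(f"{zero.size} cell(s) have zero total counts, e.g. {ids}")
    matrix.normalized = np.log1p(scale_factor * matrix.counts / totals[:, None])
    return matrix.normalized


def _rank_sum_pvalues(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Two-sided Wilcoxon rank-sum p per column (gene) of A (group 1 cells x
    genes) vs B (group 2 cells x genes).

    Exact null when both groups have <= 25 observations and the column is
    tie-free; otherwise the normal approximation with tie and continuity
    corrections.
    """
    n1, n2 = A.shape[0], B.shape[0]
    if min(n1, n2) == 0:
        raise ValueError("both groups must be non-empty")
    use_exact = max(n1, n2) <= 25
    if use_exact:
        out = np.empty(A.shape[1])
        for j in range(A.shape[1]):
            pooled = np.concatenate([A[:, j], B[:, j]])
            method = "exact" if np.unique(pooled).size == pooled.size else "asymptotic"
            out[j] = stats.mannwhitneyu(
                A[:, j], B[:, j], alternative="two-sided", method=method
            ).pvalue
        return out
    res = stats.mannwhitneyu(A, B, alternative="two-sided", method="asymptotic", axis=0)
    return np.atleast_1d(res.pvalue)


def _seurat_logfc(norm_in: np.ndarray, norm_out: np.ndarray, base: float = 2.0) -> np.ndarray:
    """log-base-2 fold change on de-logged means with pseudocount 1:
    log2((mean(expm1(x_in)) + 1) / (mean(expm1(x_out)) + 1))."""
    m_in = np.expm1(norm_in).mean(axis=0) + 1.0
    m_out = np.expm1(norm_out).mean(axis=0) + 1.0
    return np.log(m_in / m_out) / np.log(base)


def find_cell_type_markers(
    matrix: CellExpressionMatrix,
    logfc_threshold: float = 0.25,
    only_pos: bool = True,
    alpha: float = 0.05,
    logfc_base: float = 2.0,
) -> dict[str, pd.DataFrame]:
    """One-vs-rest Wilcoxon marker tests per cell type.

    Genes are pre-filtered by log2 fold change (in-type vs all other cells);
    the Bonferroni denominator is the number of genes tested for that type.
    Returns per-type DataFrames with logfc, p, p_adj, pct_in, pct_out and an
    ``is_marker`` flag (p_adj < alpha).  Types with fewer than 3 cells are
    skipped with a warning.
    """
    types = matrix.cells["cell_type"].unique()
    if len(types) < 2:
        raise ValueError("need at least 2 cell types for one-vs-rest marker tests")
    norm = matrix.require_normalized()
    out: dict[str, pd.DataFrame] = {}
    for t in types:
        in_mask = (matrix.cells["cell_type"] == t).to_numpy()
        if in_mask.sum() < 3:
            warnings.warn(f"cell type {t!r} has <3 cells; skipped")
            continue
        Ni, No = norm[in_mask], norm[~in_mask]
        logfc = _seurat_logfc(Ni, No, base=logfc_base)
        passing = logfc >= logfc_threshold if only_pos else np.abs(logfc) >= logfc_threshold
        tested = np.flatnonzero(passing)
        pvals = np.ones(len(matrix.genes))
        if tested.size:
            pvals[tested] = _rank_sum_pvalues(Ni[:, tested], No[:, tested])
        n_tested = max(tested.size, 1)
        df = pd.DataFrame(
            {
                "gene": np.array(matrix.genes)[tested],
                "cell_type": t,
                "logfc": logfc[tested],
                "p": pvals[tested],
                "p_adj": np.minimum(pvals[tested] * n_tested, 1.0),
                "pct_in": (Ni[:, tested] > 0).mean(axis=0),
                "pct_out": (No[:, tested] > 0).mean(axis=0),
            }
        ).set_index("gene")
        df["is_marker"] = df["p_adj"] < alpha
        out[t] = df
    return out


def unique_markers(markers_by_type: dict[str, pd.DataFrame], target_type: str) -> list[str]:
    """Target-type markers minus the union of every other type's markers."""
    if target_type not in markers_by_type:
        raise ValueError(f"no marker table for target type {target_type!r}")
    target = set(markers_by_type[target_type].query("is_marker").index)
    others: set[str] = set()
    for t, df in markers_by_type.items():
        if t != target_type:
            others |= set(df.query("is_marker").index)
    unique = sorted(target - others)
    if target and not unique:
        warnings.warn(f"all {target_type!r} markers are shared with other cell types")
    return unique


def risk_allele_de(
    matrix: CellExpressionMatrix,
    cell_type: str,
    gene_set: list[str],
    logfc_threshold: float = 0.0,
    alpha: float = 0.05,
    logfc_base: float = 2.0,
) -> tuple[pd.DataFrame, list[str]]:
    """Carrier vs non-carrier Wilcoxon tests across cells of one type.

    Cells of ``cell_type`` are pooled by their donor's carrier status; each
    gene in ``gene_set`` with |log2 FC| >= threshold is tested and Bonferroni
    correction uses the number of genes tested in this run.  Genes absent
    from the matrix are skipped and reported in the second return value.
    """
    present = [g for g in gene_set if g in matrix.genes]
    skipped = [g for g in gene_set if g not in matrix.genes]
    if skipped:
        logger.info("risk_allele_de: %d gene(s) absent from matrix: %s", len(skipped), skipped)
    if not present:
        return (
            pd.DataFrame(columns=["logfc", "p", "p_adj", "direction", "significant"]),
            skipped,
        )
    type_mask = (matrix.cells["cell_type"] == cell_type).to_numpy()
    if type_mask.sum() == 0:
        raise ValueError(f"no cells of type {cell_type!r}")
    sub = matrix.subset_cells(type_mask)
    norm = sub.require_normalized()
    carrier = sub.carrier_mask()
    if carrier.all() or not carrier.any():
        raise ValueError("both carrier and non-carrier cells are required")
    idx = np.array([matrix.genes.index(g) for g in present])
    Nc, Nn = norm[carrier][:, idx], norm[~carrier][:, idx]
    logfc = _seurat_logfc(Nc, Nn, base=logfc_base)
    passing = np.abs(logfc) >= logfc_threshold
    tested = np.flatnonzero(passing)
    n_tested = max(tested.size, 1)
    pvals = np.full(len(present), np.nan)
    if tested.size:
        pvals[tested] = _rank_sum_pvalues(Nc[:, tested], Nn[:, tested])
    df = pd.DataFrame(
        {
            "gene": present,
            "logfc": logfc,
            "p": pvals,
            "p_adj": np.minimum(pvals * n_tested, 1.0),
            "direction": np.where(logfc >= 0, "up_in_carriers", "down_in_carriers"),
        }
    ).set_index("gene")
    df["significant"] = df["p_adj"] < alpha
    return df, skipped


def replicate(
    discovery: pd.DataFrame,
    replication_matrix: CellExpressionMatrix,
    cell_type: str,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Replication of discovery-significant genes in a second cohort.

    Reruns the carrier-status test on the replication matrix restricted to
    the discovery-significant genes (Bonferroni denominator = number of
    genes carried forward); replicated genes need adjusted p < alpha AND a
    fold change in the same direction as in discovery.
    """
    carried = list(discovery.query("significant").index)
    if not carried:
        return pd.DataFrame(
            columns=["logfc", "p", "p_adj", "direction", "significant", "replicated"]
        )
    rep, _ = risk_allele_de(replication_matrix, cell_type, carried, logfc_threshold=0.0, alpha=alpha)
    same_sign = np.sign(rep["logfc"]) == np.sign(discovery.loc[rep.index, "logfc"])
    rep["replicated"] = rep["significant"] & same_sign
    return rep


def module_score(
    matrix: CellExpressionMatrix,
    gene_set: list[str],
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Per-cell module score against expression-matched control genes.

    All genes are ranked by mean normalized expression across cells and cut
    into ``n_bins`` equal-frequency bins; each gene-set gene contributes
    ``n_ctrl`` control genes sampled (seeded) from its own bin — without
    replacement when the bin is large enough, with replacement otherwise.
    Score = mean over the gene set minus mean over the pooled (unique)
    control genes, per cell.
    """
    if not gene_set:
        raise ValueError("gene_set must be non-empty")
    missing = [g for g in gene_set if g not in matrix.genes]
    if missing:
        raise ValueError(f"gene_set genes absent from matrix: {missing}")
    norm = matrix.require_normalized()
    rng = np.random.default_rng(seed)
    avg = norm.mean(axis=0)
    order = stats.rankdata(avg, method="average")
    bins = np.floor((order - 1) / len(order) * n_bins).astype(int)
    bins = np.clip(bins, 0, n_bins - 1)
    set_idx = np.array([matrix.genes.index(g) for g in gene_set])
    ctrl: set[int] = set()
    for gi in set_idx:
        pool = np.flatnonzero(bins == bins[gi])
        pool = pool[pool != gi]
        if pool.size == 0:
            warnings.warn("control bin exhausted; sampling from all genes with replacement")
            pool = np.delete(np.arange(len(matrix.genes)), gi)
        if pool.size >= n_ctrl:
            draw = rng.choice(pool, size=n_ctrl, replace=False)
        else:
            warnings.warn("small control bin; sampling with replacement")
            draw = rng.choice(pool, size=n_ctrl, replace=True)
        ctrl.update(int(i) for i in draw)
    ctrl_idx = np.array(sorted(ctrl - set(int(i) for i in set_idx)))
    if ctrl_idx.size == 0:
        raise ValueError("no control genes available outside the gene set")
    return norm[:, set_idx].mean(axis=1) - norm[:, ctrl_idx].mean(axis=1)


def _ranksum_p_from_ranks(
    rank_sum_1: float, n1: int, n2: int, tie_term: float
) -> float:
    """Two-sided Mann-Whitney p from the rank sum of group 1, using the
    normal approximation with tie and continuity corrections (identical to
    the asymptotic path of scipy.stats.mannwhitneyu)."""
    U1 = rank_sum_1 - n1 * (n1 + 1) / 2.0
    n = n1 + n2
    mu = n1 * n2 / 2.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return 1.0
    U = max(U1, n1 * n2 - U1)
    z = (U - mu - 0.5) / np.sqrt(var)
    return float(min(2.0 * special.ndtr(-z), 1.0))


def module_group_test(
    scores: np.ndarray,
    cells: pd.DataFrame,
    donors: pd.DataFrame,
) -> dict:
    """Two-sided Wilcoxon rank-sum comparison of cell-level module scores
    between carrier and non-carrier donors' cells."""
    carrier = donors["risk_carrier"].astype(bool).loc[cells["donor_id"]].to_numpy()
    if not carrier.any() or carrier.all():
        raise ValueError("both carrier and non-carrier cells are required")
    res = stats.mannwhitneyu(
        scores[carrier], scores[~carrier], alternative="two-sided", method="asymptotic"
    )
    return {"statistic": float(res.statistic), "p": float(res.pvalue)}


def permutation_module_test(
    matrix: CellExpressionMatrix,
    gene_set: list[str],
    B: int = 10000,
    seed: int = 0,
    cell_type: str | None = None,
    n_bins: int = 24,
    n_ctrl: int = 100,
) -> dict:
    """Donor-level permutation null for the module-score group comparison.

    Carrier labels are shuffled across DONORS (cells keep their donor, so
    within-donor correlation is preserved under the null); for each of B
    permutations the rank-sum p of the group comparison is recorded.  The
    permutation p is (#null p <= observed p + 1)/(B + 1); the raw proportion
    is reported alongside.  When the number of distinct carrier assignments
    is below B, all distinct assignments are enumerated instead (logged).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    work = matrix
    if cell_type is not None:
        work = matrix.subset_cells((matrix.cells["cell_type"] == cell_type).to_numpy())
    scores = module_score(work, gene_set, n_bins=n_bins, n_ctrl=n_ctrl, seed=seed)
    donor_ids = list(work.donors.index)
    carrier_by_donor = work.donors["risk_carrier"].astype(bool).to_numpy()
    n_carrier_donors = int(carrier_by_donor.sum())
    if n_carrier_donors < 2 or len(donor_ids) - n_carrier_donors < 2:
        raise ValueError("need at least 2 donors per carrier group")

    # per-donor rank sums let each permutation cost O(#donors)
    ranks = stats.rankdata(scores)
    _, tie_counts = np.unique(scores, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    donor_of_cell = work.cells["donor_id"].to_numpy()
    donor_rank_sum = np.zeros(len(donor_ids))
    donor_cell_count = np.zeros(len(donor_ids), dtype=int)
    donor_pos = {d: i for i, d in enumerate(donor_ids)}
    for d, r in zip(donor_of_cell, ranks):
        i = donor_pos[d]
        donor_rank_sum[i] += r
        donor_cell_count[i] += 1

    def p_for(assignment: np.ndarray) -> float:
        n1 = int(donor_cell_count[assignment].sum())
        n2 = len(scores) - n1
        if n1 == 0 or n2 == 0:
            return 1.0
        return _ranksum_p_from_ranks(donor_rank_sum[assignment].sum(), n1, n2, tie_term)

    observed_p = p_for(carrier_by_donor)

    n_donors = len(donor_ids)
    from math import comb

    distinct = comb(n_donors, n_carrier_donors)
    rng = np.random.default_rng(seed)
    null_p = []
    if distinct <= B:
        logger.info("enumerating all %d distinct carrier assignments (B capped)", distinct)
        for combo in itertools.combinations(range(n_donors), n_carrier_donors):
            mask = np.zeros(n_donors, dtype=bool)
            mask[list(combo)] = True
            null_p.append(p_for(mask))
        B_used = distinct
    else:
        for _ in range(B):
            mask = np.zeros(n_donors, dtype=bool)
            mask[rng.choice(n_donors, size=n_carrier_donors, replace=False)] = True
            null_p.append(p_for(mask))
        B_used = B
    null_p = np.asarray(null_p)
    r = int((null_p <= observed_p).sum())
    return {
        "observed_p": observed_p,
        "perm_p": (r + 1) / (B_used + 1),
        "perm_p_raw": r / B_used,
        "null_p": null_p,
        "B": B_used,
    }


def sex_stratified_de(
    matrix: CellExpressionMatrix,
    gene_set: list[str],
    cell_type: str = "adipocyte",
    alpha_tiers: tuple[float, ...] = (0.05, 0.01, 0.001, 0.0001),
) -> dict[str, pd.DataFrame]:
    """Carrier-status tests run separately within each sex.

    A sex whose donors fall into a single carrier group (or that has no
    donors) is skipped with a log entry.  Each result table carries a
    significance ``tier`` column (number of tiers passed, 0-4, from adjusted
    p < 0.05 down to < 0.0001).
    """
    out: dict[str, pd.DataFrame] = {}
    for sex in sorted(matrix.donors["sex"].unique()):
        donor_ids = matrix.donors.index[matrix.donors["sex"] == sex]
        if len(donor_ids) == 0:
            logger.info("sex %s: no donors, skipped", sex)
            continue
        status = matrix.donors.loc[donor_ids, "risk_carrier"].astype(bool)
        if status.all() or not status.any():
            logger.info("sex %s: single carrier group, skipped", sex)
            continue
        mask = matrix.cells["donor_id"].isin(donor_ids).to_numpy()
        sub = matrix.subset_cells(mask)
        df, _ = risk_allele_de(sub, cell_type, gene_set)
        df["tier"] = np.sum(
            df["p_adj"].to_numpy()[:, None] < np.asarray(alpha_tiers)[None, :], axis=1
        )
        out[sex] = df
    return out
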