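"""Phylogenetic modelling of allele-frequency clines.

A neighbor-joining tree built from pairwise F_ST distances supplies the
population-structure covariance for a phylogenetic generalized least
squares (PGLS) regression of derived-allele frequency on latitude and
mean annual temperature.  Under a Brownian-motion model, the expected
covariance of tip values is proportional to the shared root-to-tip branch
length, so GLS with that covariance tests whether latitude predicts the
frequency beyond what shared ancestry alone explains.  Model support is
summarized with a likelihood-ratio test of the full model against the
ancestry-only null and with Akaike weights over all predictor subsets,
and stability is probed by refitting with each population left out.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from skbio import TreeNode

logger = logging.getLogger(__name__)

__all__ = [
    "PglsFit",
    "neighbor_joining",
    "bm_covariance",
    "pgls_fit",
    "likelihood_ratio_test",
    "akaike_model_average",
    "fit_cline_models",
    "leave_one_out_stability",
]


def neighbor_joining(dist: pd.DataFrame) -> TreeNode:
    """Saitou-Nei neighbor joining from a symmetric distance matrix.

    Standard Q-criterion agglomeration.  A negative pendant branch length is
    clamped to zero with the deficit transferred to its sister branch, so
    path lengths through the joined pair are preserved.  The returned tree is
    unrooted (trifurcating root).
    """
    D = np.asarray(dist, dtype=float)
    labels = list(dist.index)
    if D.shape[0] != D.shape[1] or list(dist.columns) != labels:
        raise ValueError("distance matrix must be square with matching labels")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    if (D < -1e-12).any():
        raise ValueError("distances must be non-negative")
    if len(labels) < 3:
        raise ValueError("need at least 3 taxa")

    nodes: list[TreeNode] = [TreeNode(name=l) for l in labels]
    D = D.copy()
    while len(nodes) > 3:
        n = len(nodes)
        r = D.sum(axis=1)
        Q = (n - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        i, j = np.unravel_index(np.argmin(Q), Q.shape)  # first minimum: deterministic
        if i > j:
            i, j = j, i
        vi = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (n - 2))
        vj = D[i, j] - vi
        if vi < 0:
            vj += vi
            vi = 0.0
        if vj < 0:
            vi += vj
            vj = 0.0
        parent = TreeNode(children=[nodes[i], nodes[j]])
        nodes[i].length = max(vi, 0.0)
        nodes[j].length = max(vj, 0.0)
        d_new = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(n) if k not in (i, j)]
        D_next = np.empty((n - 1, n - 1))
        D_next[:-1, :-1] = D[np.ix_(keep, keep)]
        D_next[-1, :-1] = d_new[keep]
        D_next[:-1, -1] = d_new[keep]
        D_next[-1, -1] = 0.0
        nodes = [nodes[k] for k in keep] + [parent]
        D = D_next

    # three-point formulas for the final trifurcation
    a = 0.5 * (D[0, 1] + D[0, 2] - D[1, 2])
    b = 0.5 * (D[0, 1] + D[1, 2] - D[0, 2])
    c = 0.5 * (D[0, 2] + D[1, 2] - D[0, 1])
    for node, v in zip(nodes, (a, b, c)):
        node.length = max(float(v), 0.0)
    return TreeNode(children=nodes)


def _is_rooted(tree: TreeNode) -> bool:
    return len(tree.children) == 2


def bm_covariance(tree: TreeNode) -> pd.DataFrame:
    """Brownian-motion covariance over tips: shared root-to-tip branch length.

    Unrooted input is midpoint-rooted first (logged).  Entry (i, j) is the
    depth of the most recent common ancestor of tips i and j; the diagonal
    is the root-to-tip depth.
    """
    if not _is_rooted(tree):
        logger.info("unrooted tree: midpoint-rooting before covariance construction")
        tree = tree.root_at_midpoint()
    tips = list(tree.tips())
    names = [t.name for t in tips]
    depth: dict[int, float] = {id(tree): 0.0}
    for node in tree.preorder(include_self=False):
        depth[id(node)] = depth[id(node.parent)] + float(node.length or 0.0)
    cov = np.zeros((len(tips), len(tips)))
    for i, ti in enumerate(tips):
        cov[i, i] = depth[id(ti)]
        for j in range(i + 1, len(tips)):
            anc = tree.lowest_common_ancestor([ti, tips[j]])
            cov[i, j] = cov[j, i] = depth[id(anc)]
    return pd.DataFrame(cov, index=names, columns=names)


@dataclass
class PglsFit:
    params: pd.Series
    se: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    sigma2_ml: float
    loglik: float
    aic: float
    predictors: tuple[str, ...]
    n: int
    shapiro_p: float
    residuals: np.ndarray = field(repr=False, default=None)

    @property
    def n_coef(self) -> int:
        return len(self.params)

    @property
    def aicc(self) -> float:
        """Small-sample corrected AIC (k counts the variance parameter)."""
        k = self.n_coef + 1
        denom = self.n - k - 1
        if denom <= 0:
            return float("inf")
        return self.aic + 2.0 * k * (k + 1) / denom


def pgls_fit(
    y: np.ndarray,
    X: pd.DataFrame | np.ndarray,
    V: np.ndarray | pd.DataFrame,
    predictors: tuple[str, ...] | None = None,
    jitter: float = 1e-10,
) -> PglsFit:
    """Generalized least squares with a known correlation structure.

    beta-hat = (X' V^-1 X)^-1 X' V^-1 y with the Brownian rate sigma^2
    profiled at its maximum-likelihood value r' V^-1 r / n.  The reported
    log-likelihood and AIC count sigma^2 as a parameter (AIC = 2k - 2 logL,
    k = #coefficients + 1).  Standard errors use the unbiased scale
    r' V^-1 r / (n - p) with t-based p values.  A Shapiro-Wilk p for the
    whitened residuals is attached as a normality diagnostic.  ``X`` should
    include an intercept column.
    """
    y = np.asarray(y, dtype=float)
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        Xm = X.to_numpy(dtype=float)
    else:
        Xm = np.asarray(X, dtype=float)
        names = [f"x{i}" for i in range(Xm.shape[1])]
    Vm = np.asarray(V, dtype=float)
    n, p = Xm.shape
    if y.shape[0] != n or Vm.shape != (n, n):
        raise ValueError("dimension mismatch between y, X and V")
    Vj = Vm + jitter * np.trace(Vm) / n * np.eye(n)
    try:
        L = np.linalg.cholesky(Vj)
    except np.linalg.LinAlgError as e:
        raise ValueError("covariance not positive definite even after jitter") from e
    # whiten: solve L z = v  =>  z = L^-1 v
    yw = np.linalg.solve(L, y)
    Xw = np.linalg.solve(L, Xm)
    XtX = Xw.T @ Xw
    cond = np.linalg.cond(XtX)
    if cond > 1e12:
        raise ValueError(f"singular design after whitening (condition number {cond:.3g})")
    beta = np.linalg.solve(XtX, Xw.T @ yw)
    resid_w = yw - Xw @ beta
    rss = float(resid_w @ resid_w)
    sigma2_ml = rss / n
    logdetV = 2.0 * np.sum(np.log(np.diag(L)))
    loglik = -0.5 * (n * np.log(2.0 * np.pi * sigma2_ml) + logdetV + n)
    k = p + 1  # coefficients + profiled variance
    aic = 2.0 * k - 2.0 * loglik
    sigma2_unb = rss / max(n - p, 1)
    cov_beta = sigma2_unb * np.linalg.inv(XtX)
    se = np.sqrt(np.diag(cov_beta))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df=max(n - p, 1))
    shapiro_p = float(stats.shapiro(resid_w).pvalue) if n >= 3 else float("nan")
    return PglsFit(
        params=pd.Series(beta, index=names),
        se=pd.Series(se, index=names),
        tvalues=pd.Series(tvals, index=names),
        pvalues=pd.Series(pvals, index=names),
        sigma2_ml=sigma2_ml,
        loglik=float(loglik),
        aic=float(aic),
        predictors=tuple(predictors if predictors is not None else [n_ for n_ in names if n_ != "intercept"]),
        n=n,
        shapiro_p=shapiro_p,
        residuals=resid_w,
    )


def likelihood_ratio_test(null_fit: PglsFit, full_fit: PglsFit) -> dict:
    """Likelihood-ratio comparison of nested PGLS models fit on one covariance.

    Reports LR = 2 (logL_full - logL_null) and two p values.  Because the
    covariance is fixed by the tree, the whitened models are ordinary
    Gaussian linear regressions, so the LR statistic is a monotone function
    of the exact F statistic; the default ``p`` comes from that exact
    F(df, n - p_full) reference, which stays calibrated at small n where the
    asymptotic chi-square is anticonservative.  The chi-square p is reported
    alongside as ``p_chi2``.
    """
    if not set(null_fit.predictors) <= set(full_fit.predictors):
        raise ValueError("null model predictors are not nested in the full model")
    df = full_fit.n_coef - null_fit.n_coef
    if df < 0:
        raise ValueError("full model has fewer coefficients than the null")
    if null_fit.n != full_fit.n:
        raise ValueError("models were fit on different data")
    lr = max(2.0 * (full_fit.loglik - null_fit.loglik), 0.0)
    p_chi2 = float(stats.chi2.sf(lr, df)) if df > 0 else 1.0
    n = full_fit.n
    if df > 0:
        rss0 = null_fit.sigma2_ml * n
        rss1 = full_fit.sigma2_ml * n
        dfe = n - full_fit.n_coef
        f_stat = ((rss0 - rss1) / df) / (rss1 / dfe)
        p = float(stats.f.sf(max(f_stat, 0.0), df, dfe))
    else:
        p = 1.0
    return {"statistic": lr, "df": df, "p": p, "p_chi2": p_chi2}


def akaike_model_average(fits: dict[str, PglsFit], use_aicc: bool = False) -> dict:
    """Akaike weights over a model set plus per-predictor summed weights.

    AIC by default; ``use_aicc`` switches to the small-sample correction.
    """
    if len(fits) < 2:
        raise ValueError("need at least 2 models for Akaike weights")
    names = list(fits)
    aics = np.array([fits[m].aicc if use_aicc else fits[m].aic for m in names])
    delta = aics - aics.min()
    w = np.exp(-delta / 2.0)
    w = w / w.sum()
    weights = pd.Series(w, index=names)
    predictors = sorted({p for m in names for p in fits[m].predictors})
    pred_weights = pd.Series(
        {p: float(weights[[m for m in names if p in fits[m].predictors]].sum()) for p in predictors}
    )
    return {"model_weights": weights, "predictor_weights": pred_weights}


def _design(dataset: pd.DataFrame, predictors: tuple[str, ...]) -> pd.DataFrame:
    cols = {"intercept": np.ones(len(dataset))}
    mapping = {"latitude": "latitude_deg", "temperature": "temp_c"}
    for p in predictors:
        cols[p] = dataset[mapping[p]].to_numpy(dtype=float)
    return pd.DataFrame(cols, index=dataset.index)


def fit_cline_models(
    dataset: pd.DataFrame,
    tree: TreeNode,
    response: str = "frequency",
    logit_scale: bool = False,
) -> dict[str, PglsFit]:
    """Fit the null (ancestry only), latitude, temperature and full PGLS
    models on a shared Brownian covariance.

    ``dataset`` is indexed by population with columns ``frequency``,
    ``latitude_deg`` and ``temp_c``; populations must match the tree tips.
    The response is the raw frequency by default, logit-transformed when
    ``logit_scale`` is set.
    """
    cov = bm_covariance(tree)
    pops = list(dataset.index)
    if set(pops) != set(cov.index):
        raise ValueError("dataset populations do not match tree tips")
    V = cov.loc[pops, pops].to_numpy()
    y = dataset[response].to_numpy(dtype=float)
    if logit_scale:
        eps = 1e-6
        y = np.log(np.clip(y, eps, 1 - eps) / (1 - np.clip(y, eps, 1 - eps)))
    out = {}
    subsets = [(), ("latitude",), ("temperature",), ("latitude", "temperature")]
    labels = ["null", "latitude", "temperature", "full"]
    for label, preds in zip(labels, subsets):
        X = _design(dataset, preds)
        out[label] = pgls_fit(y, X, V, predictors=preds)
    return out


def leave_one_out_stability(
    dataset: pd.DataFrame,
    tree: TreeNode,
    response: str = "frequency",
    slope_predictor: str = "latitude",
    logit_scale: bool = False,
) -> pd.DataFrame:
    """Refit the full model with each population (and its tip) left out.

    Returns one row per left-out population with the refitted latitude and
    temperature coefficients; populations whose removal would leave fewer
    than 3 tips are skipped with a warning.
    """
    if len(dataset) < 4:
        raise ValueError("need at least 4 populations for leave-one-out")
    rows = []
    for pop in dataset.index:
        if len(dataset) - 1 < 3:
            logger.warning("skipping %s: too few populations would remain", pop)
            continue
        sub = dataset.drop(index=pop)
        pruned = tree.copy().shear(list(sub.index))
        pruned.prune()
        fits = fit_cline_models(sub, pruned, response=response, logit_scale=logit_scale)
        full = fits["full"]
        rows.append(
            {
                "left_out": pop,
                "latitude": full.params["latitude"],
                "temperature": full.params["temperature"],
                "loglik": full.loglik,
            }
        )
    out = pd.DataFrame(rows).set_index("left_out")
    out.attrs["slope_min"] = float(out[slope_predictor].min())
    out.attrs["slope_max"] = float(out[slope_predictor].max())
    return out
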