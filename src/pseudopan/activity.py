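"""Transcription calling and parent-gene statistics.

Transcription is called with strict FPKM cutoffs (a pseudogene counts as
transcribed only when FPKM exceeds the cutoff) after restricting
quantification to uniquely mappable exon pieces longer than 100 bp.
Parent-versus-non-parent expression contrasts use the Mann-Whitney U test;
the relationship between paralog counts and pseudogene counts is fitted
linearly for duplicated pseudogenes and logarithmically for processed
ones; and gene essentiality is modelled as a function of parent status and
transcription with both a linear probability model (OLS) and a probit
model (Newton-Raphson maximum likelihood), reporting the parent-status
marginal effect at covariate means.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import mannwhitneyu, norm, spearmanr, ttest_ind


# ---------------------------------------------------------------------------
# mappability filtering


def mappability_filter(exons: list, mappability_track: pd.DataFrame,
                       min_len_bp: int = 100) -> list:
    """Retain, per exon, its uniquely mappable pieces longer than min_len_bp.

    ``exons`` is a list of (chrom, start, end); the track is a DataFrame of
    uniquely mappable (chrom, start, end) intervals.  Returns the retained
    pieces; an element with no surviving piece should be excluded from
    quantification by the caller.
    """
    trees = defaultdict(IntervalTree)
    for row in mappability_track.itertuples():
        if row.start < row.end:
            trees[row.chrom].addi(row.start, row.end)
    retained = []
    for chrom, start, end in exons:
        for iv in sorted(trees.get(chrom, IntervalTree()).overlap(start, end)):
            a, b = max(start, iv.begin), min(end, iv.end)
            if b - a > min_len_bp:
                retained.append((chrom, a, b))
    return retained


def quantifiable_records(records: list, mappability_track: pd.DataFrame,
                         min_len_bp: int = 100) -> list:
    """Records with at least one uniquely mappable exon piece > min_len_bp."""
    out = []
    for r in records:
        exons = ([(r.chrom, a, b) for a, b in r.exon_intervals]
                 if r.exon_intervals else [(r.chrom, r.start, r.end)])
        if mappability_filter(exons, mappability_track, min_len_bp=min_len_bp):
            out.append(r)
    return out


# ---------------------------------------------------------------------------
# transcription calling


def call_transcribed(table: pd.DataFrame, cutoff_fpkm: float):
    """Strictly-greater-than-cutoff transcription calls per column.

    Returns (dict column -> set of transcribed uids, breadth Series giving
    the number of columns in which each uid is transcribed).
    """
    if cutoff_fpkm < 0:
        raise ValueError("cutoff must be >= 0")
    above = table > cutoff_fpkm
    per_col = {c: set(table.index[above[c]]) for c in table.columns}
    breadth = above.sum(axis=1)
    breadth.name = "breadth"
    return per_col, breadth


def transcribed_any(table: pd.DataFrame, cutoff_fpkm: float) -> set:
    """Uids transcribed (strictly above cutoff) in at least one column."""
    _, breadth = call_transcribed(table, cutoff_fpkm)
    return set(breadth.index[breadth > 0])


# ---------------------------------------------------------------------------
# parent-gene contrasts


def parent_expression_contrast(expression, parent_flags, test: str = "mannwhitney"):
    """Compare expression of pseudogene parents against non-parents.

    Returns dict with median_difference (parents minus non-parents), the
    test statistic and two-sided p-value.
    """
    x = np.asarray(expression, dtype=float)
    flags = np.asarray(parent_flags, dtype=bool)
    parents, others = x[flags], x[~flags]
    if len(parents) == 0 or len(others) == 0:
        raise ValueError("both groups must be non-empty")
    if test == "mannwhitney":
        stat, p = mannwhitneyu(parents, others, alternative="two-sided")
    elif test == "welch":
        stat, p = ttest_ind(parents, others, equal_var=False)
    else:
        raise ValueError(f"unknown test {test!r}")
    return {
        "median_difference": float(np.median(parents) - np.median(others)),
        "statistic": float(stat), "p_value": float(p),
        "n_parents": int(flags.sum()), "n_others": int((~flags).sum()),
    }


def paralog_pseudogene_fit(n_paralogs, n_pseudogenes, biotype: str = "processed"):
    """Fit pseudogene counts against paralog counts per parent gene.

    Duplicated mode fits y = a + b*x (line); processed mode fits
    y = a + b*ln(x+1), where b < 0 reflects large families producing few
    processed pseudogenes per member.  Returns dict with a, b, and the
    Spearman correlation.
    """
    x = np.asarray(n_paralogs, dtype=float)
    y = np.asarray(n_pseudogenes, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 parents")
    if np.std(x) == 0:
        raise ValueError("zero variance in paralog counts")
    pred = x if biotype == "duplicated" else np.log1p(x)
    X = np.column_stack([np.ones_like(pred), pred])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    rho, p = spearmanr(x, y)
    return {"a": float(beta[0]), "b": float(beta[1]),
            "spearman_rho": float(rho), "spearman_p": float(p), "mode": biotype}


# ---------------------------------------------------------------------------
# essentiality models


@dataclass
class EssentialityModelFit:
    """Fitted essentiality model (linear probability or probit)."""

    model: str
    coefficients: dict
    standard_errors: dict
    marginal_effect: float
    log_likelihood: float | None = None
    converged: bool = True
    n_iterations: int = 0
    covariates: list = field(default_factory=lambda: ["intercept", "parent_status", "log_expression"])
    covariance: np.ndarray | None = None
    covariate_means: np.ndarray | None = None

    @property
    def marginal_effect_se(self) -> float:
        """Delta-method standard error of the parent-status marginal effect."""
        if self.covariance is None:
            raise ValueError("fit carries no covariance matrix")
        beta = np.array(list(self.coefficients.values()))
        if self.model == "lpm":
            return float(np.sqrt(self.covariance[1, 1]))
        x1, x0 = self.covariate_means.copy(), self.covariate_means.copy()
        x1[1], x0[1] = 1.0, 0.0
        grad = norm.pdf(x1 @ beta) * x1 - norm.pdf(x0 @ beta) * x0
        return float(np.sqrt(grad @ self.covariance @ grad))

    def __post_init__(self):
        if self.log_likelihood is not None and self.log_likelihood > 1e-9:
            raise ValueError("probit log-likelihood must be <= 0")
        if not -1.0 <= self.marginal_effect <= 1.0:
            raise ValueError("marginal effect must lie in [-1, 1]")


def _design(parent_status, expression):
    p = np.asarray(parent_status, dtype=float)
    x = np.asarray(expression, dtype=float)
    return np.column_stack([np.ones_like(p), p, x])


def fit_lpm(essential, parent_status, expression) -> EssentialityModelFit:
    """Linear probability model: OLS of essentiality on parent status and
    transcription; the parent coefficient is itself the marginal effect."""
    y = np.asarray(essential, dtype=float)
    X = _design(parent_status, expression)
    n, k = X.shape
    if n <= k:
        raise ValueError("need more observations than coefficients")
    if np.std(y) == 0:
        raise ValueError("zero-variance response")
    if np.linalg.matrix_rank(X) < k:
        raise ValueError("design matrix is rank deficient")
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ (X.T @ y)
    resid = y - X @ beta
    sigma2 = float(resid @ resid) / (n - k)
    se = np.sqrt(np.diag(sigma2 * XtX_inv))
    names = ["intercept", "parent_status", "log_expression"]
    return EssentialityModelFit(
        model="lpm",
        coefficients=dict(zip(names, map(float, beta))),
        standard_errors=dict(zip(names, map(float, se))),
        marginal_effect=float(beta[1]),
        covariance=sigma2 * XtX_inv, covariate_means=X.mean(axis=0))


def probit_log_likelihood(beta, y, X) -> float:
    z = X @ np.asarray(beta, dtype=float)
    ll = np.where(y > 0.5, norm.logcdf(z), norm.logcdf(-z))
    return float(ll.sum())


def fit_probit(essential, parent_status, expression, tol: float = 1e-8,
               max_iter: int = 100) -> EssentialityModelFit:
    """Probit model fitted by Newton-Raphson (Fisher scoring).

    The marginal effect of parent status is Phi(x_bar . beta | parent=1)
    minus Phi(x_bar . beta | parent=0) with other covariates at their means.
    Perfect separation raises rather than returning runaway coefficients.
    """
    y = np.asarray(essential, dtype=float)
    X = _design(parent_status, expression)
    n, k = X.shape
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present")
    if np.linalg.matrix_rank(X) < k:
        raise ValueError("design matrix is rank deficient")
    beta = np.zeros(k)
    ll_old = probit_log_likelihood(beta, y, X)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        z = X @ beta
        pdf = norm.pdf(z)
        cdf = np.clip(norm.cdf(z), 1e-12, 1 - 1e-12)
        score = X.T @ (pdf * (y - cdf) / (cdf * (1 - cdf)))
        w = pdf ** 2 / (cdf * (1 - cdf))
        info = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise ValueError("probit information matrix is singular "
                             "(possible perfect separation)") from exc
        beta = beta + step
        if np.abs(beta).max() > 50.0:
            raise ValueError("perfect separation detected: coefficients diverged")
        ll_new = probit_log_likelihood(beta, y, X)
        if abs(ll_new - ll_old) < tol and np.abs(step).max() < np.sqrt(tol):
            converged = True
            ll_old = ll_new
            break
        ll_old = ll_new
    z = X @ beta
    pdf = norm.pdf(z)
    cdf = np.clip(norm.cdf(z), 1e-12, 1 - 1e-12)
    w = pdf ** 2 / (cdf * (1 - cdf))
    info = (X * w[:, None]).T @ X
    cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    xbar = X.mean(axis=0)
    x1, x0 = xbar.copy(), xbar.copy()
    x1[1], x0[1] = 1.0, 0.0
    me = float(norm.cdf(x1 @ beta) - norm.cdf(x0 @ beta))
    names = ["intercept", "parent_status", "log_expression"]
    return EssentialityModelFit(
        model="probit",
        coefficients=dict(zip(names, map(float, beta))),
        standard_errors=dict(zip(names, map(float, se))),
        marginal_effect=me, log_likelihood=ll_old,
        converged=converged, n_iterations=it,
        covariance=cov, covariate_means=xbar)


def essentiality_enrichment(essential, parent_status) -> float:
    """Naive enrichment: P(essential | parent) / P(essential | non-parent)."""
    y = np.asarray(essential, dtype=float)
    p = np.asarray(parent_status, dtype=bool)
    if p.all() or (~p).all():
        raise ValueError("need both parents and non-parents")
    base = y[~p].mean()
    if base == 0:
        raise ValueError("no essential non-parent genes; enrichment undefined")
    return float(y[p].mean() / base)


# ---------------------------------------------------------------------------
# disablement density


def disablement_density_trend(records: list):
    """Disablements-per-bp against divergence from the parent (100 - identity).

    Returns dict with the least-squares slope and the Spearman correlation;
    a positive trend means older pseudogenes carry more disablements.
    """
    if len(records) < 3:
        raise ValueError("need at least 3 records")
    div = np.array([100.0 - r.pct_identity for r in records])
    dens = np.array([sum(r.disablements.values()) / r.length for r in records])
    X = np.column_stack([np.ones_like(div), div])
    beta, *_ = np.linalg.lstsq(X, dens, rcond=None)
    if np.std(dens) == 0 or np.std(div) == 0:
        rho, p = 0.0, 1.0
    else:
        rho, p = spearmanr(div, dens)
    return {"slope": float(beta[1]), "intercept": float(beta[0]),
            "spearman_rho": float(rho), "spearman_p": float(p)}
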