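"""Differential OTU abundance between H and D groups.

Counts are filtered (total > min_total, relative-abundance variance >
min_variance), normalized by median-of-ratios scaling factors, fitted with
a single common negative-binomial dispersion by conditional maximum
likelihood, and tested OTU-by-OTU with a two-sided exact test that
conditions on the two-group sum, followed by Benjamini-Hochberg FDR control.

The NB is parameterized as variance = mu + phi * mu^2; phi = 0 is Poisson.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .datatypes import OTUTable

__all__ = [
    "filter_otus",
    "scaling_normalize",
    "pseudo_counts",
    "estimate_dispersion",
    "exact_test",
    "exact_test_pvalue",
    "bh_adjust",
    "ExactTestResult",
]

log = logging.getLogger(__name__)


@dataclass
class ExactTestResult:
    table: pd.DataFrame          # columns: otu_id, taxonomy, log2fc, p, fdr
    dispersion: float
    scaling_factors: pd.Series


def filter_otus(
    table: OTUTable, min_total: int = 3, min_variance: float = 1e-8
) -> OTUTable:
    """Drop OTUs with total count <= ``min_total`` (strict "more than")
    or relative-abundance variance <= ``min_variance``.

    The variance filter acts on per-sample relative abundances (configurable
    semantics live here: pass ``min_variance=0`` to disable all but the
    constant-OTU removal).
    """
    counts = table.counts
    if counts.empty:
        raise ValueError("empty OTU table")
    keep_total = counts.sum(axis=1) > min_total
    rel = counts / counts.sum(axis=0).replace(0, np.nan)
    keep_var = rel.var(axis=1, ddof=1) > min_variance
    keep = keep_total & keep_var
    if not keep.any():
        raise ValueError(
            f"all {len(keep)} OTUs removed (min_total={min_total}, "
            f"min_variance={min_variance}); totals range "
            f"{counts.sum(axis=1).min()}..{counts.sum(axis=1).max()}"
        )
    return OTUTable(
        counts=counts.loc[keep],
        taxonomy=table.taxonomy.loc[keep],
        sample_meta=table.sample_meta,
    )


def scaling_normalize(table: OTUTable) -> tuple[pd.Series, pd.DataFrame]:
    """Median-of-ratios scaling factors and normalized counts.

    The reference profile is the per-OTU geometric mean over samples,
    restricted to OTUs nonzero in every sample; each sample's factor is the
    median ratio to the reference, rescaled so factors have geometric mean
    one. Normalized count = raw / factor. If no OTU is present in all
    samples the factors fall back to total counts (warning logged).
    """
    counts = table.counts
    if (counts.sum(axis=0) == 0).any():
        raise ValueError("every sample needs at least one nonzero OTU")
    allpos = (counts > 0).all(axis=1)
    if allpos.any():
        sub = counts.loc[allpos].astype(float)
        ref = np.exp(np.log(sub).mean(axis=1))
        factors = sub.div(ref, axis=0).median(axis=0)
    else:
        log.warning("no OTU present in all samples; falling back to total-count factors")
        factors = counts.sum(axis=0).astype(float)
    factors = factors / np.exp(np.log(factors).mean())
    return factors, counts / factors


def pseudo_counts(counts: pd.DataFrame, factors: pd.Series) -> pd.DataFrame:
    """Integer counts adjusted to a common effective library.

    Raw counts are divided by the sample's scaling factor (factors have
    geometric mean 1, so the common library is the geometric-mean scale)
    and rounded half-up — the integer input the exact test requires.
    """
    adj = counts / factors
    return np.floor(adj + 0.5).astype(np.int64)


def _conditional_loglik(r: float, counts: np.ndarray, groups: np.ndarray) -> float:
    """Log conditional likelihood of NB counts given per-group sums.

    For n iid NB(r, p) counts the distribution given their sum s is
    Dirichlet-multinomial with concentration r, free of p:
    P(y | s) = prod C(y_i + r - 1, y_i) / C(s + n r - 1, s).
    Summed over OTUs (rows) and over the two groups.
    """
    ll = 0.0
    for glab in np.unique(groups):
        y = counts[:, groups == glab]
        n = y.shape[1]
        s = y.sum(axis=1)
        ll += float(
            np.sum(special.gammaln(y + r) - special.gammaln(r) - special.gammaln(y + 1))
            + np.sum(special.gammaln(n * r) + special.gammaln(s + 1) - special.gammaln(s + n * r))
        )
    return ll


def estimate_dispersion(table: OTUTable, groups=None) -> float:
    """Common NB dispersion phi by conditional maximum likelihood.

    Counts are first adjusted to equal libraries (``pseudo_counts`` with
    median-of-ratios factors); the conditional likelihood — which does not
    involve the per-OTU means — is summed over all OTUs and maximized over
    phi = 1/r on a log scale. Returns phi >= 0 (numerically, >= 1e-10).
    """
    if groups is None:
        groups = table.groups()
    g = np.asarray(list(groups))
    _, counts_per_group = np.unique(g, return_counts=True)
    if np.any(counts_per_group < 2):
        raise ValueError(
            "dispersion undefined with a single sample in a group; "
            "override with phi=0 if counts are Poisson"
        )
    factors, _ = scaling_normalize(table)
    pseudo = pseudo_counts(table.counts, factors).values

    def neg_ll(log_phi: float) -> float:
        return -_conditional_loglik(1.0 / np.exp(log_phi), pseudo, g)

    res = optimize.minimize_scalar(neg_ll, bounds=(np.log(1e-10), np.log(50.0)), method="bounded")
    phi = float(np.exp(res.x))
    return 0.0 if phi <= 2e-10 else phi


def exact_test_pvalue(
    s1: int, s2: int, n1: int, n2: int, phi: float, two_sided: str = "min-likelihood"
) -> float:
    """Two-sided exact NB p-value for an observed split (s1 | s2).

    Conditions on s = s1 + s2: under the null of equal means, the group-1
    sum is distributed over a = 0..s with P(a) proportional to
    NB(a; n1 r, p) * NB(s - a; n2 r, p), r = 1/phi (binomial with
    probability n1/(n1+n2) in the Poisson limit phi = 0). The two-sided p
    sums P over every split no more probable than the observed one
    (``min-likelihood``) or doubles the smaller tail (``double-tail``).
    """
    s = int(s1 + s2)
    if s == 0:
        return 1.0
    a = np.arange(s + 1)
    if phi <= 0:
        logp = stats.binom.logpmf(a, s, n1 / (n1 + n2))
    else:
        r = 1.0 / phi
        mu = s / (n1 + n2)          # any common per-sample mean works
        p = r / (r + mu)
        logp = stats.nbinom.logpmf(a, n1 * r, p) + stats.nbinom.logpmf(s - a, n2 * r, p)
        logp = logp - special.logsumexp(logp)
    prob = np.exp(logp)
    obs = prob[int(s1)]
    if two_sided == "min-likelihood":
        pval = float(prob[prob <= obs * (1 + 1e-12)].sum())
    elif two_sided == "double-tail":
        lower = float(prob[: int(s1) + 1].sum())
        upper = float(prob[int(s1):].sum())
        pval = 2.0 * min(lower, upper)
    else:
        raise ValueError(f"unknown two_sided rule: {two_sided}")
    return min(pval, 1.0)


def exact_test(
    table: OTUTable,
    groups=None,
    phi: float | None = None,
    prior_count: float = 0.125,
    two_sided: str = "min-likelihood",
) -> ExactTestResult:
    """Per-OTU two-sided exact NB test of H vs D differential abundance.

    Counts are adjusted to a common library (median-of-ratios pseudo-counts)
    and each OTU's (H-sum | D-sum) split is tested conditionally on its
    total. log2FC is the H/D ratio of mean normalized counts with
    ``prior_count`` added to each group mean so structural zeros stay
    finite. FDR by Benjamini-Hochberg.
    """
    if groups is None:
        groups = table.groups()
    g = np.asarray(list(groups))
    uniq = np.unique(g)
    if len(uniq) != 2:
        raise ValueError(f"exact test needs exactly 2 groups, got {list(uniq)}")
    # H vs D orientation when present, else lexicographic
    g1, g2 = ("H", "D") if set(uniq) == {"H", "D"} else (uniq[0], uniq[1])
    factors, norm = scaling_normalize(table)
    if phi is None:
        phi = estimate_dispersion(table, g)
    pseudo = pseudo_counts(table.counts, factors)
    m1 = g == g1
    m2 = g == g2
    n1, n2 = int(m1.sum()), int(m2.sum())
    s1 = pseudo.loc[:, m1].sum(axis=1)
    s2 = pseudo.loc[:, m2].sum(axis=1)
    pvals = np.array([
        exact_test_pvalue(int(a), int(b), n1, n2, phi, two_sided=two_sided)
        for a, b in zip(s1.values, s2.values)
    ])
    mean1 = norm.loc[:, m1].mean(axis=1) + prior_count
    mean2 = norm.loc[:, m2].mean(axis=1) + prior_count
    log2fc = np.log2(mean1 / mean2)
    out = pd.DataFrame(
        {
            "otu_id": table.counts.index,
            "taxonomy": table.taxonomy.values,
            "log2fc": log2fc.values,
            "p": pvals,
            "fdr": bh_adjust(pvals),
        }
    ).set_index("otu_id", drop=False)
    return ExactTestResult(table=out, dispersion=float(phi), scaling_factors=factors)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    adjusted_(i) = min_{j >= i} p_(j) * m / j over the ascending order
    statistics, capped at 1.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out
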