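"""Nonparametric group comparisons for fitted diffusion coefficients.

Thin, explicit wrappers around SciPy's rank tests plus two post-hoc
procedures after Kruskal-Wallis: Dunn's z-test on mean ranks (the standard
choice) and Tukey's HSD applied to rank-transformed data (an alternative
sometimes reported in the literature).  All results come back as a uniform
:class:`TestResult` record.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "mann_whitney_u",
    "kruskal_wallis",
    "posthoc_pairwise",
]


@dataclass
class TestResult:
    statistic: float
    pvalue: float
    method: str
    group_sizes: tuple

    def __post_init__(self) -> None:
        if not 0.0 <= self.pvalue <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def mann_whitney_u(x, y, alternative: str = "two-sided") -> TestResult:
    """Mann-Whitney U test with midrank ties.

    Exact p by enumeration for combined sample size <= 12 without ties,
    normal approximation with tie correction otherwise (SciPy's switching
    rule matches this policy via ``method='auto'``... the method actually
    used is recorded in the label).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    has_ties = len(np.unique(np.concatenate([x, y]))) < x.size + y.size
    method = "exact" if (x.size + y.size <= 12 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative=alternative, method=method)
    return TestResult(
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
        method=f"mann-whitney-{method}",
        group_sizes=(x.size, y.size),
    )


def kruskal_wallis(groups) -> TestResult:
    """Kruskal-Wallis H test with tie correction and chi-squared p-value."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(g.size < 2 for g in groups):
        raise ValueError("each group needs at least two observations")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        # degenerate: no rank variation at all
        return TestResult(
            statistic=0.0,
            pvalue=1.0,
            method="kruskal-wallis",
            group_sizes=tuple(g.size for g in groups),
        )
    res = sps.kruskal(*groups)
    return TestResult(
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
        method="kruskal-wallis",
        group_sizes=tuple(g.size for g in groups),
    )


def _dunn(groups, labels, p_adjust):
    pooled = np.concatenate(groups)
    n = pooled.size
    ranks = sps.rankdata(pooled)
    mean_ranks = []
    i0 = 0
    for g in groups:
        mean_ranks.append(ranks[i0 : i0 + g.size].mean())
        i0 += g.size
    # tie correction to the rank variance
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (12.0 * (n - 1))
    var_base = n * (n + 1) / 12.0 - tie_term
    results = []
    raw_p = []
    pairs = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            se = np.sqrt(var_base * (1.0 / groups[i].size + 1.0 / groups[j].size))
            z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
            p = 2.0 * sps.norm.sf(abs(z))
            pairs.append((labels[i], labels[j], z, groups[i].size, groups[j].size))
            raw_p.append(min(p, 1.0))
    if p_adjust:
        adj = multipletests(raw_p, method=p_adjust)[1]
    else:
        adj = raw_p
    for (la, lb, z, na, nb), p in zip(pairs, adj):
        results.append(
            (
                (la, lb),
                TestResult(
                    statistic=float(z),
                    pvalue=float(p),
                    method=f"dunn{'-' + p_adjust if p_adjust else ''}",
                    group_sizes=(na, nb),
                ),
            )
        )
    return dict(results)


def _tukey_on_ranks(groups, labels):
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    pooled = np.concatenate(groups)
    ranks = sps.rankdata(pooled)
    group_labels = np.concatenate(
        [[labels[i]] * g.size for i, g in enumerate(groups)]
    )
    res = pairwise_tukeyhsd(ranks, group_labels)
    out = {}
    for row, p in zip(res.summary().data[1:], res.pvalues):
        la, lb = str(row[0]), str(row[1])
        na = next(g.size for i, g in enumerate(groups) if labels[i] == la)
        nb = next(g.size for i, g in enumerate(groups) if labels[i] == lb)
        out[(la, lb)] = TestResult(
            statistic=float(row[2]),
            pvalue=float(p),
            method="tukey-hsd-on-ranks",
            group_sizes=(na, nb),
        )
    return out


def posthoc_pairwise(
    groups,
    labels=None,
    method: str = "dunn",
    p_adjust: str | None = None,
) -> dict:
    """All-pairs post-hoc comparisons after a Kruskal-Wallis test.

    ``method='dunn'`` (default) performs Dunn's z-tests on mean ranks with
    tie correction; ``method='tukey_on_ranks'`` applies Tukey's HSD to the
    rank-transformed data.  ``p_adjust`` (e.g. ``'holm'``) applies a
    multiple-testing correction to Dunn p-values; Tukey's HSD already
    controls the family-wise error by construction.  Returns a dict keyed
    by label pairs.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if labels is None:
        labels = [f"group{i}" for i in range(len(groups))]
    if len(labels) != len(groups):
        raise ValueError("labels must match groups")
    if method == "dunn":
        return _dunn(groups, labels, p_adjust)
    if method == "tukey_on_ranks":
        return _tukey_on_ranks(groups, labels)
    raise ValueError(f"unknown post-hoc method {method!r}")
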