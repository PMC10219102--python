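"""Group statistics for descriptor and MFI tables.

The comparison layer mirrors common cytometry practice: Shapiro-Wilk
normality screening; for matched (paired) designs Wilcoxon signed-rank
(two groups) or the Friedman omnibus followed by pairwise Wilcoxon with
Benjamini-Hochberg FDR adjustment; for independent designs Kruskal-Wallis
followed by Dunn's z tests (tie-corrected pooled ranks) with BH adjustment.
Normally distributed data may instead be dispatched to t-tests or
ANOVA + Tukey.  p < 0.05 is the conventional significance level.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from itertools import combinations
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "StatResult",
    "normality",
    "bh_adjust",
    "compare_paired",
    "compare_unpaired_multi",
    "dunn_posthoc",
    "anova_two_way",
    "ALPHA",
]

ALPHA = 0.05


@dataclass
class StatResult:
    test: str
    groups: tuple[str, ...]
    statistic: float
    p: float
    p_adjusted: float | None = None
    method_adjust: Literal["BH", "Tukey", "none"] = "none"
    n_per_group: tuple[int, ...] = ()

    def to_dict(self) -> dict:
        return asdict(self)


def normality(values, name: str = "sample") -> StatResult:
    """Shapiro-Wilk test of normality (3 <= n <= 5000)."""
    x = np.asarray(values, dtype=float)
    if not 3 <= len(x) <= 5000:
        raise ValueError(f"Shapiro-Wilk requires 3 <= n <= 5000, got {len(x)}")
    if np.ptp(x) == 0:
        raise ValueError("constant sample: normality test undefined (zero variance)")
    w, p = sps.shapiro(x)
    return StatResult("shapiro-wilk", (name,), float(w), float(p),
                      n_per_group=(len(x),))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def _is_normal(groups) -> bool:
    try:
        return all(normality(g).p > ALPHA for g in groups)
    except ValueError:
        return False


def _wilcoxon(a, b) -> tuple[float, float]:
    """Paired Wilcoxon signed-rank: exact for n <= 25 (no zero diffs),
    normal approximation with continuity correction above."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    d = a - b
    n_nonzero = int(np.sum(d != 0))
    if n_nonzero == 0:
        return 0.0, 1.0
    method = "exact" if n_nonzero <= 25 else "approx"
    res = sps.wilcoxon(a, b, zero_method="wilcox", correction=(method == "approx"),
                       method=method)
    return float(res.statistic), float(res.pvalue)


def compare_paired(
    groups: Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
    parametric: Literal["auto", "never", "force"] = "never",
) -> list[StatResult]:
    """Compare >= 2 matched samples.

    Two groups: Wilcoxon signed-rank (or paired t-test on normal data with
    ``parametric='auto'``).  More: Friedman omnibus plus all pairwise
    Wilcoxon tests BH-adjusted (or repeated-measures ANOVA is *not*
    attempted; normal data under 'auto' falls back to paired t-tests with
    BH).  Group sizes must match (matched design).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    n = len(groups[0])
    if any(len(g) != n for g in groups):
        raise ValueError("paired comparison requires equal n in every group")
    if n < 5:
        raise ValueError(f"need n >= 5 matched observations, got {n}")
    labels = list(labels) if labels else [f"g{i}" for i in range(len(groups))]

    use_param = (parametric == "force") or (parametric == "auto" and _is_normal(groups))

    results: list[StatResult] = []
    if len(groups) == 2:
        if use_param:
            t, p = sps.ttest_rel(groups[0], groups[1])
            results.append(StatResult("paired-t", tuple(labels), float(t), float(p),
                                      n_per_group=(n, n)))
        else:
            w, p = _wilcoxon(groups[0], groups[1])
            results.append(StatResult("wilcoxon", tuple(labels), w, p,
                                      n_per_group=(n, n)))
        return results

    if np.allclose(np.ptp(np.column_stack(groups), axis=1), 0):
        omni_stat, omni_p = 0.0, 1.0
    else:
        omni_stat, omni_p = sps.friedmanchisquare(*groups)
    results.append(
        StatResult("friedman", tuple(labels), float(omni_stat), float(omni_p),
                   n_per_group=tuple(len(g) for g in groups))
    )

    pair_results = []
    for i, j in combinations(range(len(groups)), 2):
        if use_param:
            stat, p = sps.ttest_rel(groups[i], groups[j])
            name = "paired-t"
        else:
            stat, p = _wilcoxon(groups[i], groups[j])
            name = "wilcoxon"
        pair_results.append((name, (labels[i], labels[j]), float(stat), float(p)))
    adj = bh_adjust([r[3] for r in pair_results])
    for (name, pair, stat, p), pa in zip(pair_results, adj):
        results.append(StatResult(name, pair, stat, p, float(pa), "BH", (n, n)))
    return results


def dunn_posthoc(
    groups: Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
) -> list[StatResult]:
    """Dunn's post-hoc z tests on pooled ranks with tie correction.

    z_ij = (R̄_i − R̄_j) / sqrt[(N(N+1)/12 − T)(1/n_i + 1/n_j)] with the tie
    term T = Σ(t³ − t) / (12 (N − 1)); two-sided normal p, BH-adjusted.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    labels = list(labels) if labels else [f"g{i}" for i in range(len(groups))]
    pooled = np.concatenate(groups)
    N = len(pooled)
    ranks = sps.rankdata(pooled)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (N - 1))

    mean_ranks, sizes = [], []
    start = 0
    for g in groups:
        mean_ranks.append(float(ranks[start : start + len(g)].mean()))
        sizes.append(len(g))
        start += len(g)

    raw = []
    for i, j in combinations(range(len(groups)), 2):
        se = np.sqrt((N * (N + 1) / 12.0 - tie_term) * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p = 2.0 * sps.norm.sf(abs(z))
        raw.append(((labels[i], labels[j]), float(z), float(p), (sizes[i], sizes[j])))
    adj = bh_adjust([r[2] for r in raw])
    return [
        StatResult("dunn", pair, z, p, float(pa), "BH", ns)
        for (pair, z, p, ns), pa in zip(raw, adj)
    ]


def compare_unpaired_multi(
    groups: Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
) -> list[StatResult]:
    """Kruskal-Wallis omnibus over >= 3 independent groups, followed by
    Dunn's pairwise z tests with BH adjustment."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 3:
        raise ValueError("need >= 3 groups (use a pairwise test for 2)")
    if any(len(g) < 3 for g in groups):
        raise ValueError("every group needs n >= 3")
    labels = list(labels) if labels else [f"g{i}" for i in range(len(groups))]

    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        omni = StatResult("kruskal-wallis", tuple(labels), 0.0, 1.0,
                          n_per_group=tuple(len(g) for g in groups))
    else:
        h, p = sps.kruskal(*groups)
        omni = StatResult("kruskal-wallis", tuple(labels), float(h), float(p),
                          n_per_group=tuple(len(g) for g in groups))
    return [omni] + dunn_posthoc(groups, labels)


def anova_two_way(
    df: pd.DataFrame,
    response: str,
    factor_a: str,
    factor_b: str,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-way ANOVA (type II) with Tukey HSD on the factor_a margins.

    Returns (anova_table, tukey_table); used for normally distributed MFI
    comparisons across subsets and treatments.
    """
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    d = df.rename(columns={response: "y", factor_a: "fa", factor_b: "fb"})
    model = smf.ols("y ~ C(fa) * C(fb)", data=d).fit()
    table = anova_lm(model, typ=2)
    tukey = pairwise_tukeyhsd(d["y"], d["fa"])
    tukey_df = pd.DataFrame(
        tukey.summary().data[1:], columns=tukey.summary().data[0]
    )
    return table, tukey_df
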