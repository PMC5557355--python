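"""Group-comparison statistics and qPCR relative quantification.

The test battery mirrors common practice for morphometric group data: a
D'Agostino-Pearson normality gate selecting between one-way ANOVA (with
Tukey HSD post-hoc) and Kruskal-Wallis (with Dunn's rank post-hoc),
Mann-Whitney U for two-group comparisons, and the two-sample
Kolmogorov-Smirnov test for comparing cluster-area distributions.  Post-hoc
tests are computed only when the omnibus p-value clears alpha.

Relative expression from qPCR Ct tables uses the Livak 2^-ddCt model with an
implicit amplification efficiency of 2: dCt subtracts the housekeeping-gene
mean per condition, ddCt subtracts the reference condition's mean dCt, and
higher expression than the reference yields a fold change above 1.

Dunn's post-hoc (z-tests on mean ranks with tie correction) is implemented
here directly; Bonferroni adjustment by default, Holm available.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "kruskal_wallis_dunn",
    "dunn_posthoc",
    "mann_whitney",
    "ks_two_sample",
    "anova_tukey",
    "ddct_fold_change",
    "normality_gate",
    "auto_group_test",
]


@dataclass
class TestResult:
    """Outcome of one hypothesis test (plus optional post-hoc pairs)."""

    test_name: str
    statistic: float
    p_value: float
    posthoc: list[tuple[tuple[str, str], float]] | None = None
    meta: dict = field(default_factory=dict)


def _check_groups(groups: dict[str, np.ndarray], min_groups: int = 2,
                  min_n: int = 1) -> dict[str, np.ndarray]:
    if len(groups) < min_groups:
        raise ValueError(f"need at least {min_groups} groups")
    out = {}
    for name, vals in groups.items():
        arr = np.asarray(vals, dtype=float).ravel()
        if arr.size < min_n:
            raise ValueError(f"group '{name}' has fewer than {min_n} values")
        out[name] = arr
    return out


def _adjust(pvals: list[float], method: str) -> list[float]:
    m = len(pvals)
    if method == "bonferroni":
        return [min(1.0, p * m) for p in pvals]
    if method == "holm":
        order = np.argsort(pvals)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * pvals[idx])
            adj[idx] = min(1.0, running)
        return adj.tolist()
    raise ValueError("adjustment must be 'bonferroni' or 'holm'")


def dunn_posthoc(groups: dict[str, np.ndarray],
                 adjust: str = "bonferroni"
                 ) -> list[tuple[tuple[str, str], float]]:
    """Dunn's multiple-comparison z-tests on pooled mean ranks.

    z_ij = (rbar_i - rbar_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j)) with the
    tie term T = sum(t^3 - t) / (12 (N - 1)); two-sided normal p-values,
    family-wise adjusted.
    """
    groups = _check_groups(groups)
    names = list(groups)
    pooled = np.concatenate([groups[n] for n in names])
    ranks = sps.rankdata(pooled)
    n_tot = pooled.size
    mean_ranks = {}
    start = 0
    for n in names:
        size = groups[n].size
        mean_ranks[n] = ranks[start : start + size].mean()
        start += size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_tot - 1))
    var_base = n_tot * (n_tot + 1) / 12.0 - tie_term

    pairs = list(itertools.combinations(names, 2))
    raw = []
    for a, b in pairs:
        se = math.sqrt(var_base * (1.0 / groups[a].size + 1.0 / groups[b].size))
        z = 0.0 if se == 0 else (mean_ranks[a] - mean_ranks[b]) / se
        raw.append(2.0 * sps.norm.sf(abs(z)))
    adj = _adjust(raw, adjust)
    return [((a, b), p) for (a, b), p in zip(pairs, adj)]


def kruskal_wallis_dunn(groups: dict[str, list | np.ndarray],
                        alpha: float = 0.05,
                        adjust: str = "bonferroni") -> TestResult:
    """Kruskal-Wallis H (tie-corrected) with Dunn post-hoc when p < alpha."""
    groups = _check_groups(groups)
    arrays = list(groups.values())
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        h, p = 0.0, 1.0
    else:
        h, p = sps.kruskal(*arrays)
    posthoc = dunn_posthoc(groups, adjust) if p < alpha else None
    return TestResult("kruskal-wallis", float(h), float(p), posthoc,
                      meta={"alpha": alpha, "posthoc": "dunn",
                            "adjustment": adjust})


def mann_whitney(a, b) -> TestResult:
    """Two-sided Mann-Whitney U (exact for small untied samples)."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    u, p = sps.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return TestResult("mann-whitney", float(u), float(min(p, 1.0)))


def ks_two_sample(a, b) -> TestResult:
    """Two-sample Kolmogorov-Smirnov: D = sup |ECDF_a - ECDF_b|, asymptotic p."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    d, p = sps.ks_2samp(a, b, method="asymp")
    return TestResult("kolmogorov-smirnov", float(d), float(p))


def anova_tukey(groups: dict[str, list | np.ndarray],
                alpha: float = 0.05) -> TestResult:
    """One-way ANOVA F with Tukey HSD pairwise post-hoc when p < alpha."""
    groups = _check_groups(groups, min_n=2)
    arrays = list(groups.values())
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        raise ValueError("degenerate input: all values identical across groups")
    f, p = sps.f_oneway(*arrays)
    posthoc = None
    if p < alpha:
        names = list(groups)
        res = sps.tukey_hsd(*arrays)
        posthoc = []
        for i, j in itertools.combinations(range(len(names)), 2):
            posthoc.append(((names[i], names[j]), float(res.pvalue[i, j])))
    return TestResult("one-way-anova", float(f), float(p), posthoc,
                      meta={"alpha": alpha, "posthoc": "tukey-hsd"})


def normality_gate(groups: dict[str, list | np.ndarray],
                   alpha: float = 0.05, min_n: int = 8) -> str:
    """Choose 'parametric' or 'nonparametric' by D'Agostino-Pearson.

    Groups smaller than ``min_n`` cannot support the omnibus normality test,
    so their presence forces the nonparametric branch by policy.
    """
    groups = _check_groups(groups, min_groups=1)
    for vals in groups.values():
        if vals.size < min_n:
            return "nonparametric"
    for vals in groups.values():
        _, p = sps.normaltest(vals)
        if p < alpha:
            return "nonparametric"
    return "parametric"


def auto_group_test(groups: dict[str, list | np.ndarray],
                    alpha: float = 0.05) -> TestResult:
    """Normality-gated omnibus test: ANOVA+Tukey or Kruskal-Wallis+Dunn."""
    branch = normality_gate(groups, alpha)
    if branch == "parametric":
        result = anova_tukey(groups, alpha)
    else:
        result = kruskal_wallis_dunn(groups, alpha)
    result.meta["normality_gate"] = branch
    return result


def ddct_fold_change(ct_table: pd.DataFrame, reference_gene: str,
                     reference_condition: str) -> pd.DataFrame:
    """Relative expression 2^-ddCt per (gene, condition).

    dCt(target, condition, replicate) = Ct - mean Ct(reference gene,
    condition); ddCt(gene, condition) = mean dCt(condition) - mean
    dCt(reference condition); fold = 2^-ddCt, so the reference condition maps
    to 1 by construction and higher expression gives fold > 1.

    Expects a tidy table with columns gene, condition, replicate, ct.
    Returns a frame with columns gene, condition, ddct, fold_change.
    """
    required = {"gene", "condition", "ct"}
    if not required.issubset(ct_table.columns):
        raise ValueError(f"ct table must have columns {sorted(required)}")
    targets = ct_table[ct_table.gene != reference_gene]
    house = ct_table[ct_table.gene == reference_gene]
    if house.empty:
        raise ValueError(f"reference gene '{reference_gene}' absent from table")
    house_mean = house.groupby("condition")["ct"].mean()
    missing = set(targets.condition) - set(house_mean.index)
    if missing:
        raise ValueError(
            "reference gene missing for condition(s): " + ", ".join(sorted(missing))
        )
    dct = targets.assign(
        dct=targets.ct - targets.condition.map(house_mean)
    )
    mean_dct = dct.groupby(["gene", "condition"])["dct"].mean()
    rows = []
    for gene in mean_dct.index.get_level_values(0).unique():
        per_gene = mean_dct.loc[gene]
        if reference_condition not in per_gene.index:
            raise ValueError(
                f"reference condition '{reference_condition}' absent for "
                f"gene '{gene}'"
            )
        base = per_gene[reference_condition]
        for cond, val in per_gene.items():
            ddct = val - base
            rows.append((gene, cond, ddct, 2.0 ** (-ddct)))
    return pd.DataFrame(rows, columns=["gene", "condition", "ddct",
                                       "fold_change"])
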