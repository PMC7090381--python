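"""Normality-gated group comparisons with the animal as unit of inference.

Decision tree (all tests two-tailed, alpha = 0.05):

* data are assumed normal unless the D'Agostino-Pearson omnibus test
  rejects at alpha; the omnibus test is only attempted for groups with
  n >= 8 (its validity floor), so small groups default to normal;
* two paired groups           -> paired t test;
* two independent groups      -> unpaired t (pooled variance) if all
  groups pass the gate, else Mann-Whitney U (exact enumeration when
  both n <= 8 and there are no ties, tie-corrected normal approximation
  otherwise);
* >= 3 groups vs one control  -> one-way ANOVA with Dunnett's multiple
  comparisons if normal, else Kruskal-Wallis with Dunn's rank contrasts
  vs control (Bonferroni over the k-1 contrasts by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "Contrast",
    "GroupComparisonResult",
    "normality_gate",
    "compare_two_paired",
    "compare_two_independent",
    "compare_vs_control",
    "dunn_vs_control",
    "dunnett_max_t_pvalue",
]

ALPHA = 0.05
NORMALITY_MIN_N = 8


@dataclass
class Contrast:
    """One group-vs-control (or A-vs-B) comparison."""

    name: str
    statistic: float
    p_unadjusted: Optional[float]
    p_adjusted: float

    @property
    def significant(self) -> bool:
        return self.p_adjusted < ALPHA


@dataclass
class GroupComparisonResult:
    metric: str
    design: str  # two-group-paired | two-group-independent | multi-group-vs-control
    normality: dict  # group -> True (normal) / False
    test_used: str
    statistic: float
    pvalue: float
    comparisons: list[Contrast] = field(default_factory=list)
    alpha: float = ALPHA
    two_tailed: bool = True

    @property
    def any_significant_contrast(self) -> bool:
        return any(c.p_adjusted < self.alpha for c in self.comparisons)


def _clean(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return x[np.isfinite(x)]


def normality_gate(
    samples: dict[str, Sequence[float]],
    alpha: float = ALPHA,
    min_n: int = NORMALITY_MIN_N,
) -> tuple[bool, dict[str, bool]]:
    """Per-group normality verdicts and the overall verdict.

    Returns (all_normal, {group: is_normal}). A group is flagged
    non-normal only when it has at least ``min_n`` values AND the
    omnibus test rejects at ``alpha``; otherwise normality is assumed.
    """
    verdicts: dict[str, bool] = {}
    for name, values in samples.items():
        v = _clean(values)
        if v.size < 2:
            raise ValueError(f"group {name!r}: need >= 2 values, got {v.size}")
        if v.size < min_n:
            verdicts[name] = True
            continue
        stat, p = stats.normaltest(v)
        verdicts[name] = bool(p >= alpha)
    return all(verdicts.values()), verdicts


def compare_two_paired(
    a: Sequence[float],
    b: Sequence[float],
    *,
    metric: str = "",
    labels: tuple[str, str] = ("A", "B"),
) -> GroupComparisonResult:
    """Two-tailed paired t test (within-animal contrasts)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if a.size < 2:
        raise ValueError("paired t test needs n >= 2 pairs")
    d = a - b
    if np.var(d, ddof=1) == 0:
        raise ValueError(
            "paired differences have zero variance; the paired t "
            "statistic is undefined"
        )
    t, p = stats.ttest_rel(a, b)
    return GroupComparisonResult(
        metric=metric,
        design="two-group-paired",
        normality={labels[0]: True, labels[1]: True},
        test_used="paired t",
        statistic=float(t),
        pvalue=float(p),
        comparisons=[
            Contrast(
                name=f"{labels[0]} vs {labels[1]}",
                statistic=float(t),
                p_unadjusted=float(p),
                p_adjusted=float(p),
            )
        ],
    )


def _mannwhitney(a: np.ndarray, b: np.ndarray) -> tuple[float, float, str]:
    # exact enumeration for small samples (no tie correction there),
    # tie-corrected normal approximation otherwise
    method = "exact" if (a.size <= 8 and b.size <= 8) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue), method


def compare_two_independent(
    a: Sequence[float],
    b: Sequence[float],
    *,
    metric: str = "",
    labels: tuple[str, str] = ("A", "B"),
    force: Optional[str] = None,  # None | "parametric" | "nonparametric"
    welch: bool = False,
    alpha: float = ALPHA,
) -> GroupComparisonResult:
    """Unpaired t or Mann-Whitney U, chosen by the normality gate."""
    a, b = _clean(a), _clean(b)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 values")
    _, verdicts = normality_gate({labels[0]: a, labels[1]: b}, alpha=alpha)
    use_parametric = all(verdicts.values()) if force is None else force == "parametric"
    if use_parametric:
        t, p = stats.ttest_ind(a, b, equal_var=not welch)
        test = "unpaired t (Welch)" if welch else "unpaired t"
        stat = float(t)
    else:
        stat, p, method = _mannwhitney(a, b)
        test = f"Mann-Whitney U ({method})"
    return GroupComparisonResult(
        metric=metric,
        design="two-group-independent",
        normality=verdicts,
        test_used=test,
        statistic=stat,
        pvalue=float(p),
        comparisons=[
            Contrast(
                name=f"{labels[0]} vs {labels[1]}",
                statistic=stat,
                p_unadjusted=float(p),
                p_adjusted=float(p),
            )
        ],
    )


def dunn_vs_control(
    groups: dict[str, np.ndarray],
    control: str,
    adjustment: str = "bonferroni",
) -> list[Contrast]:
    """Dunn's rank-based z contrasts of each group against the control.

    Uses the pooled mid-ranks of the full dataset with tie correction:

        z = (Rbar_i - Rbar_0) / sqrt((N(N+1)/12 - T) * (1/n_i + 1/n_0))
        T = sum(t^3 - t) / (12 (N - 1))   over tie groups of size t

    ``adjustment`` is "bonferroni" (over the k-1 control contrasts) or
    "none".
    """
    if adjustment not in ("bonferroni", "none"):
        raise ValueError("adjustment must be 'bonferroni' or 'none'")
    names = list(groups)
    pooled = np.concatenate([groups[g] for g in names])
    ranks = stats.rankdata(pooled)
    N = pooled.size
    _, tie_counts = np.unique(pooled, return_counts=True)
    T = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (N - 1))
    mean_ranks: dict[str, float] = {}
    i = 0
    for g in names:
        n = groups[g].size
        mean_ranks[g] = float(ranks[i : i + n].mean())
        i += n
    k_minus_1 = len(names) - 1
    out = []
    n0 = groups[control].size
    for g in names:
        if g == control:
            continue
        se = np.sqrt((N * (N + 1) / 12.0 - T) * (1.0 / groups[g].size + 1.0 / n0))
        z = (mean_ranks[g] - mean_ranks[control]) / se
        p = 2.0 * stats.norm.sf(abs(z))
        p_adj = min(1.0, p * k_minus_1) if adjustment == "bonferroni" else p
        out.append(
            Contrast(
                name=f"{g} vs {control}",
                statistic=float(z),
                p_unadjusted=float(p),
                p_adjusted=float(p_adj),
            )
        )
    return out


def compare_vs_control(
    groups: dict[str, Sequence[float]],
    control: str,
    *,
    metric: str = "",
    force: Optional[str] = None,  # None | "parametric" | "nonparametric"
    dunn_adjustment: str = "bonferroni",
    alpha: float = ALPHA,
    rng: Optional[np.random.Generator] = None,
) -> GroupComparisonResult:
    """Multi-group comparison against one designated control.

    Normal data: one-way ANOVA omnibus, then two-sided Dunnett
    comparisons of each group against the control at familywise alpha.
    Non-normal data: Kruskal-Wallis omnibus, then Dunn's z contrasts vs
    control. Post-hoc contrasts are reported unconditionally (not gated
    on the omnibus p), matching common practice in the field's software.
    """
    if control not in groups:
        raise KeyError(f"control group {control!r} not among groups {list(groups)}")
    if len(groups) < 3:
        raise ValueError(
            "compare_vs_control needs >= 3 groups; use the two-group functions"
        )
    clean = {g: _clean(v) for g, v in groups.items()}
    for g, v in clean.items():
        if v.size < 2:
            raise ValueError(f"group {g!r}: need >= 2 values")
    _, verdicts = normality_gate(clean, alpha=alpha)
    use_parametric = all(verdicts.values()) if force is None else force == "parametric"
    treatment_names = [g for g in clean if g != control]
    if use_parametric:
        F, p = stats.f_oneway(*clean.values())
        res = stats.dunnett(
            *[clean[g] for g in treatment_names],
            control=clean[control],
            alternative="two-sided",
            rng=rng if rng is not None else np.random.default_rng(0),
        )
        df = sum(v.size for v in clean.values()) - len(clean)
        comparisons = [
            Contrast(
                name=f"{g} vs {control}",
                statistic=float(res.statistic[i]),
                p_unadjusted=float(2.0 * stats.t.sf(abs(res.statistic[i]), df)),
                p_adjusted=float(res.pvalue[i]),
            )
            for i, g in enumerate(treatment_names)
        ]
        test = "one-way ANOVA + Dunnett"
        stat, pval = float(F), float(p)
    else:
        H, p = stats.kruskal(*clean.values())
        comparisons = dunn_vs_control(clean, control, adjustment=dunn_adjustment)
        test = f"Kruskal-Wallis + Dunn ({dunn_adjustment})"
        stat, pval = float(H), float(p)
    return GroupComparisonResult(
        metric=metric,
        design="multi-group-vs-control",
        normality=verdicts,
        test_used=test,
        statistic=stat,
        pvalue=pval,
        comparisons=comparisons,
        alpha=alpha,
    )


def dunnett_max_t_pvalue(
    t_obs: float,
    n_per_group: Sequence[int],
    *,
    n_draws: int = 100_000,
    rng: Optional[np.random.Generator] = None,
) -> float:
    """Monte-Carlo adjusted p for a two-sided Dunnett contrast.

    Simulates the null distribution of max_i |t_i| over the k-1
    control contrasts (all groups drawn from one normal population,
    pooled-variance t statistics) and returns P(max |t| >= |t_obs|).
    Serves as an independent check of the multivariate-t computation.
    ``n_per_group[0]`` is the control group size.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    sizes = list(n_per_group)
    k = len(sizes)
    N = sum(sizes)
    df = N - k
    maxima = np.empty(n_draws)
    # vectorized over draws: one normal matrix per group
    data = [rng.standard_normal((n_draws, n)) for n in sizes]
    means = np.stack([d.mean(axis=1) for d in data], axis=1)
    ss = np.stack([((d - d.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) for d in data], axis=1)
    sp2 = ss.sum(axis=1) / df
    t_stats = np.empty((n_draws, k - 1))
    for i in range(1, k):
        se = np.sqrt(sp2 * (1.0 / sizes[i] + 1.0 / sizes[0]))
        t_stats[:, i - 1] = (means[:, i] - means[:, 0]) / se
    maxima = np.abs(t_stats).max(axis=1)
    return float(np.mean(maxima >= abs(t_obs)))
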