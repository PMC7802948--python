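"""The study's statistical battery.

One-way ANOVA with Bonferroni-corrected pairwise comparisons, the classical
pooled-variance unpaired t-test, a Fisher variance-ratio check of
inter-operator agreement, and Pearson correlation with its OLS line and R².
All tests are two-sided; Welch correction is available by flag but off by
default (group variances in these designs are treated as comparable).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

ALPHA_DEFAULT = 0.05


@dataclass(frozen=True)
class PairwiseComparison:
    pair: tuple[str, str]
    t: float
    p_raw: float
    p_adjusted: float
    significant: bool


@dataclass(frozen=True)
class GroupComparison:
    """One-way ANOVA result plus Bonferroni-protected pairwise tests."""

    labels: tuple[str, ...]
    sizes: tuple[int, ...]
    F: float
    df_between: int
    df_within: int
    p_anova: float
    pairwise: tuple[PairwiseComparison, ...]
    alpha: float = ALPHA_DEFAULT

    def summary(self) -> str:
        lines = [
            f"One-way ANOVA: F({self.df_between}, {self.df_within}) = "
            f"{self.F:.4g}, p = {self.p_anova:.3g}",
            f"groups: " + ", ".join(
                f"{lab} (n={n})" for lab, n in zip(self.labels, self.sizes)
            ),
        ]
        if self.pairwise:
            lines.append("pairwise (Bonferroni-adjusted):")
            for c in self.pairwise:
                star = " *" if c.significant else ""
                lines.append(
                    f"  {c.pair[0]} vs {c.pair[1]}: t = {c.t:.3f}, "
                    f"p_adj = {c.p_adjusted:.3g}{star}"
                )
        return "\n".join(lines)


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson r with the OLS line of y on x; r_squared = r²."""

    r: float
    r_squared: float
    slope: float
    intercept: float
    n: int

    def summary(self) -> str:
        return (
            f"Pearson r = {self.r:.4f}, R² = {self.r_squared:.4f}; "
            f"y = {self.slope:.4g}·x + {self.intercept:.4g} (n = {self.n})"
        )


@dataclass(frozen=True)
class AgreementResult:
    """Inter-operator agreement: variance-ratio F test then unpaired t."""

    F: float
    p_f: float
    t: float
    p_t: float
    agreement: bool
    alpha: float = ALPHA_DEFAULT


def _as_groups(groups: Sequence[Sequence[float]]) -> list[np.ndarray]:
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) < 2 for g in gs):
        raise ValueError("each group needs n >= 2")
    return gs


def one_way_anova(
    groups: Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
    alpha: float = ALPHA_DEFAULT,
) -> GroupComparison:
    """Classical between/within mean-square F with (k−1, N−k) df.

    The degenerate all-groups-identical case (zero between and within
    variance) is reported as F = 0, p = 1.
    """
    gs = _as_groups(groups)
    labels = tuple(labels) if labels is not None else tuple(
        f"group{i+1}" for i in range(len(gs))
    )
    k = len(gs)
    n_total = sum(len(g) for g in gs)
    grand = np.concatenate(gs).mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in gs)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in gs)
    df_b, df_w = k - 1, n_total - k
    ms_between = ss_between / df_b
    ms_within = ss_within / df_w
    if ms_within == 0:
        if ms_between == 0:
            f_stat, p = 0.0, 1.0
        else:
            f_stat, p = float("inf"), 0.0
    else:
        f_stat = ms_between / ms_within
        p = float(sps.f.sf(f_stat, df_b, df_w))
    return GroupComparison(
        labels=labels,
        sizes=tuple(len(g) for g in gs),
        F=float(f_stat),
        df_between=df_b,
        df_within=df_w,
        p_anova=p,
        pairwise=(),
        alpha=alpha,
    )


def bonferroni_pairwise(
    groups: Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
    alpha: float = ALPHA_DEFAULT,
    variance: str = "pooled_anova",
) -> GroupComparison:
    """All k(k−1)/2 pairwise t-tests with Bonferroni-adjusted p values.

    ``variance='pooled_anova'`` (default) uses the within-group mean square
    of the full ANOVA with N−k df for every pair — the classical
    Bonferroni-protected comparison; ``'per_pair'`` pools only the two
    groups compared.  Adjusted p = min(1, raw p × number of comparisons).
    """
    gs = _as_groups(groups)
    base = one_way_anova(gs, labels=labels, alpha=alpha)
    m = len(gs) * (len(gs) - 1) // 2
    ms_within = (
        sum(((g - g.mean()) ** 2).sum() for g in gs) / base.df_within
    )
    comparisons = []
    for i, j in itertools.combinations(range(len(gs)), 2):
        a, b = gs[i], gs[j]
        if variance == "pooled_anova":
            se = np.sqrt(ms_within * (1 / len(a) + 1 / len(b)))
            df = base.df_within
        elif variance == "per_pair":
            sp2 = (
                ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
            ) / (len(a) + len(b) - 2)
            se = np.sqrt(sp2 * (1 / len(a) + 1 / len(b)))
            df = len(a) + len(b) - 2
        else:
            raise ValueError(f"unknown variance mode {variance!r}")
        diff = a.mean() - b.mean()
        if se == 0:
            t = 0.0 if diff == 0 else float(np.sign(diff)) * float("inf")
            p_raw = 1.0 if diff == 0 else 0.0
        else:
            t = diff / se
            p_raw = float(2 * sps.t.sf(abs(t), df))
        p_adj = min(1.0, p_raw * m)
        comparisons.append(
            PairwiseComparison(
                pair=(base.labels[i], base.labels[j]),
                t=float(t),
                p_raw=p_raw,
                p_adjusted=p_adj,
                significant=p_adj < alpha,
            )
        )
    from dataclasses import replace
    return replace(base, pairwise=tuple(comparisons))


def unpaired_t(
    a: Sequence[float], b: Sequence[float], welch: bool = False
) -> tuple[float, float]:
    """Two-sided unpaired Student's t (pooled variance unless ``welch``)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    res = sps.ttest_ind(a, b, equal_var=not welch)
    return float(res.statistic), float(res.pvalue)


def fisher_f_agreement(
    operator_a: Sequence[float],
    operator_b: Sequence[float],
    alpha: float = ALPHA_DEFAULT,
) -> AgreementResult:
    """Inter-operator agreement check.

    Fisher's F = larger sample variance / smaller sample variance with a
    two-sided p, followed by an unpaired t-test on the means; the operators
    agree when neither test is significant at ``alpha``.
    """
    a = np.asarray(operator_a, dtype=float)
    b = np.asarray(operator_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each operator needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va >= vb:
        num, den, dfn, dfd = va, vb, len(a) - 1, len(b) - 1
    else:
        num, den, dfn, dfd = vb, va, len(b) - 1, len(a) - 1
    if den == 0:
        f_stat = 1.0 if num == 0 else float("inf")
        p_f = 1.0 if num == 0 else 0.0
    else:
        f_stat = float(num / den)
        p_f = float(min(1.0, 2 * sps.f.sf(f_stat, dfn, dfd)))
    if va == 0 and vb == 0:
        t = 0.0 if a.mean() == b.mean() else float("inf")
        p_t = 1.0 if a.mean() == b.mean() else 0.0
    else:
        t, p_t = unpaired_t(a, b)
    return AgreementResult(
        F=f_stat, p_f=p_f, t=t, p_t=p_t,
        agreement=(p_f > alpha and p_t > alpha), alpha=alpha,
    )


def pearson_fit(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson correlation with the OLS regression line of y on x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired samples with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in x or y; correlation undefined")
    fit = sps.linregress(x, y)
    return CorrelationResult(
        r=float(fit.rvalue),
        r_squared=float(fit.rvalue**2),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        n=len(x),
    )
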