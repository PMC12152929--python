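"""Per-condition comparison statistics for droplet counts and volumes.

One-way fixed-effects ANOVA across condition groups, followed by all
pairwise two-sample comparisons using the pooled within-group variance
(the classical "means comparison" of spreadsheet statistics packages)
with Bonferroni adjustment over the number of pairs.  A Welch variant
of the pairwise tests is available for unequal variances.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

from scipy import stats as _sps

__all__ = [
    "ConditionGroup",
    "PairwiseComparison",
    "ComparisonReport",
    "DegenerateVarianceError",
    "anova_bonferroni",
    "disassembly_contrast",
    "significance_stars",
]


class DegenerateVarianceError(ValueError):
    """All groups identical with zero within-group variance: no test possible."""


@dataclass
class ConditionGroup:
    """Per-image values (count or mean volume) for one condition.

    Images with an undefined value (e.g. mean volume of an image with
    zero particles) should be excluded before construction; ``n`` is the
    number of retained images (the design default is 30 images per
    condition).
    """

    name: str
    values: list[float]

    @property
    def n(self) -> int:
        return len(self.values)

    def mean(self) -> float:
        return sum(self.values) / self.n


@dataclass
class PairwiseComparison:
    group_a: str
    group_b: str
    mean_diff: float
    t_statistic: float
    raw_p: float
    adjusted_p: float
    stars: str


@dataclass
class ComparisonReport:
    """One-way ANOVA result plus Bonferroni-adjusted pairwise comparisons."""

    f_statistic: float
    overall_p: float
    df_between: int
    df_within: int
    pairwise: list[PairwiseComparison] = field(default_factory=list)


def significance_stars(p: float) -> str:
    """Flag convention: *** p<0.001, ** p<0.01, * p<0.05, ns otherwise."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def anova_bonferroni(
    groups: list[ConditionGroup], welch: bool = False
) -> ComparisonReport:
    """One-way ANOVA with Bonferroni-adjusted pairwise means comparisons.

    The F statistic is computed from between/within sums of squares; the
    pairwise tests reuse the pooled within-group variance (mean square
    within) with its full degrees of freedom, and each raw two-sided p
    is multiplied by the number of pairs, capped at 1.  With
    ``welch=True`` the pairwise tests instead use Welch's unequal-
    variance t with Satterthwaite degrees of freedom (the overall F is
    unchanged).

    Raises
    ------
    DegenerateVarianceError
        If every observation in every group is identical (zero within-
        and between-group variance).
    ValueError
        Fewer than 2 groups, or a group with fewer than 2 values.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.n < 2 for g in groups):
        raise ValueError("every group needs at least 2 values")

    k = len(groups)
    n_total = sum(g.n for g in groups)
    means = {id(g): g.mean() for g in groups}
    grand_mean = sum(sum(g.values) for g in groups) / n_total
    ss_between = sum(g.n * (means[id(g)] - grand_mean) ** 2 for g in groups)
    ss_within = sum(
        sum((v - means[id(g)]) ** 2 for v in g.values) for g in groups
    )
    df_between = k - 1
    df_within = n_total - k
    ms_within = ss_within / df_within
    if ms_within == 0.0:
        if ss_between == 0.0:
            raise DegenerateVarianceError(
                "all groups identical with zero variance; F is undefined"
            )
        f_stat, overall_p = math.inf, 0.0
    else:
        f_stat = (ss_between / df_between) / ms_within
        overall_p = float(_sps.f.sf(f_stat, df_between, df_within))

    n_pairs = k * (k - 1) // 2
    pairwise = []
    for ga, gb in itertools.combinations(groups, 2):
        diff = means[id(gb)] - means[id(ga)]
        if welch:
            t, p, _ = _welch_t(ga, gb)
        else:
            se = math.sqrt(ms_within * (1.0 / ga.n + 1.0 / gb.n))
            if se == 0.0:
                t = math.inf if diff != 0 else 0.0
                p = 0.0 if diff != 0 else 1.0
            else:
                t = diff / se
                p = 2.0 * float(_sps.t.sf(abs(t), df_within))
        adj = min(1.0, n_pairs * p)
        pairwise.append(
            PairwiseComparison(ga.name, gb.name, diff, t, p, adj, significance_stars(adj))
        )
    return ComparisonReport(f_stat, overall_p, df_between, df_within, pairwise)


def _welch_t(ga: ConditionGroup, gb: ConditionGroup) -> tuple[float, float, float]:
    ma, mb = ga.mean(), gb.mean()
    va = sum((v - ma) ** 2 for v in ga.values) / (ga.n - 1)
    vb = sum((v - mb) ** 2 for v in gb.values) / (gb.n - 1)
    se2 = va / ga.n + vb / gb.n
    diff = mb - ma
    if se2 == 0.0:
        return (math.inf if diff != 0 else 0.0, 0.0 if diff != 0 else 1.0, 1.0)
    t = diff / math.sqrt(se2)
    df = se2**2 / (
        (va / ga.n) ** 2 / (ga.n - 1) + (vb / gb.n) ** 2 / (gb.n - 1)
    )
    return t, 2.0 * float(_sps.t.sf(abs(t), df)), df


@dataclass
class DisassemblyReport:
    """Before/after contrast of counts and volumes with a direction summary."""

    counts: ComparisonReport
    volumes: ComparisonReport
    counts_decreased: bool
    counts_significant: bool
    volumes_increased: bool
    volumes_significant: bool

    def summary(self) -> str:
        c = "decreased" if self.counts_decreased else "did not decrease"
        v = "increased" if self.volumes_increased else "did not increase"
        return (
            f"particle count {c} "
            f"({self.counts.pairwise[0].stars}, adj p={self.counts.pairwise[0].adjusted_p:.3g}); "
            f"mean particle volume {v} "
            f"({self.volumes.pairwise[0].stars}, adj p={self.volumes.pairwise[0].adjusted_p:.3g})"
        )


def disassembly_contrast(
    counts_before: ConditionGroup,
    counts_after: ConditionGroup,
    volumes_before: ConditionGroup,
    volumes_after: ConditionGroup,
    alpha: float = 0.05,
) -> DisassemblyReport:
    """Test whether a treatment dissolved condensates.

    Compares per-image particle counts and per-image mean volumes before
    and after treatment (e.g. added NaCl or 1,6-hexanediol).  Reports
    both contrasts with Bonferroni-adjusted significance and a direction
    summary: condensate disassembly that preferentially dissolves small
    droplets shows up as a significant count decrease together with an
    *increase* of the surviving mean volume.
    """
    rep_c = anova_bonferroni([counts_before, counts_after])
    rep_v = anova_bonferroni([volumes_before, volumes_after])
    # Bonferroni over the two family members (counts + volumes)
    for rep in (rep_c, rep_v):
        pc = rep.pairwise[0]
        pc.adjusted_p = min(1.0, 2.0 * pc.raw_p)
        pc.stars = significance_stars(pc.adjusted_p)
    dc = counts_after.mean() - counts_before.mean()
    dv = volumes_after.mean() - volumes_before.mean()
    return DisassemblyReport(
        counts=rep_c,
        volumes=rep_v,
        counts_decreased=dc < 0,
        counts_significant=rep_c.pairwise[0].adjusted_p < alpha,
        volumes_increased=dv > 0,
        volumes_significant=rep_v.pairwise[0].adjusted_p < alpha,
    )
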