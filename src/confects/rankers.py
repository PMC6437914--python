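"""Competing gene-ranking strategies for benchmarking.

Seven total orderings of genes are compared in the simulation harness:

1. ``pvalue``        — ascending two-sided moderated-t p-value.
2. ``confect``       — the confect ordering at 5% FDR; genes without a
                       confect fall back to p-value order.
3. ``ci_inner``      — descending inner end of a per-gene 95% CI; genes
                       whose interval spans zero fall back to p-value order.
4. ``fwer_ci_inner`` — as 3 but with Bonferroni-corrected CIs holding the
                       family-wise error rate at 5%.
5. ``treat_p_1``     — ascending TREAT p-value at LFC threshold 1.0.
6. ``treat_p_5``     — ascending TREAT p-value at LFC threshold 5.0.
7. ``abs_lfc``       — descending |estimated LFC|; the ideal ranking only
                       under homoscedastic noise.

Ties are broken deterministically (documented per ranker) so every
ordering is a reproducible strict total order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .model import ConfectModel
from .moderation import GeneStats
from .treat import treat_pvalue

__all__ = [
    "RankerOutput",
    "rank_by_pvalue",
    "rank_by_confect",
    "rank_by_ci_inner",
    "rank_by_treat_p",
    "rank_by_abs_lfc",
    "RANKERS",
]


@dataclass
class RankerOutput:
    """A total ordering of genes produced by one ranking strategy.

    order : permutation of gene indices, best first
    bound : per-gene signed effect bound where the method provides one
        (NaN = none), else None
    fallback_mask : per-gene flag for genes ranked only by the fallback
        (p-value) rule, else None
    """

    method_id: str
    order: np.ndarray
    bound: np.ndarray | None = None
    fallback_mask: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        n = len(self.order)
        if not np.array_equal(np.sort(self.order), np.arange(n)):
            raise ValueError("order must be a permutation of gene indices")


def _gid(stats: GeneStats) -> np.ndarray:
    return np.asarray([str(g) for g in stats.gene_id], dtype=object)


def rank_by_pvalue(stats: GeneStats) -> RankerOutput:
    """Ascending p(0); ties by |effect| descending, then gene id."""
    p0 = treat_pvalue(stats.effect, stats.se, stats.df, 0.0)
    order = np.lexsort((_gid(stats), -np.abs(stats.effect), np.atleast_1d(p0)))
    return RankerOutput("pvalue", order)


def rank_by_confect(stats: GeneStats, q: float = 0.05, step: float = 0.01,
                    max_e: float = 30.0) -> RankerOutput:
    """The confect total order; fallback_mask marks genes with no confect."""
    res = ConfectModel(stats).fit(fdr=q, step=step, max_e=max_e)
    fallback = np.isnan(res.confect)
    return RankerOutput(
        "confect", res.order, bound=res.bounds(), fallback_mask=fallback,
        meta={"n_with_confect": res.n_with_confect},
    )


def rank_by_ci_inner(stats: GeneStats, level: float = 0.95,
                     bonferroni: bool = False) -> RankerOutput:
    """Descending inner end of a two-sided CI; spans-zero genes fall back.

    The plain variant uses a per-gene CI at ``level``; the Bonferroni
    variant widens to per-gene level 1 - (1 - level)/n_gene so the family
    of intervals holds a FWER of 1 - level.  The inner end of an interval
    excluding zero is sign(x) * (|x| - halfwidth); genes whose interval
    touches or spans zero are ranked after all others, by p(0).
    """
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0, 1), got {level}")
    n = len(stats)
    lv = 1.0 - (1.0 - level) / n if bonferroni else level
    halfwidth = sps.t.ppf((1.0 + lv) / 2.0, stats.df) * stats.se
    inner = np.abs(stats.effect) - halfwidth
    excludes = inner > 0
    bound = np.where(excludes, np.sign(stats.effect) * inner, np.nan)
    p0 = np.atleast_1d(treat_pvalue(stats.effect, stats.se, stats.df, 0.0))
    gid = _gid(stats)
    idx_b = np.flatnonzero(excludes)
    order_b = idx_b[np.lexsort((gid[idx_b], p0[idx_b], -inner[idx_b]))]
    idx_f = np.flatnonzero(~excludes)
    order_f = idx_f[np.lexsort((gid[idx_f], p0[idx_f]))]
    method = "fwer_ci_inner" if bonferroni else "ci_inner"
    return RankerOutput(method, np.concatenate([order_b, order_f]),
                        bound=bound, fallback_mask=~excludes)


def rank_by_treat_p(stats: GeneStats, e: float) -> RankerOutput:
    """Ascending TREAT p at threshold e; ties by |effect| descending."""
    if e < 0:
        raise ValueError("threshold e must be non-negative")
    p = np.atleast_1d(treat_pvalue(stats.effect, stats.se, stats.df, e))
    order = np.lexsort((_gid(stats), -np.abs(stats.effect), p))
    mid = {1.0: "treat_p_1", 5.0: "treat_p_5"}.get(e, f"treat_p_{e:g}")
    return RankerOutput(mid, order)


def rank_by_abs_lfc(stats: GeneStats) -> RankerOutput:
    """Descending |effect|; ties by se ascending, then gene id."""
    order = np.lexsort((_gid(stats), stats.se, -np.abs(stats.effect)))
    return RankerOutput("abs_lfc", order)


#: Registry of all seven strategies, keyed by method id.
RANKERS = {
    "pvalue": rank_by_pvalue,
    "confect": rank_by_confect,
    "ci_inner": lambda stats: rank_by_ci_inner(stats, 0.95, bonferroni=False),
    "fwer_ci_inner": lambda stats: rank_by_ci_inner(stats, 0.95, bonferroni=True),
    "treat_p_1": lambda stats: rank_by_treat_p(stats, 1.0),
    "treat_p_5": lambda stats: rank_by_treat_p(stats, 5.0),
    "abs_lfc": rank_by_abs_lfc,
}
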