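"""Confident-effect-size model and results.

``ConfectModel`` wraps a per-gene statistics table (log2 fold change
estimate, standard error, degrees of freedom) — supplied directly or
computed from a two-group expression matrix — and ``fit()`` runs the
nested-BH scan of the TREAT p-value functions, returning a
``ConfectResults`` with the ranked table, the signed confect values, and
the false-coverage self-check.

The confect of a gene is the largest effect-size threshold e at which the
gene remains in the FDR-controlled selected set S(e); it acts as a lower
confidence bound on |LFC| whose confidence level adapts to the number of
genes selected, so that the false coverage-statement rate of the reported
bounds is controlled at the same level q as the FDR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ConfectParams, ScanOutcome, confect_scan
from .moderation import ExpressionMatrix, GeneStats, make_gene_stats
from .treat import treat_pvalue

__all__ = ["ConfectModel", "ConfectResults", "FcrCheck", "compute_confects"]


class ConfectModel:
    """Effect-size ranking model for a set of genes.

    Parameters
    ----------
    stats : GeneStats or DataFrame
        Per-gene estimates with columns/fields gene_id, effect, se, df.
    """

    def __init__(self, stats):
        if isinstance(stats, pd.DataFrame):
            stats = GeneStats.from_frame(stats)
        if not isinstance(stats, GeneStats):
            raise TypeError("stats must be a GeneStats or a DataFrame")
        if len(stats) < 1:
            raise ValueError("at least one gene is required")
        self.stats = stats

    @classmethod
    def from_expression(cls, mat, group=None, *, moderate=True) -> "ConfectModel":
        """Build from a genes x samples log2-expression matrix.

        ``mat`` may be an :class:`ExpressionMatrix`, or a DataFrame indexed
        by gene id with ``group`` giving one of two labels per sample.
        Standard errors use empirical-Bayes moderated variances unless
        ``moderate=False``.
        """
        if not isinstance(mat, ExpressionMatrix):
            mat = ExpressionMatrix.from_frame(mat, group)
        return cls(make_gene_stats(mat, moderate=moderate))

    def pvalues(self, e, idx=None):
        """TREAT p-values at threshold ``e`` for genes ``idx`` (default all)."""
        s = self.stats
        if idx is None:
            idx = slice(None)
        return np.atleast_1d(treat_pvalue(s.effect[idx], s.se[idx], s.df[idx], e))

    def fit(self, fdr=0.05, step=0.01, max_e=30.0) -> "ConfectResults":
        """Scan the effect-size grid and rank genes by confect.

        Ordering: decreasing |confect|; among equal confects, by the
        p-value at the first grid threshold at which the gene left the
        selected set; genes with no confect come last, ordered by their
        plain (e = 0) p-value.  Remaining ties break on gene id, making
        the order a strict total order.
        """
        params = ConfectParams(fdr=fdr, step=step, max_e=max_e)
        scan = confect_scan(self.pvalues, len(self.stats), params)
        return ConfectResults(self, params, scan)


@dataclass
class FcrCheck:
    """Result of the false-coverage self-check.

    For every gene with a confect, p_i(|c_i|) must not exceed
    |S(|c_i|)| / n_gene * q — the Benjamini-Yekutieli condition that makes
    the reported bounds FCR-valid for any selection of the form
    "all genes with |confect| >= e".  ``max_slack`` is the largest value of
    p_i(|c_i|) - |S(|c_i|)| q / n over checked genes (<= 0 when all pass).
    """

    ok: np.ndarray
    max_slack: float
    violations: pd.DataFrame

    def __bool__(self):
        return bool(self.ok.all())


class ConfectResults:
    """Ranked confect table with diagnostics.

    Attributes
    ----------
    table : DataFrame
        Columns rank, gene_id, confect, effect, se, df, p_zero, in rank
        order.  ``confect`` is signed by the effect estimate and NaN for
        genes never selected at any threshold.
    n_with_confect : int
        Number of genes assigned a confect.
    """

    def __init__(self, model: ConfectModel, params: ConfectParams, scan: ScanOutcome):
        self.model = model
        self.params = params
        self.scan = scan
        s = model.stats
        n = len(s)
        mag = scan.confect_mag
        sign = np.sign(s.effect)
        sign[sign == 0] = 0.0  # zero effect keeps an (unsigned) zero confect
        confect = sign * mag

        has = ~np.isnan(mag)
        gid = np.asarray([str(g) for g in s.gene_id], dtype=object)
        # lexsort: last key is primary
        idx_has = np.flatnonzero(has)
        order_has = idx_has[
            np.lexsort((gid[idx_has], scan.drop_p[idx_has], -mag[idx_has]))
        ]
        idx_no = np.flatnonzero(~has)
        order_no = idx_no[np.lexsort((gid[idx_no], scan.p_zero[idx_no]))]
        order = np.concatenate([order_has, order_no])

        self.order = order
        self.confect = confect
        self.n_with_confect = int(has.sum())
        self.table = pd.DataFrame(
            {
                "rank": np.arange(1, n + 1),
                "gene_id": s.gene_id[order],
                "confect": confect[order],
                "effect": s.effect[order],
                "se": s.se[order],
                "df": s.df[order],
                "p_zero": scan.p_zero[order],
            }
        ).reset_index(drop=True)

    # -- selection ---------------------------------------------------------

    def _snap_up(self, e: float) -> float:
        """Round an off-grid threshold up to the next grid point."""
        if e < 0:
            raise ValueError("threshold must be non-negative")
        step = self.params.step
        return np.ceil(e / step - 1e-9) * step

    def selected_set_at(self, e: float) -> np.ndarray:
        """Gene ids with |confect| >= e; equals BH selection S(e) at level q.

        Off-grid thresholds round up to the next grid point (conservative:
        a gene is never claimed to exceed a threshold it was not tested at).
        """
        e = self._snap_up(e)
        mask = np.abs(self.confect) >= e - 1e-9
        mask &= ~np.isnan(self.confect)
        return self.model.stats.gene_id[mask]

    def bounds(self) -> np.ndarray:
        """Signed confect per gene in input order (NaN where none)."""
        return self.confect.copy()

    # -- diagnostics -------------------------------------------------------

    def check_fcr_inequality(self) -> FcrCheck:
        """Verify p_i(|c_i|) <= |S(|c_i|)| / n_gene * q for every confect.

        Holds by construction (each gene entered S(|c_i|) under exactly
        this condition); exposed as a release-gate self-test against
        implementation drift.
        """
        s = self.model.stats
        n = len(s)
        scan = self.scan
        has = ~np.isnan(scan.confect_mag)
        idx = np.flatnonzero(has)
        mag = scan.confect_mag[idx]
        p_at_c = treat_pvalue(s.effect[idx], s.se[idx], s.df[idx], mag)
        p_at_c = np.atleast_1d(p_at_c)
        # |S(e)| for each gene's own confect threshold
        gi = np.rint(mag / self.params.step).astype(int)
        sizes = scan.set_sizes[gi]
        limit = sizes * self.params.fdr / n
        slack = p_at_c - limit
        ok = slack <= 1e-12
        viol = pd.DataFrame(
            {
                "gene_id": s.gene_id[idx][~ok],
                "e": mag[~ok],
                "p": p_at_c[~ok],
                "bound": limit[~ok],
            }
        )
        return FcrCheck(ok=ok, max_slack=float(slack.max()) if slack.size else -np.inf,
                        violations=viol)

    # -- presentation ------------------------------------------------------

    def summary(self, top: int = 10) -> str:
        """Plain-text summary in the style of a regression results table."""
        head = self.table.head(top)
        lines = [
            "Confident effect size ranking",
            "=" * 64,
            f"genes: {len(self.model.stats)}    with confect: "
            f"{self.n_with_confect}    FDR target q: {self.params.fdr}",
            f"grid step: {self.params.step}    scanned up to e = "
            f"{self.scan.grid[-1]:.4g}"
            + ("    [scan truncated at max_e]" if self.scan.truncated else ""),
            "-" * 64,
            f"{'rank':>4} {'gene_id':>12} {'confect':>9} {'effect':>9} "
            f"{'se':>8} {'p(0)':>10}",
        ]
        for _, r in head.iterrows():
            c = "" if np.isnan(r["confect"]) else f"{r['confect']:9.3f}"
            lines.append(
                f"{int(r['rank']):>4} {str(r['gene_id']):>12} {c:>9} "
                f"{r['effect']:9.3f} {r['se']:8.3f} {r['p_zero']:10.3g}"
            )
        lines.append("=" * 64)
        return "\n".join(lines)

    def __repr__(self):
        return (
            f"<ConfectResults: {self.n_with_confect}/{len(self.model.stats)} "
            f"genes with confect at q={self.params.fdr}>"
        )


def compute_confects(stats, fdr=0.05, step=0.01, max_e=30.0) -> ConfectResults:
    """Functional shorthand for ``ConfectModel(stats).fit(...)``."""
    return ConfectModel(stats).fit(fdr=fdr, step=step, max_e=max_e)
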