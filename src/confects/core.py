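"""Nested Benjamini-Hochberg selection over an effect-size grid.

For each threshold e on a grid 0, step, 2*step, ... the largest set

    S(e) = { i : p_i(e) <= |S(e)| / n_gene * q }

is found (equivalently: classical BH step-up selection at level q applied
to the p-values p_i(e), with n_gene the full universe size).  Because
p_i(e) is non-decreasing in e these sets nest, S(e) ⊆ S(e') for e > e',
so the scan only ever re-tests genes still selected.  The confect of gene
i is the largest grid e with i ∈ S(e), signed by the sign of its estimated
effect; genes in no set get none.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["ConfectParams", "ScanOutcome", "bh_largest_set", "confect_scan"]


@dataclass
class ConfectParams:
    """Tuning of the confect computation.

    fdr : target false discovery rate q in (0, 1)
    step : grid spacing in log2-fold-change units
    max_e : safety cap on the scan (log2 units); reaching it with a
        non-empty selection is recorded as a warning, not an error
    """

    fdr: float = 0.05
    step: float = 0.01
    max_e: float = 30.0

    def __post_init__(self):
        if not 0.0 < self.fdr < 1.0:
            raise ValueError(f"fdr must be in (0, 1), got {self.fdr}")
        if self.step <= 0:
            raise ValueError("step must be positive")
        if self.max_e <= 0:
            raise ValueError("max_e must be positive")


def bh_largest_set(pvals, q, n_gene=None):
    """Benjamini-Hochberg step-up selection at level q.

    Returns a boolean mask over ``pvals`` marking the selected genes: sort
    p ascending, find the largest k with p_(k) <= k * q / n_gene, select
    those k.  This is the largest set satisfying the self-referential
    condition S = {i : p_i <= |S| q / n_gene}.  ``n_gene`` defaults to
    ``len(pvals)`` but may be larger when the universe includes genes not
    passed in (here it is the total gene count even while scanning a
    surviving subset).
    """
    p = np.asarray(pvals, dtype=float)
    if p.size and (np.any(p < 0) | np.any(p > 1) | np.any(~np.isfinite(p))):
        raise ValueError("p-values must lie in [0, 1]")
    if n_gene is None:
        n_gene = p.size
    if n_gene < p.size:
        raise ValueError("n_gene must be at least the number of p-values")
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    order = np.argsort(p, kind="stable")
    thresh = (np.arange(1, p.size + 1) * q) / n_gene
    ok = p[order] <= thresh
    mask = np.zeros(p.size, dtype=bool)
    if ok.any():
        k = int(np.flatnonzero(ok)[-1]) + 1
        mask[order[:k]] = True
    return mask


@dataclass
class ScanOutcome:
    """Raw result of the nested-BH grid scan.

    confect_mag : per-gene largest grid e with membership in S(e); nan for
        genes never selected
    drop_p : per-gene p-value at the first grid e where the gene was not
        in S(e) (the tie-break key among equal confects); for genes still
        selected when the scan hit max_e, the p-value at the last grid e
    p_zero : p_i(0) for every gene
    set_sizes : |S(e)| for each scanned grid value, parallel to ``grid``
    truncated : True when max_e stopped the scan with a non-empty set
    """

    confect_mag: np.ndarray
    drop_p: np.ndarray
    p_zero: np.ndarray
    grid: np.ndarray
    set_sizes: np.ndarray
    truncated: bool
    fdr: float
    step: float


def confect_scan(pfunc, n_gene, params: ConfectParams) -> ScanOutcome:
    """Scan e = 0, step, 2*step, ... until S(e) is empty (or max_e).

    Parameters
    ----------
    pfunc : callable
        ``pfunc(e, idx)`` returning the p-values at threshold ``e`` for the
        genes with indices ``idx`` (an int array into the gene universe).
        Must be non-decreasing in ``e`` per gene.
    n_gene : int
        Total number of genes (the BH universe).
    params : ConfectParams
    """
    if n_gene < 1:
        raise ValueError("at least one gene is required")
    all_idx = np.arange(n_gene)
    p_zero = np.asarray(pfunc(0.0, all_idx), dtype=float)
    if p_zero.shape != (n_gene,):
        raise ValueError("pfunc must return one p-value per requested gene")

    confect_mag = np.full(n_gene, np.nan)
    drop_p = np.full(n_gene, np.nan)
    grid_vals: list[float] = []
    set_sizes: list[int] = []

    active = all_idx
    k = 0
    truncated = False
    while active.size:
        e = k * params.step
        if e > params.max_e:
            truncated = True
            warnings.warn(
                f"confect scan reached max_e={params.max_e} with "
                f"{active.size} gene(s) still selected; their confects are "
                "truncated at the cap",
                RuntimeWarning,
            )
            break
        p = p_zero[active] if k == 0 else np.asarray(pfunc(e, active), dtype=float)
        sel = bh_largest_set(p, params.fdr, n_gene)
        grid_vals.append(e)
        set_sizes.append(int(sel.sum()))
        confect_mag[active[sel]] = e
        dropped = active[~sel]
        drop_p[dropped] = p[~sel]
        active = active[sel]
        k += 1
    if truncated:
        # tie-break the capped genes by their p-value at the last grid e
        drop_p[active] = np.asarray(pfunc(grid_vals[-1], active), dtype=float)

    return ScanOutcome(
        confect_mag=confect_mag,
        drop_p=drop_p,
        p_zero=p_zero,
        grid=np.asarray(grid_vals),
        set_sizes=np.asarray(set_sizes, dtype=int),
        truncated=truncated,
        fdr=params.fdr,
        step=params.step,
    )
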