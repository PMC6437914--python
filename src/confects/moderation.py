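"""Per-gene two-group statistics with empirical-Bayes variance moderation.

Takes a genes x samples matrix of log2-scale expression with a binary group
assignment, fits the two-group mean-difference model per gene, and shrinks
the residual variances towards a common prior.  The prior is a scaled
inverse chi-square distribution with degrees of freedom ``d0`` and scale
``v0``; under it the sample variances follow a scaled F law, so ``(d0, v0)``
are estimated by matching the first two moments of the log sample variances
to the theoretical log-F moments (digamma/trigamma relations).  The
posterior (squeezed) variance of gene g is the convex combination

    s2_post_g = (d0 * v0 + df * s2_g) / (d0 + df)

and the moderated degrees of freedom are df + d0.  When the observed spread
of log variances is no larger than expected under a single shared variance,
d0 is reported as infinite and every posterior variance equals v0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import digamma, polygamma

__all__ = [
    "ExpressionMatrix",
    "GeneStats",
    "ModerationFit",
    "fit_group_difference",
    "moderate_variances",
    "make_gene_stats",
]

# t with a million df is numerically normal; stands in for d0 = infinity
MAX_MODERATED_DF = 1e6


@dataclass
class ExpressionMatrix:
    """A genes x samples log2-expression matrix with a two-group design.

    ``group`` holds one label per sample; exactly two distinct labels are
    required and each must cover at least two samples.  Rows containing
    missing values are rejected (never imputed) by :func:`make_gene_stats`.
    """

    values: np.ndarray
    gene_ids: np.ndarray
    group: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.group = np.asarray(self.group)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        n_gene, n_sample = self.values.shape
        if len(self.gene_ids) != n_gene:
            raise ValueError("one gene id per row is required")
        if len(set(map(str, self.gene_ids))) != n_gene:
            raise ValueError("gene ids must be unique")
        if len(self.group) != n_sample:
            raise ValueError("one group label per sample is required")
        labels = pd.unique(self.group)
        if len(labels) != 2:
            raise ValueError(f"exactly two groups required, got {list(labels)}")
        for lab in labels:
            n = int(np.sum(self.group == lab))
            if n < 2:
                raise ValueError(
                    f"group {lab!r} has {n} sample(s); at least 2 are required"
                )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, group) -> "ExpressionMatrix":
        """Build from a DataFrame indexed by gene id, columns = samples."""
        return cls(frame.to_numpy(dtype=float), frame.index.to_numpy(), np.asarray(group))

    @property
    def labels(self):
        # sorted so that "effect = mean(second label) - mean(first label)"
        # does not depend on sample order; relabelling A<->B negates effects
        return np.sort(pd.unique(self.group))


@dataclass
class GeneStats:
    """Per-gene effect estimates feeding the TREAT test.

    effect : estimated log2 fold change x_i
    se     : its standard error s_i (> 0)
    df     : degrees of freedom d, possibly non-integer after moderation
    """

    gene_id: np.ndarray
    effect: np.ndarray
    se: np.ndarray
    df: np.ndarray

    def __post_init__(self):
        self.gene_id = np.asarray(self.gene_id, dtype=object)
        self.effect = np.asarray(self.effect, dtype=float)
        self.se = np.asarray(self.se, dtype=float)
        self.df = np.broadcast_to(np.asarray(self.df, dtype=float), self.effect.shape).copy()
        n = len(self.gene_id)
        if not (len(self.effect) == len(self.se) == len(self.df) == n):
            raise ValueError("gene_id, effect, se and df must have equal length")
        if len(set(map(str, self.gene_id))) != n:
            raise ValueError("gene ids must be unique")
        if not np.all(np.isfinite(self.effect)):
            raise ValueError("effects must be finite")
        if np.any(self.se <= 0) or not np.all(np.isfinite(self.se)):
            raise ValueError("standard errors must be finite and > 0")
        if np.any(self.df <= 0):
            raise ValueError("degrees of freedom must be > 0")

    def __len__(self):
        return len(self.gene_id)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "GeneStats":
        return cls(
            frame["gene_id"].to_numpy(),
            frame["effect"].to_numpy(float),
            frame["se"].to_numpy(float),
            frame["df"].to_numpy(float),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene_id": self.gene_id, "effect": self.effect, "se": self.se, "df": self.df}
        )


@dataclass
class ModerationFit:
    """Estimated variance prior and the squeezed per-gene variances."""

    prior_df: float  # d0; np.inf when no excess spread is observed
    prior_var: float  # v0
    posterior_vars: np.ndarray
    moderated_df: float = field(init=False)

    def __post_init__(self):
        if self.prior_df < 0 or self.prior_var <= 0:
            raise ValueError("prior_df must be >= 0 and prior_var > 0")


def _trigamma_inverse(y: float, *, max_iter: int = 50, rtol: float = 1e-10) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = float(polygamma(1, x))
        step = tri * (1.0 - tri / y) / float(polygamma(2, x))
        x += step
        if abs(step) < rtol * x:
            break
    return x


def fit_group_difference(mat: ExpressionMatrix):
    """Two-group mean-difference fit per gene.

    Returns ``(effect, residual_variance, residual_df)`` where effect is
    mean(group B) - mean(group A) (B = second group label in order of
    appearance), residual_variance is the pooled within-group variance and
    residual_df = n_A + n_B - 2.  The standard error of the effect is
    sqrt(residual_variance * (1/n_A + 1/n_B)).
    """
    lab_a, lab_b = mat.labels
    a = mat.values[:, mat.group == lab_a]
    b = mat.values[:, mat.group == lab_b]
    n_a, n_b = a.shape[1], b.shape[1]
    effect = b.mean(axis=1) - a.mean(axis=1)
    ss = ((a - a.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (b - b.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    residual_df = n_a + n_b - 2
    residual_variance = ss / residual_df
    return effect, residual_variance, residual_df


def moderate_variances(sample_vars, residual_df, *, prior_df=None) -> ModerationFit:
    """Estimate the variance prior and squeeze the sample variances.

    Parameters
    ----------
    sample_vars : array_like
        Per-gene residual variances, all >= 0, not all zero.
    residual_df : float
        Residual degrees of freedom of each sample variance (>= 1).
    prior_df : float, optional
        Fix d0 instead of estimating it.  ``prior_df=0`` disables
        moderation (posterior = sample variances).

    With fewer than 10 positive-variance genes the prior cannot be
    estimated reliably; the fit falls back to no moderation (d0 = 0).
    """
    s2 = np.asarray(sample_vars, dtype=float)
    if np.any(s2 < 0):
        raise ValueError("sample variances must be non-negative")
    if residual_df < 1:
        raise ValueError("residual_df must be >= 1")
    if not np.any(s2 > 0):
        raise ValueError("all sample variances are zero; degenerate input")

    if prior_df is not None and prior_df == 0:
        fit = ModerationFit(0.0, float(np.mean(s2[s2 > 0])), s2.copy())
        fit.moderated_df = float(residual_df)
        return fit

    pos = s2 > 0
    z = np.log(s2[pos])
    df = float(residual_df)
    # log s2_g = log sigma2_g + log(chi2_df/df); centre by the chi-square
    # log-moment so that ebar estimates E[log sigma2]
    ebar_terms = z - digamma(df / 2.0) + np.log(df / 2.0)

    if prior_df is None:
        if pos.sum() < 10:
            warnings.warn(
                "fewer than 10 genes with positive variance; moderation disabled",
                RuntimeWarning,
            )
            fit = ModerationFit(0.0, float(np.mean(s2[pos])), s2.copy())
            fit.moderated_df = df
            return fit
        emean = float(np.mean(ebar_terms))
        evar = float(np.var(ebar_terms, ddof=1)) - float(polygamma(1, df / 2.0))
        if evar > 0:
            d0 = 2.0 * _trigamma_inverse(evar)
            v0 = float(np.exp(emean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
        else:
            # no excess spread: single shared variance; E[s2] = v0
            d0 = np.inf
            v0 = float(np.mean(s2[pos]))
    else:
        d0 = float(prior_df)
        emean = float(np.mean(ebar_terms))
        if np.isinf(d0):
            v0 = float(np.mean(s2[pos]))
        else:
            v0 = float(np.exp(emean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))

    if np.isinf(d0):
        post = np.full_like(s2, v0)
        moderated_df = MAX_MODERATED_DF
    else:
        post = (d0 * v0 + df * s2) / (d0 + df)
        moderated_df = min(df + d0, MAX_MODERATED_DF)
    fit = ModerationFit(d0, v0, post)
    fit.moderated_df = float(moderated_df)
    return fit


def make_gene_stats(mat: ExpressionMatrix, moderate: bool = True) -> GeneStats:
    """Compute GeneStats from an expression matrix.

    Rows with missing values are rejected with a warning.  With moderation
    off, zero-variance genes have no defined standard error and are dropped
    (also with a warning); with moderation on the prior rescues them.
    """
    finite = np.all(np.isfinite(mat.values), axis=1)
    n_dropped = int((~finite).sum())
    if n_dropped:
        warnings.warn(
            f"dropped {n_dropped} gene(s) with missing/non-finite values",
            RuntimeWarning,
        )
        mat = ExpressionMatrix(mat.values[finite], mat.gene_ids[finite], mat.group)

    effect, s2, res_df = fit_group_difference(mat)
    lab_a, lab_b = mat.labels
    n_a = int(np.sum(mat.group == lab_a))
    n_b = int(np.sum(mat.group == lab_b))
    scale = 1.0 / n_a + 1.0 / n_b

    if moderate:
        fit = moderate_variances(s2, res_df)
        var, df = fit.posterior_vars, fit.moderated_df
    else:
        var, df = s2, float(res_df)

    keep = var > 0
    n_zero = int((~keep).sum())
    if n_zero:
        warnings.warn(
            f"dropped {n_zero} zero-variance gene(s); no standard error "
            "can be assigned without moderation",
            RuntimeWarning,
        )
    return GeneStats(
        mat.gene_ids[keep],
        effect[keep],
        np.sqrt(var[keep] * scale),
        df,
    )
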