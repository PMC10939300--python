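"""Differential expression: normalization, moderated t, FDR, DEG selection.

The per-gene statistic is an empirical-Bayes moderated two-sample t-test:
the gene-wise pooled variance s^2 (residual df d) is shrunk toward a prior
variance s0^2 with prior df d0,

    s~^2 = (d0 * s0^2 + d * s^2) / (d0 + d),

and p-values come from a t distribution with d0 + d degrees of freedom.
The hyperparameters (d0, s0^2) are estimated by the method-of-moments fit
on the log sample variances (matching the scaled-F marginal of the
hierarchical model).  A constant prior is used for both microarray and
RNA-seq inputs; no mean-variance trend is fitted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionDataset, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_FDR_PRIMARY = 0.1
DEFAULT_FDR_FALLBACK = 0.2
DEFAULT_DEG_FLOOR = 15
DEFAULT_DEG_CAP = 500
MIN_SAMPLES_PER_CONDITION = 3


@dataclass(frozen=True)
class GeneStats:
    gene: str
    t: float
    p: float
    q: float


@dataclass(frozen=True)
class DEGSet:
    """An ordered list of differentially expressed genes (most significant first)."""

    genes: tuple[str, ...]
    threshold_used: float
    capped: bool

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class QCFailure:
    """Typed signal that a dataset failed DEG-based quality control."""

    reason: str
    detail: str = ""


@dataclass(frozen=True)
class QCReport:
    passed: bool
    reasons: tuple[str, ...]


def quantile_normalize(values: np.ndarray) -> np.ndarray:
    """Quantile-normalize columns so all share the same value distribution.

    The reference distribution is the per-rank mean of the column-sorted
    values.  Ties within a column receive the mean of the reference values
    over their rank span.  A single-column matrix is returned unchanged
    with a warning.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ValidationError("expected a 2-d matrix")
    n_rows, n_cols = values.shape
    if n_cols < 2:
        logger.warning("quantile_normalize: single-column matrix returned unchanged")
        return values.copy()
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(n_cols):
        col = values[:, j]
        order = np.argsort(col, kind="mergesort")
        sorted_col = col[order]
        assigned = np.empty(n_rows)
        i = 0
        while i < n_rows:
            k = i
            while k + 1 < n_rows and sorted_col[k + 1] == sorted_col[i]:
                k += 1
            assigned[i : k + 1] = reference[i : k + 1].mean()
            i = k + 1
        out[order, j] = assigned
    return out


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton on the inverse scale)."""
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of the prior (d0, s0^2) on log sample variances.

    Returns ``d0 = inf`` when the observed spread of log variances does not
    exceed the sampling spread (complete shrinkage limit).
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[s2 > 0]
    if s2.size < 2:
        return np.inf, float(s2.mean()) if s2.size else 1.0
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(e.mean())
    e_var = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if e_var <= 0:
        return np.inf, float(np.exp(e_mean))
    d0 = 2.0 * _trigamma_inverse(e_var)
    s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


def moderated_t(
    dataset: ExpressionDataset,
    d0: float | None = None,
    s0_sq: float | None = None,
) -> list[GeneStats]:
    """Per-gene moderated t statistics between case and control samples.

    ``d0``/``s0_sq`` may be forced (e.g. for the ordinary-t limit ``d0=0``);
    by default they are estimated from the data via
    :func:`fit_variance_prior`.
    """
    case = dataset.sample_indices("case")
    ctrl = dataset.sample_indices("control")
    n1, n2 = len(case), len(ctrl)
    if n1 < 2 or n2 < 2:
        raise ValidationError(
            f"{dataset.dataset_id}: need >=2 samples per condition for a t-test"
        )
    x1 = dataset.values[:, case]
    x2 = dataset.values[:, ctrl]
    diff = x1.mean(axis=1) - x2.mean(axis=1)
    ss = ((x1 - x1.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (x2 - x2.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    df = n1 + n2 - 2
    s2 = ss / df

    if d0 is None or s0_sq is None:
        est_d0, est_s0 = fit_variance_prior(s2, df)
        d0 = est_d0 if d0 is None else d0
        s0_sq = est_s0 if s0_sq is None else s0_sq

    if np.isinf(d0):
        s2_tilde = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        s2_tilde = (d0 * s0_sq + df * s2) / (d0 + df)
        df_total = d0 + df

    se = np.sqrt(s2_tilde * (1.0 / n1 + 1.0 / n2))
    t = np.zeros_like(diff)
    nonzero = se > 0
    t[nonzero] = diff[nonzero] / se[nonzero]
    # degenerate genes: zero variance everywhere and zero mean difference
    t[(~nonzero) & (diff != 0)] = np.inf * np.sign(diff[(~nonzero) & (diff != 0)])
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p[(~nonzero) & (diff == 0)] = 1.0
    p = np.clip(p, 0.0, 1.0)
    q = bh_fdr(p)
    return [
        GeneStats(g, float(ti), float(pi), float(qi))
        for g, ti, pi, qi in zip(dataset.genes, t, p, q)
    ]


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return np.array([])
    if (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def select_degs(
    stats_list: list[GeneStats],
    fdr_primary: float = DEFAULT_FDR_PRIMARY,
    fdr_fallback: float = DEFAULT_FDR_FALLBACK,
    floor: int = DEFAULT_DEG_FLOOR,
    cap: int = DEFAULT_DEG_CAP,
) -> DEGSet | QCFailure:
    """Select DEGs at the primary FDR cutoff, falling back to the looser one.

    Genes with q below the primary cutoff are taken; if fewer than ``floor``
    qualify the fallback cutoff is tried; if still fewer, a
    :class:`QCFailure` is returned.  When more than ``cap`` genes qualify,
    the ``cap`` smallest p are kept (ties broken by larger \\|t\\|, then
    gene-id).
    """
    if not stats_list:
        raise ValidationError("empty statistics list")
    ordered = sorted(stats_list, key=lambda s: (s.p, -abs(s.t), s.gene))
    for threshold in (fdr_primary, fdr_fallback):
        selected = [s for s in ordered if s.q < threshold]
        if len(selected) >= floor:
            capped = len(selected) > cap
            if capped:
                selected = selected[:cap]
            return DEGSet(tuple(s.gene for s in selected), threshold, capped)
    n_fallback = sum(1 for s in ordered if s.q < fdr_fallback)
    return QCFailure(
        "degs", f"only {n_fallback} genes at q < {fdr_fallback} (floor {floor})"
    )


def dataset_qc(
    dataset: ExpressionDataset,
    stats_list: list[GeneStats],
    min_samples: int = MIN_SAMPLES_PER_CONDITION,
    **deg_kwargs,
) -> QCReport:
    """Quality control: sample-count floor and DEG floor."""
    reasons: list[str] = []
    if dataset.n_case < min_samples or dataset.n_control < min_samples:
        reasons.append("samples")
    if isinstance(select_degs(stats_list, **deg_kwargs), QCFailure):
        reasons.append("degs")
    return QCReport(not reasons, tuple(reasons))
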