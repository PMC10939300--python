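"""Balanced positive/negative benchmarking of enrichment methods.

The positive benchmark scores each dataset's target pathway and its
network-related pathways as true positives at p < alpha.  The negative
benchmark rescores the same pathways on gene-label-randomized copies of
the datasets, where they are true negatives; restricting the null
evaluation to each dataset's positive list keeps the two benchmarks the
same size (TP + FN = TN + FP per dataset-repeat).  Sensitivity and
specificity are condensed into their geometric mean (G-mean), and ranking
quality into tie-averaged relative ranks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import EnrichmentResultMatrix, ExpressionDataset, ValidationError
from .network import DiseasePathwayNetwork, jaccard

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05
DEFAULT_REPEATS = 30
NULL_ID_SEP = "|null"


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fn: int = 0
    tn: int = 0
    fp: int = 0

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fn + other.fn, self.tn + other.tn, self.fp + other.fp
        )


@dataclass(frozen=True)
class SummaryMetrics:
    tpr: float
    tnr: float
    g_mean: float
    median_relative_rank: float | None = None


def positives_for(target: str, dpn: DiseasePathwayNetwork) -> list[str]:
    """Positive pathways for a dataset: its target plus related pathways."""
    return dpn.positives_for(target)


def positive_counts(
    results: EnrichmentResultMatrix,
    positives: dict[str, list[str]],
    alpha: float = DEFAULT_ALPHA,
) -> ConfusionCounts:
    """TP/FN over all datasets: positives with p < alpha count as detected.

    The threshold is strict, so p exactly at alpha counts as a miss.
    """
    if not (0 < alpha < 1):
        raise ValidationError("alpha must lie in (0, 1)")
    tp = fn = 0
    for dataset_id, pos in positives.items():
        if dataset_id not in results.pvalues.columns:
            raise ValidationError(f"dataset {dataset_id!r} missing from the result matrix")
        col = results.pvalues.loc[pos, dataset_id]
        hits = int((col < alpha).sum())
        tp += hits
        fn += len(pos) - hits
    return ConfusionCounts(tp=tp, fn=fn)


def null_dataset_id(source_id: str, repeat: int) -> str:
    return f"{source_id}{NULL_ID_SEP}{repeat}"


def source_of(null_id: str) -> str:
    return null_id.split(NULL_ID_SEP, 1)[0]


def make_null_datasets(
    datasets: list[ExpressionDataset],
    repeats: int,
    rng: np.random.Generator,
    label_pool: list[str],
) -> list[ExpressionDataset]:
    """Gene-label-randomized copies of the datasets, ``repeats`` per source.

    Expression values and designs are preserved; gene labels are replaced
    by a uniform draw (without replacement) from the genome label pool, so
    the DEG machinery yields the same number of DEGs per dataset but with
    random identities.
    """
    if repeats < 1:
        raise ValidationError("repeats must be >= 1")
    pool = np.array(sorted(set(label_pool)), dtype=object)
    out: list[ExpressionDataset] = []
    for r in range(repeats):
        for ds in datasets:
            if len(pool) < len(ds.genes):
                raise ValidationError(
                    f"label pool ({len(pool)}) smaller than gene count of {ds.dataset_id}"
                )
            labels = rng.choice(pool, size=len(ds.genes), replace=False).tolist()
            out.append(ds.with_labels(labels, null_dataset_id(ds.dataset_id, r)))
    return out


def negative_counts(
    null_results: EnrichmentResultMatrix,
    positives: dict[str, list[str]],
    alpha: float = DEFAULT_ALPHA,
    mode: str = "restrict",
) -> ConfusionCounts:
    """TN/FP on the null battery, balanced against the positive benchmark.

    ``mode='restrict'`` (default) evaluates, for each null dataset, only
    the positive pathways of its source dataset - under random gene labels
    those are true negatives, and the negative benchmark then has exactly
    as many tests per repeat as the positive one.  ``mode='rescale'``
    instead computes the false-positive fraction over the full pathway
    panel and rescales it to the positive count.
    """
    if mode not in ("restrict", "rescale"):
        raise ValidationError(f"unknown mode {mode!r}")
    tn = fp = 0
    if mode == "rescale":
        frac_fp = 0.0
        total = 0
        for null_id in null_results.pvalues.columns:
            col = null_results.pvalues[null_id]
            frac_fp += float((col < alpha).mean()) * len(positives[source_of(null_id)])
            total += len(positives[source_of(null_id)])
        fp = int(round(frac_fp))
        tn = total - fp
        return ConfusionCounts(tn=tn, fp=fp)
    for null_id in null_results.pvalues.columns:
        src = source_of(null_id)
        if src not in positives:
            raise ValidationError(f"no positive list for source dataset {src!r}")
        col = null_results.pvalues.loc[positives[src], null_id]
        hits = int((col < alpha).sum())
        fp += hits
        tn += len(positives[src]) - hits
    return ConfusionCounts(tn=tn, fp=fp)


def summarize(counts: ConfusionCounts) -> SummaryMetrics:
    """TPR, TNR and their geometric mean."""
    if counts.tp + counts.fn == 0 or counts.tn + counts.fp == 0:
        raise ValidationError("confusion counts have an empty benchmark side")
    tpr = counts.tp / (counts.tp + counts.fn)
    tnr = counts.tn / (counts.tn + counts.fp)
    return SummaryMetrics(tpr, tnr, float(np.sqrt(tpr * tnr)))


def relative_ranks(
    results: EnrichmentResultMatrix,
    positives: dict[str, list[str]],
    denominator: str = "n",
) -> tuple[list[float], float]:
    """Tie-averaged relative rank of every positive pathway, plus the median.

    Per dataset, pathways are sorted by ascending p-value; tied p-values
    receive the mean of their rank span; a positive pathway's relative
    rank is the fraction of ranks more significant than it,
    (rank - 1) / N.  ``denominator='n-1'`` switches to (rank - 1) / (N - 1).
    """
    if denominator not in ("n", "n-1"):
        raise ValidationError(f"unknown denominator {denominator!r}")
    n_pathways = len(results.pvalues.index)
    ranks_out: list[float] = []
    for dataset_id, pos in positives.items():
        col = results.pvalues[dataset_id].to_numpy()
        ranks = sps.rankdata(col, method="average")
        index = {pid: i for i, pid in enumerate(results.pvalues.index)}
        denom = n_pathways if denominator == "n" else max(n_pathways - 1, 1)
        for pid in pos:
            ranks_out.append(float((ranks[index[pid]] - 1) / denom))
    return ranks_out, float(np.median(ranks_out)) if ranks_out else float("nan")


def per_pathway_fpr(
    null_results: EnrichmentResultMatrix, alpha: float = DEFAULT_ALPHA
) -> pd.Series:
    """Fraction of null tests with p < alpha, per pathway."""
    if null_results.pvalues.shape[1] == 0:
        raise ValidationError("no null datasets")
    return (null_results.pvalues < alpha).mean(axis=1)


@dataclass(frozen=True)
class SkewProfile:
    classification: str  # right-skewed | left-skewed | bimodal | uniform
    m0: float  # mass in [0, 0.1]
    m1: float  # mass in [0.9, 1]


def skew_profile(
    pvalues,
    low_band: float = 0.1,
    high_mass: float = 0.15,
    uniform_band: tuple[float, float] = (0.05, 0.15),
) -> SkewProfile:
    """Classify a null p-value distribution by the mass at its extremes.

    m0 is the mass in [0, ``low_band``], m1 the mass in [1 - ``low_band``, 1].
    Both above ``high_mass`` reads bimodal, only m0 right-skewed (toward 0),
    only m1 left-skewed (toward 1); otherwise uniform (both masses should
    sit inside ``uniform_band`` for an exactly calibrated method).
    """
    if isinstance(pvalues, EnrichmentResultMatrix):
        p = pvalues.pvalues.to_numpy().ravel()
    else:
        p = np.asarray(pvalues, dtype=float).ravel()
    if p.size < 100:
        raise ValidationError("need at least 100 null p-values for a skew profile")
    m0 = float((p <= low_band).mean())
    m1 = float((p >= 1 - low_band).mean())
    if m0 > high_mass and m1 > high_mass:
        label = "bimodal"
    elif m0 > high_mass:
        label = "right-skewed"
    elif m1 > high_mass:
        label = "left-skewed"
    else:
        label = "uniform"
    return SkewProfile(label, m0, m1)


def overlap_coefficient(A: set, B: set) -> float:
    """Szymkiewicz-Simpson coefficient |A n B| / min(|A|, |B|)."""
    if not A or not B:
        return 0.0
    return len(A & B) / min(len(A), len(B))


def consistency(
    results: EnrichmentResultMatrix,
    disease_groups: dict[str, list[str]],
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Cross-dataset consistency of significant pathway sets per disease.

    For every dataset pair within a disease group the significant sets
    (p < alpha) are compared by Jaccard index and by the
    Szymkiewicz-Simpson overlap coefficient; per-group medians are
    returned.  Pairs where either set is empty score 0 on both measures;
    groups with fewer than two datasets are skipped with a warning.
    """
    rows = []
    for disease, dataset_ids in disease_groups.items():
        if len(dataset_ids) < 2:
            logger.warning("disease group %r has <2 datasets; skipped", disease)
            continue
        sig = {
            d: set(results.pvalues.index[results.pvalues[d] < alpha]) for d in dataset_ids
        }
        jac, ovl = [], []
        for i, a in enumerate(dataset_ids):
            for b in dataset_ids[i + 1 :]:
                if not sig[a] or not sig[b]:
                    jac.append(0.0)
                    ovl.append(0.0)
                else:
                    jac.append(jaccard(sig[a], sig[b]))
                    ovl.append(overlap_coefficient(sig[a], sig[b]))
        rows.append(
            {
                "disease": disease,
                "n_pairs": len(jac),
                "median_jaccard": float(np.median(jac)),
                "median_overlap": float(np.median(ovl)),
            }
        )
    return pd.DataFrame(rows)


def evaluate_method(
    results: EnrichmentResultMatrix,
    null_results: EnrichmentResultMatrix,
    positives: dict[str, list[str]],
    alpha: float = DEFAULT_ALPHA,
    negative_mode: str = "restrict",
) -> tuple[ConfusionCounts, SummaryMetrics]:
    """Full balanced evaluation of one method: counts and summary metrics."""
    pos = positive_counts(results, positives, alpha)
    neg = negative_counts(null_results, positives, alpha, mode=negative_mode)
    counts = pos + neg
    _, median_rr = relative_ranks(results, positives)
    base = summarize(counts)
    return counts, SummaryMetrics(base.tpr, base.tnr, base.g_mean, median_rr)
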