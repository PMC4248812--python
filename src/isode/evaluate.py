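"""Ground-truth construction from qPCR CT tables and accuracy evaluation.

Ground truth follows the delta-CT workflow: CT values above 35 are clamped
to 35; each replicate CT is subtracted from the mean reference-gene
(POLR2A) CT of the same condition to give the log2-scale delta CT, and
normalized expression is 2^(delta CT).  Genes undetected in any replicate,
or with coefficient of variation above 25% among the four normalized values
in either condition, are dropped.  A gene is truly DE when the fold change
of mean normalized expression exceeds the threshold and an unpaired
two-tailed t-test on delta CT (BH-adjusted at 5% FDR) rejects; the
direction is the higher condition.

Predictions are scored against the 3x3 confusion matrix over
{over, non-DE, under} x {TOE, TND, TUE} with

    sensitivity = (TPOE + TPUE) / (TOE + TUE)
    PPV         = (TPOE + TPUE) / (POE + PUE)
    accuracy    = (TPOE + TPND + TPUE) / (TOE + TND + TUE)
    F-score     = 2 * sensitivity * PPV / (sensitivity + PPV)

optionally stratified by expression quintile.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .bootstrap_de import DECall
from .comparators import bh_adjust

__all__ = [
    "QpcrAssay",
    "GroundTruthConfig",
    "ConfusionMatrix3x3",
    "Metrics",
    "qpcr_ground_truth",
    "confusion",
    "metrics",
    "quintile_metrics",
]

PRED_LEVELS = ("over", "non-DE", "under")
TRUTH_LEVELS = ("TOE", "TND", "TUE")
_PRED_OF_TRUTH = {"TOE": "over", "TND": "non-DE", "TUE": "under"}


@dataclass
class QpcrAssay:
    """One gene's TaqMan assay: replicate CT values per condition."""

    gene_id: str
    cts_cond_a: list[float]
    cts_cond_b: list[float]
    detected_a: list[bool] | None = None
    detected_b: list[bool] | None = None

    def __post_init__(self) -> None:
        if self.detected_a is None:
            self.detected_a = [math.isfinite(c) for c in self.cts_cond_a]
        if self.detected_b is None:
            self.detected_b = [math.isfinite(c) for c in self.cts_cond_b]
        if len(self.cts_cond_a) != len(self.cts_cond_b):
            raise ValueError(
                f"{self.gene_id}: replicate counts differ between conditions"
            )


@dataclass
class GroundTruthConfig:
    reference_gene: str = "POLR2A"
    ct_clamp: float = 35.0
    sd_filter: float = 0.25  # max CV of normalized expression per condition
    fold_threshold: float = 2.0
    fdr: float = 0.05
    t_test: str = "student"  # or "welch"

    def __post_init__(self) -> None:
        if self.ct_clamp <= 0:
            raise ValueError("ct_clamp must be positive")
        if not 0 < self.sd_filter < 1:
            raise ValueError("sd_filter must be in (0, 1)")
        if self.t_test not in ("student", "welch"):
            raise ValueError(f"unknown t_test {self.t_test!r}")


@dataclass
class ConfusionMatrix3x3:
    """Predicted {over, non-DE, under} x truth {TOE, TND, TUE} counts."""

    counts: np.ndarray  # (3, 3), rows predicted, cols truth

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (3, 3) or (self.counts < 0).any():
            raise ValueError("confusion matrix must be 3x3 with counts >= 0")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def __add__(self, other: "ConfusionMatrix3x3") -> "ConfusionMatrix3x3":
        return ConfusionMatrix3x3(self.counts + other.counts)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=PRED_LEVELS, columns=TRUTH_LEVELS)


@dataclass
class Metrics:
    sensitivity: float
    ppv: float
    accuracy: float
    fscore: float


def _clamped(cts: Sequence[float], clamp: float) -> np.ndarray:
    return np.minimum(np.asarray(cts, dtype=float), clamp)


def qpcr_ground_truth(
    assays: Iterable[QpcrAssay], cfg: GroundTruthConfig | None = None
) -> dict[str, str]:
    """Label genes TOE / TND / TUE from replicate qPCR CT values.

    TOE means over-expressed in condition A relative to B; genes failing
    the detection or variability filters are absent from the result.
    """
    cfg = cfg or GroundTruthConfig()
    assays = list(assays)
    ref = next((a for a in assays if a.gene_id == cfg.reference_gene), None)
    if ref is None:
        raise ValueError(f"reference gene {cfg.reference_gene!r} missing from assays")
    ref_mean_a = _clamped(ref.cts_cond_a, cfg.ct_clamp).mean()
    ref_mean_b = _clamped(ref.cts_cond_b, cfg.ct_clamp).mean()

    kept: list[tuple[str, np.ndarray, np.ndarray]] = []
    for a in assays:
        if a.gene_id == cfg.reference_gene:
            continue
        if not (all(a.detected_a) and all(a.detected_b)):
            continue
        # delta CT per replicate; normalized expression 2^dct
        dct_a = ref_mean_a - _clamped(a.cts_cond_a, cfg.ct_clamp)
        dct_b = ref_mean_b - _clamped(a.cts_cond_b, cfg.ct_clamp)
        expr_a = np.exp2(dct_a)
        expr_b = np.exp2(dct_b)
        if expr_a.mean() <= 0 or expr_b.mean() <= 0:
            continue
        cv_a = expr_a.std(ddof=1) / expr_a.mean()
        cv_b = expr_b.std(ddof=1) / expr_b.mean()
        if cv_a > cfg.sd_filter or cv_b > cfg.sd_filter:
            continue
        kept.append((a.gene_id, dct_a, dct_b))

    if not kept:
        return {}
    pvals = []
    for _, dct_a, dct_b in kept:
        # t-test on the log2 (delta-CT) scale, the scale the data live on;
        # zero-variance degenerate inputs give p=0 (separated) or nan -> 1
        equal_var = cfg.t_test == "student"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            t = stats.ttest_ind(dct_a, dct_b, equal_var=equal_var)
        pvals.append(1.0 if math.isnan(t.pvalue) else float(t.pvalue))
    adj, _ = bh_adjust(pvals, cfg.fdr)

    labels: dict[str, str] = {}
    for (gene, dct_a, dct_b), p_adj in zip(kept, adj):
        mean_a = float(np.exp2(dct_a).mean())
        mean_b = float(np.exp2(dct_b).mean())
        fold = max(mean_a, mean_b) / min(mean_a, mean_b) if min(mean_a, mean_b) > 0 else math.inf
        if fold > cfg.fold_threshold and p_adj < 0.05:
            labels[gene] = "TOE" if mean_a > mean_b else "TUE"
        else:
            labels[gene] = "TND"
    return labels


def confusion(
    pred: Iterable[DECall] | Mapping[str, str], truth: Mapping[str, str]
) -> ConfusionMatrix3x3:
    """3x3 cross-tabulation of predictions against ground-truth labels.

    Evaluated over the truth gene set; a truth gene with no prediction
    counts as predicted non-DE (the caller made no positive claim).
    """
    if isinstance(pred, Mapping):
        pred_status = dict(pred)
    else:
        pred_status = {c.gene_id: c.status for c in pred}
    if not truth:
        raise ValueError("empty ground-truth label set")
    common = set(pred_status) & set(truth)
    if not common:
        raise ValueError("prediction and truth gene sets do not intersect")
    return _tabulate(pred_status, truth)


def _tabulate(pred_status: Mapping[str, str], truth: Mapping[str, str]) -> ConfusionMatrix3x3:
    counts = np.zeros((3, 3), dtype=np.int64)
    pi = {s: i for i, s in enumerate(PRED_LEVELS)}
    ti = {s: i for i, s in enumerate(TRUTH_LEVELS)}
    for g, label in truth.items():
        p = pred_status.get(g, "non-DE")
        counts[pi[p], ti[label]] += 1
    return ConfusionMatrix3x3(counts)


def metrics(cm: ConfusionMatrix3x3) -> Metrics:
    """Sensitivity, PPV, accuracy and F-score from the 3x3 matrix.

    Undefined ratios (zero denominator) are returned as NaN.
    """
    c = cm.counts
    tpoe, tpnd, tpue = c[0, 0], c[1, 1], c[2, 2]
    toe, tnd, tue = c[:, 0].sum(), c[:, 1].sum(), c[:, 2].sum()
    poe, pue = c[0, :].sum(), c[2, :].sum()

    def _ratio(num: float, den: float) -> float:
        return float(num) / float(den) if den > 0 else float("nan")

    sens = _ratio(tpoe + tpue, toe + tue)
    ppv = _ratio(tpoe + tpue, poe + pue)
    acc = _ratio(tpoe + tpnd + tpue, toe + tnd + tue)
    if math.isnan(sens) or math.isnan(ppv) or sens + ppv == 0:
        f = float("nan")
    else:
        f = 2 * sens * ppv / (sens + ppv)
    return Metrics(sensitivity=sens, ppv=ppv, accuracy=acc, fscore=f)


def quintile_metrics(
    pred: Iterable[DECall] | Mapping[str, str],
    truth: Mapping[str, str],
    expression: Mapping[str, float],
) -> list[tuple[ConfusionMatrix3x3, Metrics]]:
    """Metrics per expression quintile.

    Evaluated genes are sorted by average expression ascending (ties broken
    by gene ID) and split into 5 near-equal bins; quintile 1 holds the
    lowest-expressed genes.  Returns (confusion matrix, metrics) per bin.
    """
    if isinstance(pred, Mapping):
        pred_status = dict(pred)
    else:
        pred_status = {c.gene_id: c.status for c in pred}
    genes = [g for g in truth if g in expression]
    if len(genes) < 5:
        raise ValueError(f"need at least 5 genes for quintiles, got {len(genes)}")
    order = sorted(genes, key=lambda g: (expression[g], g))
    out = []
    for chunk in np.array_split(np.array(order, dtype=object), 5):
        cm = _tabulate(pred_status, {g: truth[g] for g in chunk})
        out.append((cm, metrics(cm)))
    return out
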