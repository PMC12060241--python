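"""Evaluation of post-imputation filters against gold-standard truth labels.

Provides the confusion accounting used throughout the benchmark (total /
false / true counts with the False % statistic per stratum), ROC analysis
of imputation-quality measures as classifiers of false associations, and
threshold selection at a target specificity.

Conventions: an association is *false* when it is significant only in the
imputed data, not in the gold-standard complete data.  In the ROC,
sensitivity is the fraction of false associations correctly discarded and
specificity the fraction of true associations correctly kept; the discard
rule at threshold ``t`` is ``quality < t``, matching the filter.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

__all__ = [
    "false_percent",
    "snp_confusion",
    "spike_confusion",
    "threshold_filter_spikes",
    "roc",
    "threshold_at_specificity",
    "RocResult",
]


def false_percent(false_count: int, total: int) -> float:
    """Percentage of false positives among all positives, rounded half-up
    to 2 decimals (printed-table convention)."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= false_count <= total:
        raise ValueError("need 0 <= false_count <= total")
    val = Decimal(100 * false_count) / Decimal(total)
    return float(val.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def _row(label: str, is_false: np.ndarray) -> dict:
    total = int(is_false.size)
    false = int(is_false.sum())
    return {
        "stratum": label,
        "total": total,
        "false": false,
        "true": total - false,
        "false_percent": false_percent(false, total) if total else np.nan,
    }


def snp_confusion(
    p_values: np.ndarray,
    truth: np.ndarray,
    quality: np.ndarray,
    significance: float = 5e-8,
    lower: float = 0.3,
    upper: float = 0.8,
) -> pd.DataFrame:
    """Stratified confusion table for significant SNPs of one format.

    ``truth`` is True for SNPs whose association is real (significant in the
    gold standard).  Rows: all significant SNPs, those surviving the upper
    and lower quality thresholds, and those in the midrange
    (``lower < quality < upper``).
    """
    p_values = np.asarray(p_values, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    quality = np.asarray(quality, dtype=float)
    sig = p_values < significance
    is_false = ~truth
    rows = [
        _row("all", is_false[sig]),
        _row(f">{upper}", is_false[sig & (quality > upper)]),
        _row(f">{lower}", is_false[sig & (quality > lower)]),
        _row("midrange", is_false[sig & (quality > lower) & (quality < upper)]),
    ]
    return pd.DataFrame(rows)


def spike_confusion(
    truth,
    retained: dict[str, np.ndarray],
    partial: dict[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Spike-level confusion rows comparing filters on one set of spikes.

    ``truth`` is a boolean vector over spikes (True = real signal).
    ``retained`` maps a filter name (e.g. ">0.8", ">0.3", "midrange_filter")
    to a boolean retained-vector; a spike counts as retained if any member
    survives.  ``partial`` optionally marks spikes retained with some
    members deleted, reported in a ``partial`` column.  The first row,
    "unfiltered", is the untouched spike set.
    """
    truth = np.asarray(truth, dtype=bool)
    is_false = ~truth
    rows = [_row("unfiltered", is_false)]
    if partial is not None:
        rows[0]["partial"] = 0
    for label, kept in retained.items():
        kept = np.asarray(kept, dtype=bool)
        if kept.shape != truth.shape:
            raise ValueError(f"retained[{label!r}] length mismatch")
        r = _row(label, is_false[kept])
        if partial is not None:
            r["partial"] = int((np.asarray(partial.get(label, np.zeros_like(kept)), bool) & kept).sum())
        rows.append(r)
    df = pd.DataFrame(rows)
    if len(truth) == 0:
        df["false_percent"] = np.nan
    return df


def threshold_filter_spikes(
    member_quality: list[np.ndarray], threshold: float
) -> tuple[np.ndarray, np.ndarray]:
    """Plain per-SNP thresholding applied at spike level (compatibility mode).

    For each spike, given the quality values of its significant members,
    discard members with ``quality < threshold``.  The spike is retained if
    any member survives; it is partial if retained but some members were
    deleted.  Returns (retained, partial) boolean arrays.
    """
    retained = np.zeros(len(member_quality), dtype=bool)
    partial = np.zeros(len(member_quality), dtype=bool)
    for i, q in enumerate(member_quality):
        q = np.asarray(q, dtype=float)
        keep = q >= threshold
        retained[i] = bool(keep.any())
        partial[i] = bool(keep.any() and (~keep).any())
    return retained, partial


@dataclass
class RocResult:
    """ROC sweep of a quality measure as a false-association classifier."""

    thresholds: np.ndarray
    sensitivity: np.ndarray  # fraction of false associations discarded
    specificity: np.ndarray  # fraction of true associations kept
    auc: float

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
            }
        )


def roc(quality: np.ndarray, truth: np.ndarray) -> RocResult:
    """ROC of discarding associations with ``quality < t`` over all t.

    ``truth`` True marks real associations.  AUC is the trapezoid over
    (1 - specificity, sensitivity), equal to
    ``P(q_false < q_true) + 0.5 P(tie)``.
    """
    quality = np.asarray(quality, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    n_false = int((~truth).sum())
    n_true = int(truth.sum())
    if n_false == 0 or n_true == 0:
        raise ValueError("roc needs at least one false and one true label")
    ts = np.concatenate([[-np.inf], np.unique(quality), [np.inf]])
    sens = np.empty(ts.size)
    spec = np.empty(ts.size)
    for i, t in enumerate(ts):
        disc = quality < t
        sens[i] = (disc & ~truth).sum() / n_false
        spec[i] = (~disc & truth).sum() / n_true
    order = np.argsort(1 - spec, kind="stable")
    auc = float(np.trapezoid(sens[order], (1 - spec)[order]))
    return RocResult(thresholds=ts, sensitivity=sens, specificity=spec, auc=auc)


def threshold_at_specificity(
    roc_result: RocResult, target_specificity: float
) -> tuple[float, float, bool]:
    """Largest finite threshold whose specificity meets the target.

    Returns ``(threshold, sensitivity, reached)``; when no finite threshold
    reaches the target, returns ``(0.0, 0.0, False)``.  The discard-all
    endpoint (+inf) is excluded: it trivially meets specificity 0 only.
    """
    finite = np.isfinite(roc_result.thresholds) | (roc_result.thresholds == -np.inf)
    ok = finite & (roc_result.specificity >= target_specificity)
    if not ok.any():
        return 0.0, 0.0, False
    idx = np.flatnonzero(ok)
    best = idx[np.argmax(roc_result.thresholds[idx])]
    t = roc_result.thresholds[best]
    if t == -np.inf:
        t = float(np.min(roc_result.thresholds[np.isfinite(roc_result.thresholds)]))
    return float(t), float(roc_result.sensitivity[best]), True
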