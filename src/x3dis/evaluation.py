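"""Residue-level evaluation measures and dataset composition summaries.

Disorder prediction is heavily imbalanced (~6% of residues are disordered),
so plain accuracy is uninformative.  The measures used throughout are the
sensitivity, specificity, their arithmetic mean (balanced accuracy), the
precision, the F-measure (harmonic mean of precision and sensitivity) and
the area under the ROC curve, all with the disordered residue as the
positive class.  Uncertainty is quantified by protein-level bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from x3dis.protein_model import ProteinRecord


class EvaluationError(ValueError):
    pass


def _as_label_array(labels) -> np.ndarray:
    if isinstance(labels, str):
        labels = list(labels)
    arr = np.asarray(labels)
    if arr.dtype.kind in "USb":
        arr = np.asarray([1 if c in ("D", 1, True) else 0 for c in labels], dtype=int)
    else:
        arr = arr.astype(int)
    return arr


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/TN/FN with the disordered residue as the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricsReport:
    """The five residue-level measures, stored on the [0, 1] scale.

    `degenerate` flags that at least one denominator was 0/0 and the
    corresponding measure was reported as 0 by convention.
    """

    sensitivity: float
    specificity: float
    balanced_accuracy: float
    precision: float
    f_measure: float
    auc: float | None = None
    degenerate: bool = False

    def as_dict(self, percent: bool = False) -> dict[str, float]:
        out = {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "balanced_accuracy": self.balanced_accuracy,
            "precision": self.precision,
            "f_measure": self.f_measure,
        }
        if percent:
            out = {k: 100.0 * v for k, v in out.items()}
        if self.auc is not None:
            out["auc"] = self.auc  # AUC is conventionally left on [0, 1]
        return out


def confusion_counts(labels, calls) -> ConfusionCounts:
    """Count prediction quadrants from O/D label and call strings."""
    y = _as_label_array(labels)
    yhat = _as_label_array(calls)
    if y.shape != yhat.shape:
        raise EvaluationError(
            f"labels ({y.size}) and calls ({yhat.size}) differ in length"
        )
    return ConfusionCounts(
        tp=int(np.sum((y == 1) & (yhat == 1))),
        fp=int(np.sum((y == 0) & (yhat == 1))),
        tn=int(np.sum((y == 0) & (yhat == 0))),
        fn=int(np.sum((y == 1) & (yhat == 0))),
    )


def _safe_div(num: float, den: float) -> tuple[float, bool]:
    if den == 0:
        return 0.0, True
    return num / den, False


def residue_metrics(cc: ConfusionCounts) -> MetricsReport:
    """Sensitivity, specificity, balanced accuracy, precision, F-measure.

    0/0 denominators yield 0 with the degenerate flag set rather than an
    exception, so that summary tables over degenerate subsets still render.
    """
    sens, d1 = _safe_div(cc.tp, cc.tp + cc.fn)
    spec, d2 = _safe_div(cc.tn, cc.tn + cc.fp)
    prec, d3 = _safe_div(cc.tp, cc.tp + cc.fp)
    f, d4 = _safe_div(2.0 * prec * sens, prec + sens)
    return MetricsReport(
        sensitivity=sens,
        specificity=spec,
        balanced_accuracy=(sens + spec) / 2.0,
        precision=prec,
        f_measure=f,
        degenerate=d1 or d2 or d3 or d4,
    )


def roc_auc(probs, labels) -> float:
    """Area under the ROC curve via the rank (Mann-Whitney) estimator.

    Equals the probability that a randomly chosen disordered residue is
    scored above a randomly chosen ordered one, ties counted half; 1.00 is a
    perfect ranking, 0.50 a random one.
    """
    y = _as_label_array(labels)
    p = np.asarray(probs, dtype=float)
    if y.shape != p.shape:
        raise EvaluationError("probs and labels differ in length")
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise EvaluationError("roc_auc requires both classes")
    ranks = rankdata(p)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def metrics_with_threshold(labels, probs, threshold: float) -> MetricsReport:
    """Full report (incl. AUC) from probabilities and a decision threshold."""
    p = np.asarray(probs, dtype=float)
    calls = (p > threshold).astype(int)
    report = residue_metrics(confusion_counts(labels, calls))
    y = _as_label_array(labels)
    auc = roc_auc(p, y) if 0 < y.sum() < y.size else None
    return MetricsReport(
        sensitivity=report.sensitivity,
        specificity=report.specificity,
        balanced_accuracy=report.balanced_accuracy,
        precision=report.precision,
        f_measure=report.f_measure,
        auc=auc,
        degenerate=report.degenerate,
    )


def bootstrap_metrics(
    labels_by_protein: Sequence,
    probs_by_protein: Sequence[np.ndarray],
    threshold: float,
    fraction: float = 1.0,
    n_reps: int = 100,
    seed: int = 0,
    max_retries: int = 100,
) -> pd.DataFrame:
    """Protein-level resampling distribution of the evaluation measures.

    With ``fraction < 1`` each replicate subsamples that fraction of
    proteins without replacement; with ``fraction == 1`` replicates are
    classical bootstrap copies drawn with replacement.  Replicates whose
    pooled labels are single-class are re-drawn (bounded retries).  Returns
    a DataFrame with a mean and an sd row per measure.
    """
    if n_reps < 2:
        raise EvaluationError("n_reps must be >= 2")
    if not 0 < fraction <= 1:
        raise EvaluationError("fraction must be in (0, 1]")
    m = len(labels_by_protein)
    if m != len(probs_by_protein):
        raise EvaluationError("labels and probs must pair per protein")
    labels_arr = [_as_label_array(l) for l in labels_by_protein]
    probs_arr = [np.asarray(p, dtype=float) for p in probs_by_protein]
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n_reps):
        for _attempt in range(max_retries):
            if fraction < 1.0:
                k = max(1, int(round(fraction * m)))
                idx = rng.choice(m, size=k, replace=False)
            else:
                idx = rng.choice(m, size=m, replace=True)
            y = np.concatenate([labels_arr[j] for j in idx])
            if 0 < y.sum() < y.size:
                break
        else:
            raise EvaluationError("could not draw a two-class replicate")
        p = np.concatenate([probs_arr[j] for j in idx])
        rep = metrics_with_threshold(y, p, threshold)
        rows.append(rep.as_dict())
    df = pd.DataFrame(rows)
    return pd.DataFrame({"mean": df.mean(), "sd": df.std(ddof=1)})


def round_percent(x: float, decimals: int = 2) -> float:
    """Percentage rendering with round-half-up, as in printed tables."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def composition_percentages(ordered: int, disordered: int) -> dict[str, float]:
    """Ordered/disordered portions (percent, 2 decimals) from raw counts."""
    total = ordered + disordered
    if total == 0:
        raise EvaluationError("empty composition")
    return {
        "ordered_pct": round_percent(100.0 * ordered / total),
        "disordered_pct": round_percent(100.0 * disordered / total),
    }


def region_stats_from_counts(
    n_regions: int, disordered_residues: int, n_proteins: int
) -> dict[str, float]:
    """Mean disordered-region length and regions per protein from counts."""
    if n_regions == 0 or n_proteins == 0:
        raise EvaluationError("need at least one region and one protein")
    return {
        "mean_region_length": disordered_residues / n_regions,
        "regions_per_protein": n_regions / n_proteins,
    }


def summarize_dataset(records: Sequence[ProteinRecord]) -> dict[str, float]:
    """Composition report: counts, percentages and disordered-region stats."""
    missing = [r.id for r in records if r.disorder is None]
    if missing:
        raise EvaluationError(f"records without disorder labels: {missing[:5]}")
    n_proteins = len(records)
    n_res = sum(r.n for r in records)
    n_dis = sum(r.disorder.labels.count("D") for r in records)
    n_ord = n_res - n_dis
    regions = [reg for r in records for reg in r.disorder.regions]
    n_regions = len(regions)
    out = {
        "n_proteins": n_proteins,
        "n_ordered": n_ord,
        "n_disordered": n_dis,
        "n_residues": n_res,
        "n_regions": n_regions,
    }
    out.update(composition_percentages(n_ord, n_dis))
    if n_regions:
        out.update(region_stats_from_counts(n_regions, n_dis, n_proteins))
    else:
        out.update({"mean_region_length": 0.0, "regions_per_protein": 0.0})
    return out


def ss3_disorder_crosstab(records: Sequence[ProteinRecord]) -> pd.DataFrame:
    """3x2 contingency of predicted secondary structure vs. disorder state.

    Rows H/E/C, columns ordered/disordered; `*_pct` columns give the
    column-conditional percentages (each class of residues sums to 100).
    """
    counts = np.zeros((3, 2), dtype=int)
    for rec in records:
        if "ss3" not in rec.tracks:
            raise EvaluationError(f"protein {rec.id!r} lacks the ss3 track")
        if rec.disorder is None:
            raise EvaluationError(f"protein {rec.id!r} lacks disorder labels")
        ss = rec.tracks["ss3"].argmax_labels()
        dis = rec.disorder.as_mask().astype(int)
        for s, d in zip(ss, dis):
            counts[s, d] += 1
    df = pd.DataFrame(counts, index=list("HEC"), columns=["ordered", "disordered"])
    for col in ("ordered", "disordered"):
        total = df[col].sum()
        df[f"{col}_pct"] = [
            round_percent(100.0 * v / total) if total else 0.0 for v in df[col]
        ]
    return df
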