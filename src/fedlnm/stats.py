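"""Diagnostic-accuracy statistics for binary reader calls against a pathology gold standard.

The central object is the 2x2 :class:`ContingencyTable` (TP/FP/FN/TN) of a
modality's lymph-node-metastasis (LNM) calls against histopathology. From it we
derive sensitivity, specificity, predictive values, accuracy and the
single-operating-point AUC, and compare groups with Pearson's chi-squared test
(proportions) and an unpaired z-test on AUCs (DeLong-type variance).

For a reader that issues a single binary call the empirical ROC curve is the
polyline (0,0) -> (1-specificity, sensitivity) -> (1,1), whose trapezoidal area
is exactly (sensitivity + specificity) / 2; that identity is what makes the
published AUCs recoverable from the published 2x2 counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_curve as _sk_roc_curve

from .exceptions import InputError

__all__ = [
    "ContingencyTable",
    "DiagnosticMetrics",
    "GroupComparison",
    "build_contingency",
    "compute_metrics",
    "compare_proportions",
    "compare_auc_unpaired",
    "roc_from_scores",
    "binary_auc_variance",
    "load_packaged_contingency",
    "load_published_metrics",
    "round_half_up",
]

ALPHA = 0.05  # two-sided significance level used throughout


def round_half_up(x: float, ndigits: int) -> float:
    """Round with ties away from zero (the convention used by the published tables)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts of a binary diagnostic call against the pathology truth."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise InputError(f"count {name}={v!r} must be a non-negative integer")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def n_positive(self) -> int:
        """Pathology-positive margin."""
        return self.tp + self.fn

    @property
    def n_negative(self) -> int:
        """Pathology-negative margin."""
        return self.fp + self.tn


@dataclass(frozen=True)
class DiagnosticMetrics:
    """Point metrics of a binary test; metrics whose margin is empty are None and flagged."""

    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    accuracy: float | None
    auc: float | None
    auc_ci: tuple[float, float] | None
    n: int
    undefined: tuple[str, ...] = ()


@dataclass(frozen=True)
class GroupComparison:
    """Two-group comparison of one metric; ``significant`` is at alpha=0.05 two-sided."""

    metric_name: str
    statistic: float | None
    p_value: float | None
    method: str  # "pearson_chi2" or "auc_z"
    significant: bool | None = field(default=None)
    undefined: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.p_value is not None:
            if not 0.0 <= self.p_value <= 1.0:
                raise InputError(f"p_value {self.p_value} outside [0, 1]")
            object.__setattr__(self, "significant", bool(self.p_value < ALPHA))


def build_contingency(calls: Sequence[bool | int], truths: Sequence[bool | int]) -> ContingencyTable:
    """Cross-tabulate binary calls against pathology truths.

    ``calls`` must already be filtered to performed examinations (no
    not-performed entries); each entry is truthy for a positive call.
    """
    if len(calls) != len(truths):
        raise InputError(f"calls ({len(calls)}) and truths ({len(truths)}) differ in length")
    if len(calls) == 0:
        raise InputError("cannot build a contingency table from empty input")
    c = np.asarray(calls, dtype=bool)
    t = np.asarray(truths, dtype=bool)
    return ContingencyTable(
        tp=int(np.sum(c & t)),
        fp=int(np.sum(c & ~t)),
        fn=int(np.sum(~c & t)),
        tn=int(np.sum(~c & ~t)),
    )


def binary_auc_variance(sens: float, spec: float, n_pos: int, n_neg: int) -> float:
    """Variance of the single-operating-point AUC estimate.

    This is DeLong's nonparametric variance estimator specialised to binary
    scores (equivalently a Hanley-McNeil-type reduction): the positive-class
    placement values take two levels, (1+spec)/2 and spec/2, so their variance
    is sens(1-sens)/4, and symmetrically for the negatives.
    """
    return sens * (1.0 - sens) / (4.0 * n_pos) + spec * (1.0 - spec) / (4.0 * n_neg)


def compute_metrics(t: ContingencyTable, alpha: float = ALPHA) -> DiagnosticMetrics:
    """Sensitivity/specificity/PPV/NPV/accuracy/AUC from a 2x2 table.

    AUC is the trapezoidal area of the one-threshold ROC,
    (sensitivity + specificity)/2, with a normal-approximation CI from
    :func:`binary_auc_variance`. Any metric whose denominator is zero is
    reported as None and named in ``undefined`` rather than coerced to 0.
    """
    undefined: list[str] = []

    def ratio(num: int, den: int, name: str) -> float | None:
        if den == 0:
            undefined.append(name)
            return None
        return num / den

    sens = ratio(t.tp, t.n_positive, "sensitivity")
    spec = ratio(t.tn, t.n_negative, "specificity")
    ppv = ratio(t.tp, t.tp + t.fp, "ppv")
    npv = ratio(t.tn, t.tn + t.fn, "npv")
    acc = ratio(t.tp + t.tn, t.total, "accuracy")

    auc = auc_ci = None
    if sens is None or spec is None:
        undefined.append("auc")
    else:
        auc = (sens + spec) / 2.0
        z = sps.norm.ppf(1.0 - alpha / 2.0)
        half = z * math.sqrt(binary_auc_variance(sens, spec, t.n_positive, t.n_negative))
        auc_ci = (max(0.0, auc - half), min(1.0, auc + half))

    return DiagnosticMetrics(
        sensitivity=sens, specificity=spec, ppv=ppv, npv=npv, accuracy=acc,
        auc=auc, auc_ci=auc_ci, n=t.total, undefined=tuple(undefined),
    )


def compare_proportions(x1: int, n1: int, x2: int, n2: int,
                        metric_name: str = "proportion") -> GroupComparison:
    """Pearson chi-squared (1 df, no continuity correction) on two proportions.

    The 2x2 table is {(x1, n1-x1), (x2, n2-x2)}; the p-value is two-sided.
    A zero margin leaves the statistic undefined and is flagged.
    """
    for x, n in ((x1, n1), (x2, n2)):
        if not 0 <= x <= n:
            raise InputError(f"count x={x} outside [0, n={n}]")
    if n1 + n2 == 0:
        raise InputError("both groups are empty")
    table = np.array([[x1, n1 - x1], [x2, n2 - x2]], dtype=float)
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        return GroupComparison(metric_name, None, None, "pearson_chi2",
                               undefined=("statistic", "p_value"))
    chi2, p, _, _ = sps.chi2_contingency(table, correction=False)
    return GroupComparison(metric_name, float(chi2), float(p), "pearson_chi2")


def compare_auc_unpaired(m1: DiagnosticMetrics, t1: ContingencyTable,
                         m2: DiagnosticMetrics, t2: ContingencyTable) -> GroupComparison:
    """Unpaired z-test on two independent single-operating-point AUCs.

    z = (auc1 - auc2) / sqrt(var1 + var2) with per-group DeLong-type variances;
    used for across-group comparisons where per-patient paired scores are not
    available. Perfect separation in both groups (zero variance) is flagged.
    """
    if m1.auc is None or m2.auc is None:
        return GroupComparison("auc", None, None, "auc_z", undefined=("statistic", "p_value"))
    var = (binary_auc_variance(m1.sensitivity, m1.specificity, t1.n_positive, t1.n_negative)
           + binary_auc_variance(m2.sensitivity, m2.specificity, t2.n_positive, t2.n_negative))
    if var == 0.0:
        return GroupComparison("auc", None, None, "auc_z", undefined=("statistic", "p_value"))
    z = (m1.auc - m2.auc) / math.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    return GroupComparison("auc", float(z), float(p), "auc_z")


def roc_from_scores(scores: Sequence[float], labels: Sequence[bool | int]
                    ) -> tuple[list[tuple[float, float]], float | None]:
    """Empirical ROC curve and trapezoidal AUC from continuous scores.

    Equal scores are grouped into a single threshold. With a single class in
    ``labels`` the AUC is undefined (returned as None) and the curve is empty.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape or s.ndim != 1:
        raise InputError("scores and labels must be 1-D and the same length")
    if y.all() or not y.any():
        return [], None
    fpr, tpr, _ = _sk_roc_curve(y.astype(int), s, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return list(zip(fpr.tolist(), tpr.tolist())), auc


def _read_packaged(name: str) -> pd.DataFrame:
    with resources.files("fedlnm.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh, dtype=str)


def load_packaged_contingency() -> dict[str, ContingencyTable]:
    """The seven imaging groups' packaged TP/FP/FN/TN counts, keyed by group name."""
    df = _read_packaged("imaging_contingency.csv")
    return {
        row.group: ContingencyTable(int(row.tp), int(row.fp), int(row.fn), int(row.tn))
        for row in df.itertuples(index=False)
    }


def load_published_metrics() -> pd.DataFrame:
    """Published point metrics as printed (strings, to preserve printed precision)."""
    return _read_packaged("imaging_published_metrics.csv")
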