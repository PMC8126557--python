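"""Threshold pre-classifier for amplifier constructors.

Within a census slice of fixed order and degree, a graph is predicted to be
an amplifier constructor if its maximal remeeting time is at least the
smallest ``max(tau_i)`` observed among true constructors AND its spectral
gap is at most the largest ``lambda_2`` among them.  Both comparisons are
inclusive, so every true constructor is predicted positive (recall is 100%
by construction) and the interesting performance figures are the precision
PRE = TP/(TP+FP) and the accuracy ACC = (TP+TN)/total, reported in percent.
The classifier is descriptive: it is fit and scored on the full census
slice, without a train/test split.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["ClassifierReport", "fit_and_score"]


@dataclass
class ClassifierReport:
    order: int
    degree: int
    tau_threshold: float
    lambda_threshold: float
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def precision(self) -> float:
        """PRE = TP/(TP+FP) in percent."""
        return 100.0 * self.tp / (self.tp + self.fp)

    @property
    def accuracy(self) -> float:
        """ACC = (TP+TN)/total in percent."""
        return 100.0 * (self.tp + self.tn) / self.total

    def to_dict(self) -> dict:
        return {
            "order": self.order,
            "degree": self.degree,
            "tau_threshold": self.tau_threshold,
            "lambda_threshold": self.lambda_threshold,
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "precision_percent": self.precision,
            "accuracy_percent": self.accuracy,
        }


def fit_and_score(records: pd.DataFrame) -> ClassifierReport:
    """Fit the max(tau)/lambda_2 thresholds on one census slice and score it.

    ``records`` needs columns ``n``, ``k``, ``max_tau``, ``lambda2`` and the
    boolean label ``is_constructor``; all rows must share the same (n, k).
    """
    if records.empty:
        raise ValueError("empty census slice: thresholds undefined")
    if records["n"].nunique() != 1 or records["k"].nunique() != 1:
        raise ValueError("classifier must be fit on a single (order, degree) slice")
    labels = records["is_constructor"].astype(bool)
    if not labels.any():
        raise ValueError("no amplifier constructors in slice: thresholds undefined")

    constructors = records[labels]
    tau_thr = float(constructors["max_tau"].min())
    lam_thr = float(constructors["lambda2"].max())
    predicted = (records["max_tau"] >= tau_thr) & (records["lambda2"] <= lam_thr)

    tp = int((predicted & labels).sum())
    fp = int((predicted & ~labels).sum())
    tn = int((~predicted & ~labels).sum())
    fn = int((~predicted & labels).sum())
    return ClassifierReport(
        order=int(records["n"].iloc[0]),
        degree=int(records["k"].iloc[0]),
        tau_threshold=tau_thr,
        lambda_threshold=lam_thr,
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
    )
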