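"""Segment-level classification metrics: confusion counts, derived rates,
and the rank-based (Mann-Whitney) ROC AUC. Ictal is the positive class."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata


@dataclass
class MetricReport:
    """Confusion counts and derived fractions for one evaluation.

    Metrics whose denominator is empty (single-class label vectors) are
    reported as NaN with the corresponding ``defined_*`` flag false — never
    silently as 0.
    """

    tp: int
    tn: int
    fp: int
    fn: int
    acc: float
    sens: float
    spec: float
    f1: float
    auc: float = float("nan")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def defined_sens(self) -> bool:
        return self.tp + self.fn > 0

    @property
    def defined_spec(self) -> bool:
        return self.tn + self.fp > 0

    @property
    def defined_auc(self) -> bool:
        return not np.isnan(self.auc)

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "tn": self.tn, "fp": self.fp, "fn": self.fn,
            "acc": self.acc, "sens": self.sens, "spec": self.spec,
            "f1": self.f1, "auc": self.auc,
        }


def confusion_metrics(labels, predictions) -> MetricReport:
    """Accuracy, sensitivity, specificity and F1 from binary labels/preds."""
    y = np.asarray(labels, dtype=int)
    p = np.asarray(predictions, dtype=int)
    if y.shape != p.shape or y.ndim != 1:
        raise ValueError("labels and predictions must be equal-length vectors")
    tp = int(((y == 1) & (p == 1)).sum())
    tn = int(((y == 0) & (p == 0)).sum())
    fp = int(((y == 0) & (p == 1)).sum())
    fn = int(((y == 1) & (p == 0)).sum())
    total = tp + tn + fp + fn
    acc = (tp + tn) / total if total else float("nan")
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    prec = tp / (tp + fp) if tp + fp else float("nan")
    if np.isnan(prec) or np.isnan(sens) or prec + sens == 0:
        f1 = float("nan")
    else:
        f1 = 2 * prec * sens / (prec + sens)
    return MetricReport(tp, tn, fp, fn, acc, sens, spec, f1)


def auc(labels, positive_scores) -> float:
    """ROC AUC via the rank (Mann-Whitney) formulation; ties count 1/2.

    NaN if only one class is present.
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(positive_scores, dtype=float)
    if y.shape != s.shape or y.ndim != 1:
        raise ValueError("labels and scores must be equal-length vectors")
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        return float("nan")
    ranks = rankdata(s)  # average ranks: ties contribute 1/2
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def evaluate_scores(labels, positive_scores, threshold: float = 0.5) -> MetricReport:
    """Full report from ictal-probability scores alone (prediction =
    score > threshold). For two-unit sigmoid outputs prefer
    ``evaluate_probs``, which uses the model's argmax decision rule."""
    s = np.asarray(positive_scores, dtype=float)
    rep = confusion_metrics(labels, (s > threshold).astype(int))
    rep.auc = auc(labels, s)
    return rep


def evaluate_probs(labels, probs) -> MetricReport:
    """Full report from per-class probabilities ``(n, 2)``: predictions by
    argmax (a tie resolves to interictal), AUC from the ictal probability."""
    p = np.asarray(probs, dtype=float)
    if p.ndim != 2 or p.shape[1] != 2:
        raise ValueError("probs must be (n, 2)")
    rep = confusion_metrics(labels, np.argmax(p, axis=1))
    rep.auc = auc(labels, p[:, 1])
    return rep


def metrics_table(
    reports: list[MetricReport], cases: list[str], percent: bool = True
) -> pd.DataFrame:
    """Per-case rows plus a mean row; percentages rounded to two decimals."""
    if len(reports) != len(cases):
        raise ValueError("one case name per report")
    cols = ("acc", "sens", "spec", "f1", "auc")
    rows = []
    for case, rep in zip(cases, reports):
        d = rep.as_dict()
        rows.append({"case": case, **{c: d[c] for c in cols}})
    df = pd.DataFrame(rows)
    mean = df[list(cols)].mean(skipna=True)
    df.loc[len(df)] = {"case": "Mean", **mean.to_dict()}
    if percent:
        df[list(cols)] = (df[list(cols)] * 100).round(2)
    return df


def table_to_markdown(df: pd.DataFrame) -> str:
    header = "| " + " | ".join(df.columns) + " |"
    sep = "|" + "---|" * len(df.columns)
    lines = [header, sep]
    for _, row in df.iterrows():
        lines.append(
            "| " + " | ".join(
                f"{v:.2f}" if isinstance(v, float) else str(v) for v in row
            ) + " |"
        )
    return "\n".join(lines)
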