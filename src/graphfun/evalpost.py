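"""Evaluation metrics and homology-based label diffusion.

Thresholded confusion metrics, ranking metrics (AUC by the tie-corrected
Mann-Whitney statistic, AUPR by precision-recall step integration),
protein-centric Fmax on the CAFA 0.01 threshold grid, multi-label Jaccard,
and a one-step convex label-diffusion update over bitscore-weighted
sequence homologs.

Undefined ratios (empty denominators) are reported as NaN and listed in the
report's ``undefined`` set, never silently as zero.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score


@dataclass
class MetricsReport:
    rec: float = math.nan
    pre: float = math.nan
    acc: float = math.nan
    f1: float = math.nan
    mcc: float = math.nan
    auc: float = math.nan
    aupr: float = math.nan
    fmax: float = math.nan
    jaccard: float = math.nan
    threshold: float = 0.5
    undefined: set = field(default_factory=set)

    def to_json(self, path=None) -> str:
        payload = {
            k: (None if isinstance(v, float) and math.isnan(v) else v)
            for k, v in self.__dict__.items()
            if k != "undefined"
        }
        payload["undefined"] = sorted(self.undefined)
        text = json.dumps(payload, indent=1)
        if path is not None:
            from pathlib import Path

            Path(path).write_text(text)
        return text


def confusion_metrics(scores, labels, threshold: float = 0.5) -> MetricsReport:
    """Recall, precision, accuracy, F1 and MCC from the thresholded confusion
    table (prediction positive when score >= threshold)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.size == 0:
        raise ValueError("empty input")
    if scores.shape != labels.shape:
        raise ValueError("scores and labels differ in length")
    pred = scores >= threshold
    pos = labels == 1
    tp = int(np.sum(pred & pos))
    fp = int(np.sum(pred & ~pos))
    fn = int(np.sum(~pred & pos))
    tn = int(np.sum(~pred & ~pos))
    rep = MetricsReport(threshold=threshold)
    rep.acc = (tp + tn) / (tp + tn + fp + fn)
    if tp + fn:
        rep.rec = tp / (tp + fn)
    else:
        rep.undefined.add("rec")
    if tp + fp:
        rep.pre = tp / (tp + fp)
    else:
        rep.undefined.add("pre")
    if not math.isnan(rep.rec) and not math.isnan(rep.pre) and (rep.rec + rep.pre) > 0:
        rep.f1 = 2 * rep.pre * rep.rec / (rep.pre + rep.rec)
    elif tp + fp and tp + fn:
        rep.f1 = 0.0
    else:
        rep.undefined.add("f1")
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if denom > 0:
        rep.mcc = (tp * tn - fp * fn) / denom
    else:
        rep.undefined.add("mcc")
    return rep


def rank_metrics(scores, labels):
    """(AUC, AUPR); requires both classes present."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("rank metrics need both classes present")
    return float(roc_auc_score(labels, scores)), float(average_precision_score(labels, scores))


FMAX_GRID = np.round(np.arange(0.0, 1.01, 0.01), 2)


def fmax(score_matrix, label_matrix):
    """Protein-centric maximum F-measure over the CAFA threshold grid.

    At each threshold t, precision is averaged over proteins with at least one
    prediction >= t and recall over all proteins with annotations; Fmax is the
    maximum harmonic mean.  Returns (fmax, argmax threshold).
    """
    S = np.asarray(score_matrix, dtype=float)
    Y = np.asarray(label_matrix, dtype=int)
    if S.shape != Y.shape:
        raise ValueError("score and label matrices differ in shape")
    annotated = Y.sum(axis=1) > 0
    if not annotated.any():
        raise ValueError("no annotated proteins")
    best, best_t = 0.0, 0.0
    for t in FMAX_GRID:
        pred = S >= t
        has_pred = pred.sum(axis=1) > 0
        if has_pred.any():
            tp = (pred & (Y == 1)).sum(axis=1)
            prec = np.mean(tp[has_pred] / pred.sum(axis=1)[has_pred])
        else:
            prec = 0.0
        tp_all = (pred & (Y == 1)).sum(axis=1)
        rec = np.mean(tp_all[annotated] / Y.sum(axis=1)[annotated])
        if prec + rec > 0:
            f = 2 * prec * rec / (prec + rec)
            if f > best:
                best, best_t = float(f), float(t)
    return best, best_t


def jaccard_multi(score_matrix, label_matrix, threshold: float = 0.5) -> float:
    """Mean per-protein Jaccard index between thresholded predicted label sets
    and true label sets; empty-vs-empty counts as 1."""
    S = np.asarray(score_matrix, dtype=float)
    Y = np.asarray(label_matrix, dtype=int)
    pred = S >= threshold
    true = Y == 1
    inter = (pred & true).sum(axis=1).astype(float)
    union = (pred | true).sum(axis=1).astype(float)
    per = np.where(union > 0, inter / np.where(union > 0, union, 1.0), 1.0)
    return float(per.mean())


def read_hits_table(path) -> pd.DataFrame:
    """Tab-separated homology hits (query id, hit id, bitscore)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["query", "hit", "bitscore"])
    if (df["bitscore"] < 0).any():
        raise ValueError("negative bitscore in hits table")
    return df


def label_diffusion(pred: dict, hits: pd.DataFrame, neighbor_labels: dict,
                    lam: float = 0.5, iterations: int = 1) -> dict:
    """Convex homology diffusion of protein label scores.

    Each step applies ``y' = lam * y + (1 - lam) * sum_h w_h * label_h`` with
    bitscore-normalised weights over the query's hits; queries without usable
    hits pass through unchanged.  Self-hits are ignored.  The neighbour
    labels are fixed, so the update is applied ``iterations`` times (default
    1) to the query scores only.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must lie in [0, 1]")
    if iterations < 1:
        raise ValueError("need at least one iteration")
    if (hits["bitscore"] < 0).any():
        raise ValueError("negative bitscore")
    out = {}
    grouped = dict(tuple(hits.groupby("query"))) if len(hits) else {}
    for qid, y in pred.items():
        y = np.asarray(y, dtype=float)
        if y.min() < 0 or y.max() > 1:
            raise ValueError(f"{qid}: scores outside [0, 1]")
        rows = grouped.get(qid)
        if rows is not None:
            rows = rows[rows["hit"] != qid]
            rows = rows[rows["hit"].isin(neighbor_labels)]
        if rows is None or len(rows) == 0 or rows["bitscore"].sum() == 0:
            out[qid] = y.copy()
            continue
        w = rows["bitscore"].to_numpy(float)
        w = w / w.sum()
        agg = np.zeros_like(y)
        for weight, hid in zip(w, rows["hit"]):
            agg += weight * np.asarray(neighbor_labels[hid], dtype=float)
        for _ in range(iterations):
            y = lam * y + (1.0 - lam) * agg
        out[qid] = np.clip(y, 0.0, 1.0)
    return out


def full_report(scores, labels, threshold: float = 0.5) -> MetricsReport:
    """Confusion + ranking metrics for one binary residue-level task."""
    rep = confusion_metrics(scores, labels, threshold)
    try:
        rep.auc, rep.aupr = rank_metrics(scores, labels)
    except ValueError:
        rep.undefined.update({"auc", "aupr"})
    return rep
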