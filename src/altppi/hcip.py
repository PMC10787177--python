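"""High-confidence interactor (HCIP) classification.

A two-class Gaussian Naive Bayes model separates genuine bait-prey
interactions from background identifications. Pairs present in a reference
interaction list are the positive class; everything else scored is negative
(no third "wrong identification" class). Training is cross-validated over
plate batches: each pair's posterior comes from a model that never saw its
plate. The network-inclusion threshold is then picked on the Jaccard /
precision / recall / F1 curves against the reference:

    J(A, B) = |A n B| / |A u B|
    precision = |A n B| / |A|
    recall = |A n B| / |B|
    F1 = 2 * precision * recall / (precision + recall)

where A is the predicted pair set at a threshold and B the reference set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.naive_bayes import GaussianNB

from altppi.compass import FEATURE_COLUMNS

Pair = frozenset


def normalize_pairs(edges) -> set[frozenset]:
    """Order-free pair identities, self-pairs dropped."""
    out = set()
    for a, b in edges:
        if a != b:
            out.add(frozenset((a, b)))
    return out


def train_classifier(
    features: pd.DataFrame,
    reference: set[frozenset],
    feature_columns: list[str] | None = None,
) -> pd.DataFrame:
    """Plate-batch cross-validated Naive Bayes posteriors for every pair.

    Returns the features frame with added ``label`` (pair in reference) and
    ``posterior`` columns. Each plate's pairs are scored by a model trained on
    all other plates; a training split lacking one of the two classes falls
    back to training on all pairs, with a warning.
    """
    if not reference:
        raise ValueError("empty reference interaction list")
    cols = feature_columns or FEATURE_COLUMNS
    plates = sorted(features["plate_id"].unique())
    if len(plates) < 2:
        raise ValueError("plate-batch cross-validation needs at least two plates")
    df = features.copy()
    df["pair"] = [frozenset((b, p)) for b, p in zip(df["bait_id"], df["prey"])]
    df["label"] = df["pair"].isin(reference)

    X = df[cols].to_numpy(dtype=float)
    y = df["label"].to_numpy()
    posterior = np.empty(len(df), dtype=float)
    for plate in plates:
        test = (df["plate_id"] == plate).to_numpy()
        train = ~test
        if len(np.unique(y[train])) < 2:
            warnings.warn(f"training split for plate {plate} lacks a class; using all pairs")
            train = np.ones(len(df), dtype=bool)
        model = GaussianNB(var_smoothing=1e-9)
        model.fit(X[train], y[train])
        pos_col = int(np.flatnonzero(model.classes_)[0]) if True in model.classes_ else None
        if pos_col is None:
            posterior[test] = 0.0
        else:
            posterior[test] = model.predict_proba(X[test])[:, pos_col]
    df["posterior"] = posterior
    return df.drop(columns=["pair"])


@dataclass
class ThresholdMetrics:
    threshold: float
    n_predicted: int
    jaccard: float
    precision: float
    recall: float
    f1: float


def _metrics_at(a: set[frozenset], b: set[frozenset], t: float) -> ThresholdMetrics:
    inter = len(a & b)
    union = len(a | b)
    jac = inter / union if union else 0.0
    prec = inter / len(a) if a else 0.0
    rec = inter / len(b) if b else 0.0
    f1 = 2 * prec * rec / (prec + rec) if (prec + rec) > 0 else 0.0
    return ThresholdMetrics(t, len(a), jac, prec, rec, f1)


def threshold_metrics(
    posteriors: pd.DataFrame,
    reference: set[frozenset],
    grid: list[float] | None = None,
) -> list[ThresholdMetrics]:
    """Jaccard/precision/recall/F1 of the predicted pair set at each threshold.

    The default grid is 200 evenly spaced points in [0, 1] plus every observed
    posterior, so the empirical argmax is exact.
    """
    if not reference:
        raise ValueError("empty reference interaction list")
    if grid is None:
        grid = sorted(set(np.linspace(0.0, 1.0, 200)) | set(posteriors["posterior"]))
    if any(t < 0 or t > 1 for t in grid):
        raise ValueError("thresholds must lie in [0, 1]")
    pairs = np.array([frozenset((b, p)) for b, p in zip(posteriors["bait_id"], posteriors["prey"])], dtype=object)
    post = posteriors["posterior"].to_numpy()
    out = []
    for t in grid:
        a = set(pairs[post >= t])
        out.append(_metrics_at(a, reference, float(t)))
    return out


def select_threshold(metrics: list[ThresholdMetrics], policy: str = "f1", recall_floor: float = 0.2) -> float:
    """Pick the network-inclusion threshold from the metric curves.

    Policies: ``f1`` (default, argmax F1), ``jaccard`` (argmax J) and
    ``precision_at_recall`` (max precision subject to recall >= floor). Ties
    break toward the smaller threshold (higher recall).
    """
    if not metrics:
        raise ValueError("no metrics to select from")
    ms = sorted(metrics, key=lambda m: m.threshold)
    if policy == "f1":
        key = lambda m: m.f1
    elif policy == "jaccard":
        key = lambda m: m.jaccard
    elif policy == "precision_at_recall":
        eligible = [m for m in ms if m.recall >= recall_floor]
        if not eligible:
            warnings.warn("no threshold satisfies the recall floor; ignoring it")
            eligible = ms
        ms, key = eligible, (lambda m: m.precision)
    else:
        raise ValueError(f"unknown policy {policy!r}")
    values = [key(m) for m in ms]
    best = max(values)
    if all(v == best for v in values) and len(values) > 1:
        warnings.warn("all thresholds score equally; returning the smallest")
    return ms[int(np.argmax(values))].threshold


def classify(posteriors: pd.DataFrame, threshold: float) -> tuple[pd.DataFrame, list[str]]:
    """Flag HCIP pairs at the threshold; list baits left with no HCIP."""
    df = posteriors.copy()
    df["hcip"] = df["posterior"] >= threshold
    with_hcip = set(df.loc[df["hcip"], "bait_id"])
    dropped = sorted(set(df["bait_id"]) - with_hcip)
    return df, dropped


def metrics_frame(metrics: list[ThresholdMetrics]) -> pd.DataFrame:
    return pd.DataFrame([m.__dict__ for m in metrics])
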