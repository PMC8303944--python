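"""Chilling-injury severity grading and evaluation.

Fruit are graded sound / moderate / severe: moderate shows flesh granulation,
severe adds water soaking.  Each fruit carries radial-profile descriptors
(and optionally fitted optical properties) at up to four acquisition
positions — 1, 2 on the equator and 3, 4 at the stylar end, where injury
develops first.  Features are aggregated per region (se, eq) or whole fruit
(wf), classified with the same discriminant engine as the phantom
pre-classification, and evaluated with per-class true-positive rates and
precision / recall / F1 for the severe class, using balanced subsampling to
cope with the heavily imbalanced cohorts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .diffusion import OpticalProperties
from .errors import AggregationError, InvalidInputError, SamplingError, VocabularyError
from .fda import FDAModel, fit_fda
from .profiles import LBIParameters

SEVERITY_LEVELS = ("sound", "moderate", "severe")

AGGREGATION_POSITIONS = {"se": (3, 4), "eq": (1, 2), "wf": (1, 2, 3, 4)}


def validate_severity(label: str) -> str:
    if label not in SEVERITY_LEVELS:
        raise VocabularyError(
            f"severity must be one of {SEVERITY_LEVELS}, got {label!r}"
        )
    return label


@dataclass
class FruitRecord:
    """One fruit: per-position descriptors, optional optics, severity label."""

    sample_id: str
    lbi: dict[int, LBIParameters]
    severity: str
    optics: dict[int, OpticalProperties] = field(default_factory=dict)

    def __post_init__(self):
        validate_severity(self.severity)
        if not self.lbi:
            raise InvalidInputError("record needs at least one position")
        if not set(self.lbi) <= {1, 2, 3, 4}:
            raise InvalidInputError("positions must be within {1, 2, 3, 4}")


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def n(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass(frozen=True)
class Metrics:
    """Precision, recall, F1 for one positive class.

    ``degenerate`` flags a zero denominator (no predicted or no actual
    positives); the affected metric is reported as 0.
    """

    precision: float
    recall: float
    f1: float
    degenerate: bool = False


def aggregate_positions(record: FruitRecord, mode: str, use: str = "lbi") -> np.ndarray:
    """Mean feature vector over the positions of an aggregation mode.

    ``mode``: 'se' (stylar end, positions 3+4), 'eq' (equator, 1+2) or 'wf'
    (whole fruit, all four).  ``use``: 'lbi' for the five profile descriptors,
    'optics' for (mu_a, mu_s').
    """
    if mode not in AGGREGATION_POSITIONS:
        raise InvalidInputError(f"mode must be one of {tuple(AGGREGATION_POSITIONS)}")
    source = record.lbi if use == "lbi" else record.optics
    vecs = []
    for pos in AGGREGATION_POSITIONS[mode]:
        if pos not in source:
            raise AggregationError(
                f"position {pos} missing from sample {record.sample_id!r} for mode {mode!r}"
            )
        v = source[pos]
        vecs.append(v.as_array() if use == "lbi" else np.array([v.mu_a, v.mu_s_prime]))
    return np.mean(vecs, axis=0)


def cohort_features(records, mode: str, use: str = "lbi"):
    """Stacked feature matrix and label list for a list of records."""
    feats = np.vstack([aggregate_positions(r, mode, use) for r in records])
    labels = [r.severity for r in records]
    return feats, labels


# ---------------------------------------------------------------------------
# Balanced subsampling
# ---------------------------------------------------------------------------

def subsample_balanced(labels, n_sets: int, seed: int) -> list[np.ndarray]:
    """Index sets with all severe samples plus equally many sound and moderate.

    Sampling is without replacement within each set and fully reproducible
    from ``seed`` (one generator drives all sets).
    """
    labels = [validate_severity(l) for l in labels]
    idx = {c: np.flatnonzero(np.array(labels) == c) for c in SEVERITY_LEVELS}
    if any(len(v) == 0 for v in idx.values()):
        raise SamplingError("every severity class must be non-empty")
    n_sev = len(idx["severe"])
    for c in ("sound", "moderate"):
        if len(idx[c]) < n_sev:
            raise SamplingError(
                f"class {c!r} has {len(idx[c])} samples; cannot draw {n_sev} "
                "without replacement"
            )
    rng = np.random.default_rng(seed)
    sets = []
    for _ in range(n_sets):
        chosen = np.concatenate(
            [
                idx["severe"],
                rng.choice(idx["sound"], size=n_sev, replace=False),
                rng.choice(idx["moderate"], size=n_sev, replace=False),
            ]
        )
        sets.append(np.sort(chosen))
    return sets


def _largest_remainder(total: int, weights) -> list[int]:
    weights = np.asarray(weights, dtype=float)
    quota = total * weights / weights.sum()
    base = np.floor(quota).astype(int)
    rem = quota - base
    for i in np.argsort(rem)[::-1][: total - base.sum()]:
        base[i] += 1
    return base.tolist()


def pool_two_class(labels, ratio_sound_to_moderate: tuple[int, int], seed: int):
    """Pool sound+moderate as the negative class, subsampled to the severe count.

    The negative draw keeps the requested sound:moderate ratio, rounded by
    largest remainder so the parts sum exactly to the severe count.  Returns
    ``(binary_labels, indices)`` where ``binary_labels`` maps every input
    sample to 'severe' or 'not_severe' and ``indices`` is the balanced subset.
    """
    labels = [validate_severity(l) for l in labels]
    arr = np.array(labels)
    idx = {c: np.flatnonzero(arr == c) for c in SEVERITY_LEVELS}
    n_sev = len(idx["severe"])
    if n_sev == 0:
        raise SamplingError("no severe samples to balance against")
    n_sound, n_mod = _largest_remainder(n_sev, ratio_sound_to_moderate)
    if n_sound > len(idx["sound"]) or n_mod > len(idx["moderate"]):
        raise SamplingError(
            f"ratio {ratio_sound_to_moderate} needs {n_sound} sound and {n_mod} "
            f"moderate samples; only {len(idx['sound'])}/{len(idx['moderate'])} available"
        )
    rng = np.random.default_rng(seed)
    chosen = np.concatenate(
        [
            idx["severe"],
            rng.choice(idx["sound"], size=n_sound, replace=False),
            rng.choice(idx["moderate"], size=n_mod, replace=False),
        ]
    )
    binary = ["severe" if l == "severe" else "not_severe" for l in labels]
    return binary, np.sort(chosen)


# ---------------------------------------------------------------------------
# Modeling and evaluation
# ---------------------------------------------------------------------------

def fit_severity_model(features, labels, basis: str = "linear") -> FDAModel:
    """Severity classifier; same optimal-scoring engine as pre-classification."""
    return fit_fda(features, labels, basis=basis)


def confusion_and_metrics(y_true, y_pred, positive_class: str):
    """Confusion counts and precision/recall/F1 against one positive class."""
    if len(y_true) != len(y_pred):
        raise InvalidInputError("label lists must have equal length")
    vocab = set(y_true) | set(y_pred)
    if positive_class not in vocab:
        raise VocabularyError(f"positive class {positive_class!r} absent from labels")
    tp = fp = tn = fn = 0
    for t, p in zip(y_true, y_pred):
        if p == positive_class:
            tp += t == positive_class
            fp += t != positive_class
        else:
            fn += t == positive_class
            tn += t != positive_class
    counts = ConfusionCounts(TP=tp, FP=fp, TN=tn, FN=fn)
    degenerate = (tp + fp == 0) or (tp + fn == 0)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return counts, Metrics(precision=precision, recall=recall, f1=f1, degenerate=degenerate)


def per_class_tp_rate(y_true, y_pred) -> dict:
    """Per-class true-positive rate (recall of each class), in percent."""
    out = {}
    for c in sorted(set(y_true)):
        sel = [p for t, p in zip(y_true, y_pred) if t == c]
        out[c] = 100.0 * sum(p == c for p in sel) / len(sel)
    return out


def evaluate_report(y_true, y_pred, positive_class: str = "severe") -> dict:
    """JSON-ready evaluation: confusion counts, P/R/F1 and per-class TP rates."""
    counts, metrics = confusion_and_metrics(y_true, y_pred, positive_class)
    return {
        "positive_class": positive_class,
        "confusion": {"TP": counts.TP, "FP": counts.FP, "TN": counts.TN, "FN": counts.FN},
        "precision": metrics.precision,
        "recall": metrics.recall,
        "f1": metrics.f1,
        "degenerate": metrics.degenerate,
        "per_class_tp_rate": per_class_tp_rate(y_true, y_pred),
    }


def dump_report(report: dict, path) -> None:
    from pathlib import Path

    Path(path).write_text(json.dumps(report, indent=2))
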