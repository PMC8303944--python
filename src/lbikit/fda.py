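"""Flexible discriminant analysis by optimal scoring.

The pre-classification metamodel predicts a coarse class (a coefficient
range) of mu_a and mu_s' from the five radial-profile descriptors; the
predicted range then bounds the inverse diffusion-model fit.  The classifier
is flexible discriminant analysis in its optimal-scoring formulation:

1. encode the K class labels as an n x K indicator matrix Y;
2. ridge-regress Y on the (optionally basis-expanded, standardized) features;
3. solve the generalized symmetric eigenproblem  (Y'Yhat/n) theta =
   alpha^2 Dp theta  with Dp = diag(class proportions), keeping the up to
   K-1 directions with alpha^2 in (0, 1);
4. classify by the weighted squared distance to class centroids in score
   space, with per-direction weights 1/(alpha^2 (1 - alpha^2)) and a
   -2 log(prior) offset.

With the linear basis this reproduces classical linear discriminant analysis
decisions exactly; the degree-2 polynomial basis adds curvature in the small
five-dimensional feature space.  Features are standardized to zero mean and
unit variance using training statistics; a ridge term (default 1e-8)
stabilizes the strongly correlated radius descriptors.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.linalg

from .errors import DegenerateFitError, InvalidInputError
from .phantoms import CalibrationSet, ClassRange
from .profiles import LBIParameters

DEFAULT_RIDGE = 1e-8
_EIG_EPS = 1e-8


def _expand(x: np.ndarray, basis: str) -> np.ndarray:
    """Basis expansion of a standardized feature matrix."""
    if basis == "linear":
        return x
    if basis == "polynomial-2":
        n, p = x.shape
        cols = [x]
        for i in range(p):
            for j in range(i, p):
                cols.append((x[:, i] * x[:, j])[:, None])
        return np.hstack(cols)
    raise InvalidInputError(f"unknown basis {basis!r}")


@dataclass
class FDAModel:
    """A fitted optimal-scoring discriminant model."""

    basis: str
    class_labels: list
    feature_mean: np.ndarray
    feature_std: np.ndarray
    reg_coef: np.ndarray  # basis-space regression coefficients (p_basis x K)
    reg_intercept: np.ndarray  # (K,)
    scoring_matrix: np.ndarray  # theta, K x L
    eigenvalues: np.ndarray  # alpha^2 per retained direction
    centroids: np.ndarray  # K x L, class means in score space
    score_weights: np.ndarray  # L
    priors: np.ndarray  # K
    training_summary: dict = field(default_factory=dict)

    def scores(self, features: np.ndarray) -> np.ndarray:
        """Discriminant scores for raw feature rows (n x p -> n x L)."""
        x = np.atleast_2d(np.asarray(features, dtype=float))
        if not np.all(np.isfinite(x)):
            raise InvalidInputError("feature vector contains missing/non-finite values")
        x = (x - self.feature_mean) / self.feature_std
        h = _expand(x, self.basis)
        yhat = self.reg_intercept + h @ self.reg_coef
        return yhat @ self.scoring_matrix

    def predict(self, features: np.ndarray) -> list:
        """Predicted class label per row; centroid-distance ties go to the
        lower class index."""
        eta = self.scores(features)
        d2 = ((eta[:, None, :] - self.centroids[None, :, :]) ** 2 * self.score_weights).sum(
            axis=2
        )
        d2 = d2 - 2.0 * np.log(self.priors)
        # argmin picks the first (= lowest class index) on exact ties
        return [self.class_labels[i] for i in np.argmin(d2, axis=1)]

    def to_json(self, path=None) -> str:
        payload = {
            "basis": self.basis,
            "class_labels": list(self.class_labels),
            "feature_mean": self.feature_mean.tolist(),
            "feature_std": self.feature_std.tolist(),
            "reg_coef": self.reg_coef.tolist(),
            "reg_intercept": self.reg_intercept.tolist(),
            "scoring_matrix": self.scoring_matrix.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "centroids": self.centroids.tolist(),
            "score_weights": self.score_weights.tolist(),
            "priors": self.priors.tolist(),
            "training_summary": self.training_summary,
        }
        text = json.dumps(
            payload, indent=2,
            default=lambda o: o.item() if hasattr(o, "item") else str(o),
        )
        if path is not None:
            from pathlib import Path

            Path(path).write_text(text)
        return text


def _as_matrix(features) -> np.ndarray:
    if len(features) and isinstance(features[0], LBIParameters):
        return np.vstack([p.as_array() for p in features])
    return np.atleast_2d(np.asarray(features, dtype=float))


def fit_fda(
    features,
    labels: Sequence,
    basis: str = "linear",
    ridge: float = DEFAULT_RIDGE,
) -> FDAModel:
    """Fit the optimal-scoring discriminant model.

    ``features`` may be an (n x p) array or a sequence of
    :class:`~lbikit.profiles.LBIParameters`.  Requires at least two classes
    with at least two samples each.
    """
    x = _as_matrix(features)
    labels = list(labels)
    if len(labels) != x.shape[0]:
        raise InvalidInputError("features and labels must have equal length")
    if not np.all(np.isfinite(x)):
        raise InvalidInputError("features must be finite")
    class_labels, y_idx = np.unique(labels, return_inverse=True)
    counts = np.bincount(y_idx)
    if len(class_labels) < 2:
        raise InvalidInputError("need at least 2 classes")
    if counts.min() < 2:
        small = class_labels[np.argmin(counts)]
        raise InvalidInputError(f"class {small!r} has fewer than 2 samples")

    n, _ = x.shape
    k = len(class_labels)
    mean = x.mean(axis=0)
    std = x.std(axis=0, ddof=0)
    std[std == 0] = 1.0
    h = _expand((x - mean) / std, basis)

    y = np.zeros((n, k))
    y[np.arange(n), y_idx] = 1.0
    priors = counts / n

    hc = h - h.mean(axis=0)
    gram = hc.T @ hc + ridge * np.eye(h.shape[1])
    try:
        coef = np.linalg.solve(gram, hc.T @ y)
    except np.linalg.LinAlgError as exc:
        raise DegenerateFitError(
            "singular within-class structure; increase the ridge term"
        ) from exc
    intercept = y.mean(axis=0) - h.mean(axis=0) @ coef
    yhat = intercept + h @ coef

    m = y.T @ yhat / n
    m = 0.5 * (m + m.T)
    dp = np.diag(priors)
    alpha2, theta = scipy.linalg.eigh(m, dp)
    order = np.argsort(alpha2)[::-1]
    alpha2, theta = alpha2[order], theta[:, order]
    # drop the trivial constant-score direction (alpha^2 = 1): it is the only
    # eigenvector with a nonzero Dp-inner product with the ones vector
    trivial = int(np.argmax(np.abs(theta.T @ priors)))
    keep = np.ones(alpha2.size, dtype=bool)
    keep[trivial] = False
    keep &= alpha2 > _EIG_EPS
    alpha2, theta = alpha2[keep][: k - 1], theta[:, keep][:, : k - 1]
    if alpha2.size == 0:
        raise DegenerateFitError("no discriminant direction found (degenerate fit)")

    eta = yhat @ theta
    centroids = np.vstack([eta[y_idx == i].mean(axis=0) for i in range(k)])
    # Mahalanobis weighting: score dimensions are within-class uncorrelated, so
    # the inverse pooled within-class variance makes the centroid rule exactly
    # LDA in the canonical subspace (linear basis)
    resid = eta - centroids[y_idx]
    within = (resid**2).sum(axis=0) / max(n - k, 1)
    weights = 1.0 / np.maximum(within, 1e-30)

    return FDAModel(
        basis=basis,
        class_labels=list(class_labels),
        feature_mean=mean,
        feature_std=std,
        reg_coef=coef,
        reg_intercept=intercept,
        scoring_matrix=theta,
        eigenvalues=alpha2,
        centroids=centroids,
        score_weights=weights,
        priors=priors,
        training_summary={str(c): int(nc) for c, nc in zip(class_labels, counts)},
    )


def predict_class(model: FDAModel, features) -> list:
    """Predicted class label(s) for one or more feature rows."""
    x = _as_matrix([features] if isinstance(features, LBIParameters) else features)
    preds = model.predict(x)
    return preds[0] if isinstance(features, LBIParameters) or x.shape[0] == 1 else preds


def loocv(features, labels: Sequence, basis: str = "linear", ridge: float = DEFAULT_RIDGE):
    """Leave-one-out cross-validation.

    Returns ``(overall_pct, per_class_pct, skipped)`` where ``per_class_pct``
    maps class label to the percentage of its held-out samples predicted
    correctly and ``skipped`` lists fold indices that could not be evaluated
    (their class would vanish from the training set).
    """
    x = _as_matrix(features)
    labels = list(labels)
    n = len(labels)
    correct = {c: 0 for c in set(labels)}
    total = {c: 0 for c in set(labels)}
    skipped = []
    for i in range(n):
        rest = [j for j in range(n) if j != i]
        rest_labels = [labels[j] for j in rest]
        if rest_labels.count(labels[i]) < 2:
            warnings.warn(
                f"LOOCV fold {i}: class {labels[i]!r} has a single member; skipped"
            )
            skipped.append(i)
            continue
        # classes reduced to a lone training sample cannot be modeled; drop them
        usable = [j for j in rest if rest_labels.count(labels[j]) >= 2]
        rest, rest_labels = usable, [labels[j] for j in usable]
        model = fit_fda(x[rest], rest_labels, basis=basis, ridge=ridge)
        pred = model.predict(x[i: i + 1])[0]
        total[labels[i]] += 1
        if pred == labels[i]:
            correct[labels[i]] += 1
    per_class = {
        c: 100.0 * correct[c] / total[c] for c in sorted(total) if total[c] > 0
    }
    n_eval = sum(total.values())
    overall = 100.0 * sum(correct.values()) / n_eval if n_eval else float("nan")
    return overall, per_class, skipped


# ---------------------------------------------------------------------------
# Calibration glue
# ---------------------------------------------------------------------------

def calibrate_preclassifier(
    calibration: CalibrationSet, basis: str = "linear", ridge: float = DEFAULT_RIDGE
) -> CalibrationSet:
    """Fit the two axis models (mu_a class, mu_s' class) on the reference matrix
    and attach them to the calibration set (returned for chaining)."""
    feats = calibration.table[list(LBIParameters.FEATURE_NAMES)].to_numpy()
    calibration.fda_mu_a = fit_fda(feats, calibration.table["mu_a_class"], basis, ridge)
    calibration.fda_mu_s = fit_fda(feats, calibration.table["mu_s_class"], basis, ridge)
    return calibration


def preclassify_bounds(
    calibration: CalibrationSet, sample: LBIParameters
) -> tuple[ClassRange, ClassRange]:
    """Predict the (mu_a, mu_s') class ranges of a sample — the bound box for
    the constrained inversion."""
    if calibration.fda_mu_a is None or calibration.fda_mu_s is None:
        raise InvalidInputError(
            "calibration has no fitted pre-classifiers; run calibrate_preclassifier first"
        )
    a_label = predict_class(calibration.fda_mu_a, sample)
    s_label = predict_class(calibration.fda_mu_s, sample)
    a_range = next(c for c in calibration.mu_a_classes if c.label == a_label)
    s_range = next(c for c in calibration.mu_s_classes if c.label == s_label)
    return a_range, s_range
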