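"""Linear max-margin classification of supercells.

The classifier is a soft-margin support vector machine with a linear kernel
fitted on z-scored points; with a large margin cost on separable supercell
clouds it reduces to the classical perceptron picture: a single separating
hyperplane whose unit normal ("amplitudes") weighs each measurement's
contribution to class separation.  Signed Euclidean distances from the
hyperplane in standardized space are the working coordinate for everything
downstream: per-point classification, per-patient cloud fractions, and the
amplitude-based rank ordering of measurements.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .exceptions import DegenerateLabelsError, InsufficientCellsError, SchemaError
from .io import CellSample, Cohort
from .sampling import (
    SupercellConfig,
    build_supercells,
    stack_supercells,
    with_size,
)

__all__ = [
    "SupercellClassifier",
    "FeatureRanking",
    "AccuracyGrid",
    "train_linear",
    "boundary_distances",
    "rank_measurements",
    "accuracy_grid",
    "svd_project",
]


@dataclass
class FeatureRanking:
    """Measurements ordered by decreasing |amplitude| (ties: input order)."""

    ordered_measurements: list[str]
    abs_amplitudes: np.ndarray
    order: np.ndarray  # original column indices, same order

    def top(self, m: int) -> list[str]:
        return self.ordered_measurements[:m]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self.ordered_measurements) + 1),
                "measurement": self.ordered_measurements,
                "abs_amplitude": self.abs_amplitudes,
            }
        )


class SupercellClassifier(ClassifierMixin, BaseEstimator):
    """Max-margin linear boundary in z-scored measurement space.

    scikit-learn compatible estimator: ``fit(X, y)`` then
    ``decision_function`` / ``predict`` / ``score``; composes with sklearn
    pipelines and model selection.

    Parameters
    ----------
    positive_class : str or None
        Class mapped to the positive side of the boundary (positive signed
        distance).  Default: the first class encountered in ``y`` — at the
        cohort level, pass ``cohort.class_names[0]`` (e.g. "healthy").
    margin_cost : float
        Soft-margin cost C.  The default 1000 is effectively a hard margin
        on separable supercell clouds while still fitting overlapping
        single-cell input.
    standardize : bool
        z-score features on the training points (default).  Amplitudes are
        then comparable across measurements with different intensity scales
        and invariant to positive rescaling of any raw column.
    tol : float
        Optimizer stopping tolerance.

    Attributes
    ----------
    classes_ : ndarray of the two class names, ``[positive, negative]``.
    feature_names_in_ : ndarray of str (from a DataFrame, or ``x0..``).
    amplitudes_ : ndarray, unit normal of the boundary, one entry per input
        feature; exactly 0.0 for dropped zero-variance features.
    intercept_ : float, offset so that the signed distance of a standardized
        point z is ``z @ amplitudes_ + intercept_``.
    mean_, scale_ : standardization parameters (identity if
        ``standardize=False``); ``scale_`` is 1 for dropped features.
    dropped_features_ : list of zero-variance feature names removed
        before fitting.
    margin_ : float, geometric half-margin of the fitted boundary in
        standardized space (meaningful for separable input at large C).
    """

    def __init__(
        self,
        positive_class: str | None = None,
        margin_cost: float = 1000.0,
        standardize: bool = True,
        tol: float = 1e-6,
    ) -> None:
        self.positive_class = positive_class
        self.margin_cost = margin_cost
        self.standardize = standardize
        self.tol = tol

    # -- fitting ------------------------------------------------------------

    def fit(self, X, y, feature_names: Sequence[str] | None = None):
        if isinstance(X, pd.DataFrame):
            feature_names = list(X.columns.astype(str))
            X = X.to_numpy(dtype=float)
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y).astype(str)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise SchemaError("X must be 2-D with one label per row")
        if not np.isfinite(X).all():
            raise SchemaError("X contains non-finite values")
        if X.shape[1] < 1:
            raise SchemaError("need at least one measurement")
        uniq = list(dict.fromkeys(y))  # first-appearance order
        if len(uniq) != 2:
            raise DegenerateLabelsError(
                f"need exactly two classes, got {uniq}"
            )
        pos = self.positive_class if self.positive_class is not None else uniq[0]
        if pos not in uniq:
            raise DegenerateLabelsError(
                f"positive_class {pos!r} not among labels {uniq}"
            )
        neg = uniq[0] if uniq[1] == pos else uniq[1]

        if feature_names is None:
            feature_names = [f"x{j}" for j in range(X.shape[1])]
        self.feature_names_in_ = np.asarray(feature_names, dtype=object)
        self.n_features_in_ = X.shape[1]

        sd = X.std(axis=0, ddof=0)
        keep = sd > 0
        self.dropped_features_ = [
            str(n) for n, k in zip(feature_names, keep) if not k
        ]
        if not keep.any():
            raise DegenerateLabelsError("all measurements have zero variance")
        if self.dropped_features_:
            warnings.warn(
                f"dropping zero-variance measurements: {self.dropped_features_}",
                UserWarning,
                stacklevel=2,
            )
        if self.standardize:
            self.mean_ = X.mean(axis=0)
            self.scale_ = np.where(keep, sd, 1.0)
        else:
            self.mean_ = np.zeros(X.shape[1])
            self.scale_ = np.ones(X.shape[1])
        Z = (X[:, keep] - self.mean_[keep]) / self.scale_[keep]

        svm = SVC(kernel="linear", C=self.margin_cost, tol=self.tol)
        svm.fit(Z, y)
        w = svm.coef_[0].copy()
        b = float(svm.intercept_[0])
        # libsvm's positive decision side is its classes_[1]
        if str(svm.classes_[1]) != pos:
            w, b = -w, -b
        norm = float(np.linalg.norm(w))
        if norm == 0.0:
            raise DegenerateLabelsError("degenerate fit: zero normal vector")
        self.margin_ = 1.0 / norm
        amp = np.zeros(X.shape[1])
        amp[keep] = w / norm
        self.amplitudes_ = amp
        self.intercept_ = b / norm
        self.classes_ = np.asarray([pos, neg], dtype=object)
        return self

    # -- inference ----------------------------------------------------------

    def _check_X(self, X) -> np.ndarray:
        check_is_fitted(self, "amplitudes_")
        if isinstance(X, pd.DataFrame):
            cols = list(X.columns.astype(str))
            if cols != list(self.feature_names_in_):
                raise SchemaError(
                    f"measurement mismatch: fitted on "
                    f"{list(self.feature_names_in_)}, got {cols}"
                )
            X = X.to_numpy(dtype=float)
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_in_:
            raise SchemaError(
                f"expected {self.n_features_in_} measurements, got {X.shape[1]}"
            )
        return X

    def decision_function(self, X) -> np.ndarray:
        """Signed Euclidean distance from the boundary in standardized
        space; positive side corresponds to ``classes_[0]``."""
        X = self._check_X(X)
        Z = (X - self.mean_) / self.scale_
        return Z @ self.amplitudes_ + self.intercept_

    def predict(self, X) -> np.ndarray:
        d = self.decision_function(X)
        # points exactly on the boundary go to the positive class
        return np.where(d >= 0, self.classes_[0], self.classes_[1])

    # -- interpretation -----------------------------------------------------

    def rank_measurements(self) -> FeatureRanking:
        """Rank-order measurements by decreasing |amplitude| (stable ties)."""
        check_is_fitted(self, "amplitudes_")
        a = np.abs(self.amplitudes_)
        order = np.argsort(-a, kind="stable")
        return FeatureRanking(
            ordered_measurements=[str(self.feature_names_in_[j]) for j in order],
            abs_amplitudes=a[order],
            order=order,
        )


# ---------------------------------------------------------------------------
# Functional surface (thin wrappers over the estimator)


def train_linear(
    points,
    labels,
    positive_class: str | None = None,
    margin_cost: float = 1000.0,
    feature_names: Sequence[str] | None = None,
    standardize: bool = True,
) -> SupercellClassifier:
    """Fit the max-margin linear boundary; returns the fitted estimator."""
    clf = SupercellClassifier(
        positive_class=positive_class,
        margin_cost=margin_cost,
        standardize=standardize,
    )
    return clf.fit(points, labels, feature_names=feature_names)


def boundary_distances(boundary: SupercellClassifier, points) -> np.ndarray:
    """Signed distances of ``points`` from a fitted boundary."""
    return boundary.decision_function(points)


def rank_measurements(boundary: SupercellClassifier) -> FeatureRanking:
    return boundary.rank_measurements()


# ---------------------------------------------------------------------------
# Accuracy over the (N, M) grid


@dataclass
class AccuracyGrid:
    """Fraction of supercells correctly classified over sizes N x top-M."""

    n_values: list[int]
    m_values: list[int]
    accuracy: np.ndarray  # (len(n_values), len(m_values))
    evaluation: str  # "training" | "held_out"

    def at(self, n: int, m: int) -> float:
        return float(
            self.accuracy[self.n_values.index(n), self.m_values.index(m)]
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"n": n, "m": m, "accuracy": self.accuracy[i, j]}
            for i, n in enumerate(self.n_values)
            for j, m in enumerate(self.m_values)
        ]
        return pd.DataFrame(rows)


def _split_cells(
    sample: CellSample, seed: int
) -> tuple[CellSample, CellSample]:
    """Split one sample's cells in half (random, seeded per sample) so that
    no cell contributes to both fitting and evaluation supercells."""
    rng = np.random.default_rng(
        np.random.SeedSequence([seed, zlib.crc32(sample.sample_id.encode()), 0xC311])
    )
    perm = rng.permutation(sample.n_cells)
    half = sample.n_cells // 2
    if half < 1:
        raise InsufficientCellsError(
            f"sample {sample.sample_id!r}: too few cells to split"
        )
    mk = lambda tag, idx: CellSample(
        f"{sample.sample_id}::{tag}",
        sample.class_label,
        sample.measurement_names,
        sample.values[np.sort(idx)],
    )
    return mk("fit", perm[:half]), mk("eval", perm[half:])


def accuracy_grid(
    cohort: Cohort,
    n_values: Sequence[int],
    m_values: Sequence[int],
    config: SupercellConfig,
    evaluation: str = "held_out",
    margin_cost: float = 1000.0,
) -> AccuracyGrid:
    """Supercell classification accuracy for every (N, M) pair.

    For each supercell size N: build clouds, fit on all measurements, rank
    by |amplitude|, then for each M refit on the top-M measurements and
    report the fraction of evaluation supercells on the correct side.

    ``evaluation="held_out"`` (default) splits each sample's *cells* in half
    before any supercell is built, so no cell influences both the boundary
    and its evaluation; ``"training"`` evaluates on the fitting supercells
    themselves (the resubstitution protocol).
    """
    if evaluation not in ("training", "held_out"):
        raise ValueError("evaluation must be 'training' or 'held_out'")
    n_values = [int(n) for n in n_values]
    m_values = [int(m) for m in m_values]
    P = len(cohort.measurement_names)
    if not n_values or not m_values:
        raise ValueError("n_values and m_values must be non-empty")
    if max(m_values) > P:
        raise SchemaError(f"m={max(m_values)} exceeds {P} measurements")
    pos = cohort.class_names[0]
    acc = np.empty((len(n_values), len(m_values)))
    for i, n in enumerate(n_values):
        cfg = with_size(config, n)
        if evaluation == "held_out":
            fit_parts, eval_parts = zip(
                *(_split_cells(s, config.seed) for s in cohort)
            )
        else:
            fit_parts = eval_parts = tuple(cohort.samples)
        fit_clouds = [build_supercells(s, cfg) for s in fit_parts]
        X_fit, y_fit, _ = stack_supercells(fit_clouds)
        if evaluation == "held_out":
            eval_clouds = [build_supercells(s, cfg) for s in eval_parts]
            X_eval, y_eval, _ = stack_supercells(eval_clouds)
        else:
            X_eval, y_eval = X_fit, y_fit
        full = train_linear(
            X_fit, y_fit, pos, margin_cost,
            feature_names=cohort.measurement_names,
        )
        order = full.rank_measurements().order
        for j, m in enumerate(m_values):
            cols = order[:m]
            clf = train_linear(X_fit[:, cols], y_fit, pos, margin_cost)
            acc[i, j] = float(np.mean(clf.predict(X_eval[:, cols]) == y_eval))
    return AccuracyGrid(n_values, m_values, acc, evaluation)


# ---------------------------------------------------------------------------
# SVD baseline


def svd_project(points, components: int) -> np.ndarray:
    """Project mean-centered points onto their top singular directions.

    This is the unsupervised low-dimensional baseline: the leading
    variance directions are not chosen to separate classes, and on
    overlapping single-cell data a 2-component projection typically stays
    non-separable even when supercell classification succeeds.
    """
    X = np.atleast_2d(np.asarray(points, dtype=float))
    if components < 1 or components > X.shape[1]:
        raise ValueError(
            f"components must be in [1, {X.shape[1]}], got {components}"
        )
    Xc = X - X.mean(axis=0)
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    scores = U * s
    if scores.shape[1] < components:  # rank-deficient: pad exact zeros
        pad = np.zeros((X.shape[0], components - scores.shape[1]))
        return np.hstack([scores, pad])
    return scores[:, :components]
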