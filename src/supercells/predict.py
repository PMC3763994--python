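"""Leave-one-patient-out diagnosis with an abstention band.

Each held-out patient is represented by its cloud of K supercells.  A
boundary fitted on the remaining patients' supercells splits the cloud; the
patient is called for a class only when at least a threshold fraction theta
(default 95%) of the cloud falls on that class's side, and is otherwise left
*unclassified*.  Cohort-level results are reported as percentages of
patients correctly classified / unclassified / incorrectly classified, as a
function of the number M of top-ranked measurements used.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .classify import train_linear
from .exceptions import DegenerateFoldError
from .io import Cohort
from .sampling import (
    SupercellConfig,
    build_supercells,
    stack_supercells,
    with_size,
)

__all__ = [
    "UNCLASSIFIED",
    "JackknifeConfig",
    "PatientPrediction",
    "JackknifeSummary",
    "ThresholdSweepResult",
    "jackknife_predict",
    "minimal_measures",
    "minimal_supercell_size",
    "threshold_sweep",
]

UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class JackknifeConfig:
    """Settings for the leave-one-patient-out run.

    ``threshold_theta`` must exceed 0.5 so at most one class can claim a
    cloud; the comparison is ``>=`` (a cloud at exactly the threshold is
    classified).  ``ranking_scope="per_fold"`` (default) re-ranks
    measurements within each training fold so nothing about the held-out
    patient leaks into the ranking; ``"global"`` uses one cohort-wide
    ranking for every fold.
    """

    supercell: SupercellConfig
    threshold_theta: float = 0.95
    m_values: Sequence[int] | None = None  # default: 1..n_measurements
    ranking_scope: str = "per_fold"
    margin_cost: float = 1000.0

    def __post_init__(self) -> None:
        if not 0.5 < self.threshold_theta <= 1.0:
            raise ValueError("threshold_theta must be in (0.5, 1]")
        if self.ranking_scope not in ("per_fold", "global"):
            raise ValueError("ranking_scope must be 'per_fold' or 'global'")


@dataclass
class PatientPrediction:
    sample_id: str
    true_class: str
    m: int
    fraction_positive_side: float
    call: str  # one of the two classes, or UNCLASSIFIED

    @property
    def outcome(self) -> str:
        if self.call == UNCLASSIFIED:
            return "unclassified"
        return "correct" if self.call == self.true_class else "incorrect"


@dataclass
class JackknifeSummary:
    """Cohort percentages per M, plus every per-patient call."""

    m_values: list[int]
    percent_correct: np.ndarray
    percent_unclassified: np.ndarray
    percent_incorrect: np.ndarray
    predictions: list[PatientPrediction]
    threshold_theta: float
    class_names: tuple[str, str]

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "m": self.m_values,
                "percent_correct": self.percent_correct,
                "percent_unclassified": self.percent_unclassified,
                "percent_incorrect": self.percent_incorrect,
            }
        )

    def predictions_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "sample_id": p.sample_id,
                    "true_class": p.true_class,
                    "m": p.m,
                    "fraction_positive_side": p.fraction_positive_side,
                    "call": p.call,
                    "outcome": p.outcome,
                }
                for p in self.predictions
            ]
        )

    def to_dict(self) -> dict:
        return {
            "threshold_theta": self.threshold_theta,
            "class_names": list(self.class_names),
            "summary": self.summary_frame().to_dict(orient="records"),
            "predictions": self.predictions_frame().to_dict(orient="records"),
        }

    def at(self, m: int) -> dict[str, float]:
        i = self.m_values.index(m)
        return {
            "correct": float(self.percent_correct[i]),
            "unclassified": float(self.percent_unclassified[i]),
            "incorrect": float(self.percent_incorrect[i]),
        }


# ---------------------------------------------------------------------------


def _cloud_fractions(
    cohort: Cohort, config: JackknifeConfig
) -> list[tuple[str, str, int, float]]:
    """Core jackknife loop, independent of theta.

    Returns (sample_id, true_class, m, fraction_positive_side) for every
    held-out patient and every M.  The same K test supercells are reused
    across M within a fold, so M-curves differ only by measurement set.
    """
    pos = cohort.class_names[0]
    P = len(cohort.measurement_names)
    m_values = list(config.m_values) if config.m_values is not None else list(
        range(1, P + 1)
    )
    if min(m_values) < 1 or max(m_values) > P:
        raise ValueError(f"m_values must lie in [1, {P}]")
    clouds = {s.sample_id: build_supercells(s, config.supercell) for s in cohort}

    global_order = None
    if config.ranking_scope == "global":
        X_all, y_all, _ = stack_supercells(list(clouds.values()))
        full = train_linear(
            X_all, y_all, pos, config.margin_cost,
            feature_names=cohort.measurement_names,
        )
        global_order = full.rank_measurements().order

    out: list[tuple[str, str, int, float]] = []
    for held in cohort:
        train_clouds = [c for sid, c in clouds.items() if sid != held.sample_id]
        y_check = {c.class_label for c in train_clouds}
        if len(y_check) < 2:
            raise DegenerateFoldError(
                f"leaving out {held.sample_id!r} removes class "
                f"{held.class_label!r} from the training fold"
            )
        X_tr, y_tr, _ = stack_supercells(train_clouds)
        if global_order is not None:
            order = global_order
        else:
            full = train_linear(
                X_tr, y_tr, pos, config.margin_cost,
                feature_names=cohort.measurement_names,
            )
            order = full.rank_measurements().order
        X_te = clouds[held.sample_id].values
        for m in m_values:
            cols = order[:m]
            clf = train_linear(X_tr[:, cols], y_tr, pos, config.margin_cost)
            d = clf.decision_function(X_te[:, cols])
            frac_pos = float(np.mean(d >= 0))
            out.append((held.sample_id, held.class_label, m, frac_pos))
    return out


def _call(frac_pos: float, theta: float, class_names: tuple[str, str]) -> str:
    if frac_pos >= theta:
        return class_names[0]
    if (1.0 - frac_pos) >= theta:
        return class_names[1]
    return UNCLASSIFIED


def _summarize(
    fractions: list[tuple[str, str, int, float]],
    theta: float,
    class_names: tuple[str, str],
) -> JackknifeSummary:
    m_values = sorted({m for _, _, m, _ in fractions})
    preds = [
        PatientPrediction(sid, truth, m, f, _call(f, theta, class_names))
        for sid, truth, m, f in fractions
    ]
    n_patients = len({p.sample_id for p in preds})
    pc, pu, pi = [], [], []
    for m in m_values:
        sub = [p for p in preds if p.m == m]
        pc.append(100.0 * sum(p.outcome == "correct" for p in sub) / n_patients)
        pu.append(100.0 * sum(p.outcome == "unclassified" for p in sub) / n_patients)
        pi.append(100.0 * sum(p.outcome == "incorrect" for p in sub) / n_patients)
    return JackknifeSummary(
        m_values=m_values,
        percent_correct=np.asarray(pc),
        percent_unclassified=np.asarray(pu),
        percent_incorrect=np.asarray(pi),
        predictions=preds,
        threshold_theta=theta,
        class_names=class_names,
    )


def jackknife_predict(cohort: Cohort, config: JackknifeConfig) -> JackknifeSummary:
    """Leave-one-patient-out prediction over the configured M values.

    Requires at least two patients per class so every training fold retains
    both classes.  Deterministic given the supercell seed.
    """
    fractions = _cloud_fractions(cohort, config)
    return _summarize(fractions, config.threshold_theta, cohort.class_names)


def minimal_measures(
    cohort: Cohort,
    config: JackknifeConfig,
    criterion: str = "zero_incorrect",
) -> int | None:
    """Smallest M whose jackknife outcome meets ``criterion``.

    ``zero_incorrect``: no patient incorrectly classified;
    ``zero_incorrect_and_unclassified``: additionally every patient called.
    Returns ``None`` when no M in range achieves it (not an exception: an
    unattainable criterion is a result, not an error).
    """
    if criterion not in ("zero_incorrect", "zero_incorrect_and_unclassified"):
        raise ValueError(f"unknown criterion {criterion!r}")
    summary = jackknife_predict(cohort, config)
    for i, m in enumerate(summary.m_values):
        ok = summary.percent_incorrect[i] == 0.0
        if criterion == "zero_incorrect_and_unclassified":
            ok = ok and summary.percent_unclassified[i] == 0.0
        if ok:
            return int(m)
    return None


def minimal_supercell_size(
    cohort: Cohort,
    config: SupercellConfig,
    m: int,
    n_candidates: Sequence[int],
    accuracy_floor: float = 0.95,
    evaluation: str = "training",
    margin_cost: float = 1000.0,
) -> int | None:
    """Smallest supercell size N whose top-``m`` classification accuracy
    reaches ``accuracy_floor`` (e.g. 1.0 for full class separation).

    ``n_candidates`` must be sorted ascending.  Returns ``None`` if no
    candidate reaches the floor.
    """
    from .classify import accuracy_grid  # local import avoids cycle at module load

    n_candidates = [int(n) for n in n_candidates]
    if n_candidates != sorted(n_candidates):
        raise ValueError("n_candidates must be sorted ascending")
    for n in n_candidates:
        grid = accuracy_grid(
            cohort, [n], [m], with_size(config, n),
            evaluation=evaluation, margin_cost=margin_cost,
        )
        if grid.accuracy[0, 0] >= accuracy_floor:
            return n
    return None


@dataclass
class ThresholdSweepResult:
    """Jackknife summaries across prediction thresholds, plus the largest
    change of each outcome percentage over any pair of thresholds."""

    thetas: list[float]
    summaries: dict[float, JackknifeSummary]
    max_variation: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for t in self.thetas:
            df = self.summaries[t].summary_frame()
            df.insert(0, "theta", t)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)


def threshold_sweep(
    cohort: Cohort,
    config: JackknifeConfig,
    thetas: Sequence[float],
) -> ThresholdSweepResult:
    """Re-call the same jackknife clouds at each threshold theta.

    The boundary fits and supercell draws are shared across thetas (only
    the calling rule changes), which both matches how a sensitivity sweep
    is meant to be read and guarantees the monotone theta behavior:
    raising theta can only move patients from classified to unclassified.
    """
    thetas = [float(t) for t in thetas]
    for t in thetas:
        if not 0.5 < t <= 1.0:
            raise ValueError(f"theta {t} outside (0.5, 1]")
    fractions = _cloud_fractions(cohort, config)
    summaries = {
        t: _summarize(fractions, t, cohort.class_names) for t in thetas
    }
    variation: dict[str, float] = {}
    for key in ("percent_correct", "percent_unclassified", "percent_incorrect"):
        arr = np.vstack([getattr(summaries[t], key) for t in thetas])  # theta x m
        variation[key.removeprefix("percent_")] = float(
            (arr.max(axis=0) - arr.min(axis=0)).max()
        )
    return ThresholdSweepResult(thetas, summaries, variation)
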