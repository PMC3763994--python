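"""Synthetic cohorts with the statistical structure the method assumes.

Cells are drawn as  value = class mean + patient offset + (optional
subpopulation offset) + cell noise,  with the class mean difference small
compared to the within-class cell spread: single cells from the two classes
overlap heavily and are not separable, while supercell averages are.  Units
are chosen so that the within-class cell SD is the natural scale: class
shifts, patient effects and subpopulation offsets are all expressed in
multiples of the per-measurement cell SD.

The module also carries the closed-form accuracy oracle for the
one-dimensional two-Gaussian case, used to cross-check the full pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .exceptions import SchemaError
from .io import CellSample, Cohort

__all__ = ["SyntheticSpec", "generate_cohort", "expected_accuracy_1d"]


def _as_vec(x, p: int, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 0:
        arr = np.full(p, float(arr))
    if arr.shape != (p,):
        raise SchemaError(f"{name} must be scalar or length {p}, got shape {arr.shape}")
    return arr


@dataclass
class SyntheticSpec:
    """Generator settings for a two-class single-cell cohort.

    Defaults emulate a small clinical flow-cytometry cohort: 8 + 14
    patients, 16 measurements of which 5 carry a modest class-mean shift of
    0.3 cell-SD each (single-cell distributions overlap almost completely;
    the pooled shift magnitude ~0.67 gives single-cell accuracy near 0.63
    while supercells of a few hundred cells separate cleanly), a small
    additive patient-level mean offset, and unit Gaussian cell noise.

    Attributes
    ----------
    n_patients_per_class : (int, int)
        Patients in the first / second class.
    cells_per_patient : int
    n_measurements : int
    class_shift : scalar or per-measurement array
        Difference of class means, in units of the cell SD.  The first
        class sits at +shift/2, the second at -shift/2, matching the
        convention that the first class is the positive boundary side.
    cell_sd : scalar or per-measurement array
        Within-class single-cell SD (raw units).
    patient_effect_sd : scalar or per-measurement array
        SD of each patient's additive mean offset, in units of cell SD.
    subpopulations : list of (weight, offset) or None
        Shared mixture structure: each cell joins component j with
        probability weight_j and gains offset_j (scalar or per-measurement,
        units of cell SD).  Offsets are centered so the class means are
        unchanged.
    subpop_weight_jitter_sd : float
        Per-patient SD of the mixture weights around their nominal values
        (clipped and renormalized).  Nonzero values emulate well-defined
        cell subpopulations whose proportions vary between individuals —
        the regime where averaging-based phenotyping degrades.
    skew : scalar or per-measurement array
        Skewness control; nonzero applies a moment-matched (zero-mean,
        unit-SD) log-normal transform to the cell noise of that measurement.
    """

    n_patients_per_class: tuple[int, int] = (8, 14)
    cells_per_patient: int = 2000
    n_measurements: int = 16
    class_shift: float | Sequence[float] = field(default=None)  # type: ignore[assignment]
    cell_sd: float | Sequence[float] = 1.0
    patient_effect_sd: float | Sequence[float] = 0.05
    subpopulations: list[tuple[float, float | Sequence[float]]] | None = None
    subpop_weight_jitter_sd: float = 0.0
    skew: float | Sequence[float] = 0.0
    class_names: tuple[str, str] = ("healthy", "diseased")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.class_shift is None:
            shift = np.zeros(self.n_measurements)
            shift[: min(5, self.n_measurements)] = 0.3
            self.class_shift = shift
        if min(self.n_patients_per_class) < 1:
            raise SchemaError("need at least one patient per class")
        if self.cells_per_patient < 1:
            raise SchemaError("cells_per_patient must be >= 1")
        if self.n_measurements < 1:
            raise SchemaError("n_measurements must be >= 1")

    # resolved per-measurement arrays ------------------------------------

    def _resolved(self) -> dict[str, np.ndarray]:
        p = self.n_measurements
        out = {
            "delta": _as_vec(self.class_shift, p, "class_shift"),
            "sigma": _as_vec(self.cell_sd, p, "cell_sd"),
            "patient_sd": _as_vec(self.patient_effect_sd, p, "patient_effect_sd"),
            "skew": _as_vec(self.skew, p, "skew"),
        }
        if (out["sigma"] < 0).any() or (out["patient_sd"] < 0).any():
            raise SchemaError("SDs must be >= 0")
        return out


def _skewed_noise(rng: np.random.Generator, shape, s: float) -> np.ndarray:
    """Zero-mean unit-SD noise with log-normal-type skewness of sign(s)."""
    z = rng.standard_normal(shape)
    if s == 0.0:
        return z
    a = abs(s)
    raw = np.exp(a * z)
    mean = np.exp(a**2 / 2)
    sd = np.sqrt((np.exp(a**2) - 1.0) * np.exp(a**2))
    out = (raw - mean) / sd
    return out if s > 0 else -out


def generate_cohort(spec: SyntheticSpec) -> Cohort:
    """Draw a cohort from ``spec``; deterministic given ``spec.seed``."""
    p = spec.n_measurements
    r = spec._resolved()
    delta, sigma, patient_sd, skew = (
        r["delta"], r["sigma"], r["patient_sd"], r["skew"],
    )

    weights = offsets = None
    if spec.subpopulations:
        weights = np.asarray([w for w, _ in spec.subpopulations], dtype=float)
        if weights.min() < 0 or not np.isclose(weights.sum(), 1.0):
            raise SchemaError("subpopulation weights must be >= 0 and sum to 1")
        offsets = np.vstack(
            [_as_vec(o, p, "subpopulation offset") for _, o in spec.subpopulations]
        )
        offsets = offsets - weights @ offsets  # center: class means unchanged
    names = [f"m{j + 1:02d}" for j in range(p)]

    samples: list[CellSample] = []
    for c, (label, n_pat) in enumerate(
        zip(spec.class_names, spec.n_patients_per_class)
    ):
        class_mean = (0.5 if c == 0 else -0.5) * delta * sigma
        for i in range(n_pat):
            rng = np.random.default_rng(
                np.random.SeedSequence([spec.seed, c, i])
            )
            offset = rng.normal(0.0, patient_sd * sigma)
            noise = np.column_stack(
                [
                    _skewed_noise(rng, spec.cells_per_patient, skew[j])
                    for j in range(p)
                ]
            )
            values = class_mean + offset + noise * sigma
            if weights is not None:
                w = weights
                if spec.subpop_weight_jitter_sd > 0:
                    w = np.clip(
                        weights + rng.normal(0, spec.subpop_weight_jitter_sd, len(weights)),
                        0.01, None,
                    )
                    w = w / w.sum()
                comp = rng.choice(len(w), size=spec.cells_per_patient, p=w)
                values = values + offsets[comp] * sigma
            samples.append(
                CellSample(f"{label}-{i + 1:02d}", label, names, values)
            )
    return Cohort(samples, spec.class_names)


def expected_accuracy_1d(delta: float, sigma: float, n: int) -> float:
    """Accuracy of the midpoint rule for two equal-variance 1-D Gaussians
    after averaging ``n`` cells: Phi(sqrt(n) * |delta| / (2 * sigma)).

    ``delta`` is the raw class-mean difference and ``sigma`` the single-cell
    SD; averaging shrinks the SD to sigma/sqrt(n) while the midpoint
    threshold stays put, so the error of either class is the Gaussian tail
    beyond half the shift.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    if n < 1:
        raise ValueError("n must be >= 1")
    return float(norm.cdf(np.sqrt(n) * abs(delta) / (2.0 * sigma)))
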