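import numpy as np
import pytest
from hypothesis import settings

from supercells import (
    CellSample,
    Cohort,
    SupercellConfig,
    SyntheticSpec,
    generate_cohort,
)

settings.register_profile("ci", deadline=None, max_examples=25, derandomize=True)
settings.load_profile("ci")


@pytest.fixture
def toy_cd3_sample() -> CellSample:
    """Five cells, one CD3-like measurement, for hand-countable gating."""
    vals = np.array([[1.0], [5.0], [2.0], [7.0], [9.0]])
    return CellSample("toy", "healthy", ["CD3"], vals)


@pytest.fixture
def small_cohort() -> Cohort:
    """Four tiny patients, three measurements, fully deterministic."""
    rng = np.random.default_rng(11)
    names = ["alpha", "beta", "gamma"]
    samples = [
        CellSample(f"h{i}", "healthy", names, rng.normal(0.5, 1.0, (40, 3)))
        for i in range(2)
    ] + [
        CellSample(f"d{i}", "diseased", names, rng.normal(-0.5, 1.0, (40, 3)))
        for i in range(2)
    ]
    return Cohort(samples, ("healthy", "diseased"))


@pytest.fixture(scope="session")
def overlap_cohort() -> Cohort:
    """The central data regime: class means differ by far less than the
    within-class cell spread, so single cells are non-separable while
    supercells of ~100 cells separate cleanly."""
    spec = SyntheticSpec(
        n_patients_per_class=(4, 4),
        cells_per_patient=1200,
        n_measurements=10,
        class_shift=[0.3, 0.3, 0.3, 0, 0, 0, 0, 0, 0, 0],
        patient_effect_sd=0.03,
        seed=7,
    )
    return generate_cohort(spec)


@pytest.fixture
def gauss1d_cohort():
    """Factory: 1-D two-Gaussian cohort with raw mean shift delta, no
    patient effects — the closed-form accuracy oracle's exact regime."""

    def make(delta: float, n_patients: int = 2, cells: int = 2000, seed: int = 3):
        spec = SyntheticSpec(
            n_patients_per_class=(n_patients, n_patients),
            cells_per_patient=cells,
            n_measurements=1,
            class_shift=delta,
            patient_effect_sd=0.0,
            seed=seed,
        )
        return generate_cohort(spec)

    return make


@pytest.fixture
def default_config() -> SupercellConfig:
    return SupercellConfig(size_n=30, count_k=100, seed=0)
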