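"""Supercell construction.

A *supercell of size N* is the arithmetic mean of the measurement vectors of
N randomly selected cells from one sample.  Drawing K such averages turns a
patient's heterogeneous cell population into a "supercell cloud" of K points
whose marginals, by the central limit theorem, are narrower than the
single-cell marginals by a factor of about 1/sqrt(N) and closer to Gaussian.
Cells are never pooled across patients: each patient stays a separate point
cloud in measurement space.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import InsufficientCellsError, SchemaError, UndefinedRatioError
from .io import LABEL_COL, SAMPLE_COL, CellSample, Cohort

__all__ = [
    "SupercellConfig",
    "SupercellSample",
    "build_supercells",
    "build_supercell_cohort",
    "stack_supercells",
    "width_ratio",
    "write_supercell_table",
]

REPLACEMENT_MODES = ("never", "within_supercell_allowed")


@dataclass(frozen=True)
class SupercellConfig:
    """Sampling plan for one supercell cloud.

    Attributes
    ----------
    size_n : int
        N, the number of cells averaged into each supercell.
    count_k : int
        K, the number of supercells drawn per sample (default 100).
    replacement : {"never", "within_supercell_allowed"}
        ``never`` (default): the N cells within one supercell are distinct;
        different supercells are drawn independently and may share cells.
        ``within_supercell_allowed``: plain i.i.d. draws with replacement.
    seed : int
        Master seed; each sample gets its own stream derived from the seed
        and a stable hash of its sample_id, so adding or removing one
        patient never perturbs another patient's supercells.
    """

    size_n: int
    count_k: int = 100
    replacement: str = "never"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.size_n < 1:
            raise ValueError("size_n must be >= 1")
        if self.count_k < 1:
            raise ValueError("count_k must be >= 1")
        if self.replacement not in REPLACEMENT_MODES:
            raise ValueError(f"replacement must be one of {REPLACEMENT_MODES}")

    def to_dict(self) -> dict:
        return {
            "size_n": self.size_n,
            "count_k": self.count_k,
            "replacement": self.replacement,
            "seed": self.seed,
        }


@dataclass
class SupercellSample:
    """K supercells of size N derived from one sample (its point cloud)."""

    sample_id: str
    class_label: str
    measurement_names: list[str]
    values: np.ndarray  # (count_k, n_measurements)
    config: SupercellConfig

    @property
    def n_supercells(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.measurement_names)
        df.insert(0, "supercell_size", self.config.size_n)
        df.insert(0, LABEL_COL, self.class_label)
        df.insert(0, SAMPLE_COL, self.sample_id)
        return df


def _stream(sample_id: str, config: SupercellConfig) -> np.random.Generator:
    # stable across runs and platforms: crc32 of the id, not Python's hash()
    key = zlib.crc32(sample_id.encode("utf-8"))
    mode = REPLACEMENT_MODES.index(config.replacement)
    ss = np.random.SeedSequence(
        [config.seed, key, config.size_n, config.count_k, mode]
    )
    return np.random.default_rng(ss)


def build_supercells(sample: CellSample, config: SupercellConfig) -> SupercellSample:
    """Draw K supercells of size N from one sample.

    Each supercell is the columnwise mean of an independently drawn subset
    of ``size_n`` cells (distinct within a supercell when
    ``replacement="never"``).  Deterministic given (sample_id, config).
    """
    n_cells = sample.n_cells
    n, k = config.size_n, config.count_k
    rng = _stream(sample.sample_id, config)
    if config.replacement == "never":
        if n > n_cells:
            raise InsufficientCellsError(
                f"sample {sample.sample_id!r}: supercell size {n} exceeds "
                f"its {n_cells} cells (replacement='never')"
            )
        if n == n_cells:
            # the only distinct subset is the whole sample
            mean = sample.values.mean(axis=0)
            values = np.tile(mean, (k, 1))
        else:
            idx = np.empty((k, n), dtype=np.intp)
            for i in range(k):
                idx[i] = rng.choice(n_cells, size=n, replace=False, shuffle=False)
            values = sample.values[idx].mean(axis=1)
    else:
        idx = rng.integers(0, n_cells, size=(k, n))
        values = sample.values[idx].mean(axis=1)
    return SupercellSample(
        sample.sample_id,
        sample.class_label,
        list(sample.measurement_names),
        values,
        config,
    )


def build_supercell_cohort(
    cohort: Cohort, config: SupercellConfig
) -> list[SupercellSample]:
    """Build one supercell cloud per cohort sample (same config for all)."""
    return [build_supercells(s, config) for s in cohort]


def stack_supercells(
    clouds: Sequence[SupercellSample],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack clouds into (X, labels, sample_ids) for classifier fitting."""
    X = np.vstack([c.values for c in clouds])
    y = np.concatenate([np.repeat(c.class_label, c.n_supercells) for c in clouds])
    ids = np.concatenate([np.repeat(c.sample_id, c.n_supercells) for c in clouds])
    return X, y, ids


def width_ratio(
    sample: CellSample, measurement: str, config: SupercellConfig
) -> float:
    """SD(supercell marginal) / SD(single-cell marginal) for one measurement.

    For i.i.d. cells this converges to 1/sqrt(N) as K grows (the CLT
    narrowing factor); e.g. ~0.18 for N=30.
    """
    single = sample.column(measurement)
    sd_single = float(np.std(single, ddof=1)) if single.size > 1 else 0.0
    if sd_single == 0.0:
        raise UndefinedRatioError(
            f"measurement {measurement!r} has zero spread in sample "
            f"{sample.sample_id!r}"
        )
    cloud = build_supercells(sample, config)
    j = cloud.measurement_names.index(measurement)
    sd_super = float(np.std(cloud.values[:, j], ddof=1))
    return sd_super / sd_single


def write_supercell_table(
    clouds: Sequence[SupercellSample], path: str | Path
) -> None:
    """Serialize clouds to the long CSV dialect (extra column
    ``supercell_size``) plus a JSON sidecar echoing the sampling config."""
    if not clouds:
        raise SchemaError("no supercell samples to write")
    path = Path(path)
    pd.concat([c.to_frame() for c in clouds], ignore_index=True).to_csv(
        path, index=False
    )
    sidecar = path.with_suffix(path.suffix + ".config.json")
    sidecar.write_text(json.dumps(clouds[0].config.to_dict(), indent=2) + "\n")


def with_size(config: SupercellConfig, size_n: int) -> SupercellConfig:
    """Copy of ``config`` at a different supercell size (same seed/K)."""
    return replace(config, size_n=size_n)
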