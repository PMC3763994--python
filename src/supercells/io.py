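"""Cohort data model, table I/O and sequential gating.

The canonical on-disk format is a single "long" CSV/TSV table with columns
``sample_id``, ``class_label`` and then one column per measurement; one row
per cell.  A per-sample directory of plain measurement tables is also
accepted, as is an Excel workbook in the same long layout.  Values are kept
exactly as read: no transform, no compensation, and any missing or
non-finite value is a hard error, because downstream statistics average raw
measurement vectors.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    EmptyGateError,
    LabelingError,
    ParseError,
    SchemaError,
)

__all__ = [
    "CellSample",
    "Cohort",
    "GatingRule",
    "read_cell_table",
    "read_excel_table",
    "write_cell_table",
    "gate_subpopulation",
]

SAMPLE_COL = "sample_id"
LABEL_COL = "class_label"


@dataclass
class CellSample:
    """One patient's (or cell line's) cells-by-measurements matrix.

    Parameters
    ----------
    sample_id : str
        Unique identifier of the patient / cell line.
    class_label : str
        One of the two cohort class names.
    measurement_names : list of str
        Column names, in the order of the columns of ``values``.
    values : ndarray of shape (n_cells, n_measurements)
        Raw per-cell measurements; must be finite.
    """

    sample_id: str
    class_label: str
    measurement_names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.measurement_names = [str(m) for m in self.measurement_names]
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.ndim != 2:
            raise SchemaError(f"sample {self.sample_id!r}: values must be 2-D")
        if self.values.shape[0] < 1:
            raise SchemaError(f"sample {self.sample_id!r}: needs at least one cell")
        if self.values.shape[1] != len(self.measurement_names):
            raise SchemaError(
                f"sample {self.sample_id!r}: {self.values.shape[1]} columns but "
                f"{len(self.measurement_names)} measurement names"
            )
        if len(set(self.measurement_names)) != len(self.measurement_names):
            raise SchemaError(
                f"sample {self.sample_id!r}: duplicate measurement names"
            )
        if not np.isfinite(self.values).all():
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ParseError(
                f"sample {self.sample_id!r}: non-finite value at cell {i}, "
                f"measurement {self.measurement_names[j]!r}"
            )

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_measurements(self) -> int:
        return self.values.shape[1]

    def column(self, measurement: str) -> np.ndarray:
        """Return one measurement's per-cell values."""
        try:
            j = self.measurement_names.index(measurement)
        except ValueError:
            raise SchemaError(
                f"sample {self.sample_id!r} has no measurement {measurement!r}"
            ) from None
        return self.values[:, j]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.measurement_names)
        df.insert(0, LABEL_COL, self.class_label)
        df.insert(0, SAMPLE_COL, self.sample_id)
        return df


@dataclass
class Cohort:
    """A labeled two-class collection of :class:`CellSample` objects.

    ``class_names`` is an *ordered* pair; by convention the first class maps
    to the positive side of a fitted boundary (e.g. ``("healthy",
    "diseased")`` puts healthy supercells at positive signed distance).
    """

    samples: list[CellSample]
    class_names: tuple[str, str]

    def __post_init__(self) -> None:
        self.class_names = tuple(self.class_names)  # type: ignore[assignment]
        if len(self.class_names) != 2 or self.class_names[0] == self.class_names[1]:
            raise SchemaError("class_names must be two distinct names")
        if not self.samples:
            raise SchemaError("cohort has no samples")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise SchemaError("duplicate sample_ids in cohort")
        names = self.samples[0].measurement_names
        for s in self.samples:
            if s.measurement_names != names:
                raise SchemaError(
                    f"sample {s.sample_id!r} has different measurement names"
                )
            if s.class_label not in self.class_names:
                raise LabelingError(
                    f"sample {s.sample_id!r} labeled {s.class_label!r}, "
                    f"not one of {self.class_names}"
                )
        for c in self.class_names:
            if not any(s.class_label == c for s in self.samples):
                raise LabelingError(f"class {c!r} has no samples")

    @property
    def measurement_names(self) -> list[str]:
        return list(self.samples[0].measurement_names)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self) -> Iterator[CellSample]:
        return iter(self.samples)

    def get(self, sample_id: str) -> CellSample:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)

    def subset(self, sample_ids: Iterable[str]) -> "Cohort":
        wanted = list(sample_ids)
        return Cohort([self.get(i) for i in wanted], self.class_names)

    def relabel(self, labels: Mapping[str, str], class_names: tuple[str, str]) -> "Cohort":
        """Return a cohort with class labels replaced per ``labels``."""
        samples = [
            CellSample(s.sample_id, labels[s.sample_id], s.measurement_names, s.values)
            for s in self.samples
        ]
        return Cohort(samples, class_names)

    def to_frame(self) -> pd.DataFrame:
        return pd.concat([s.to_frame() for s in self.samples], ignore_index=True)


@dataclass(frozen=True)
class GatingRule:
    """One threshold gate: keep cells with value > threshold (``positive``)
    or value <= threshold (``negative``).  The two directions are exact
    complements, so a positive and a negative gate at the same threshold
    partition the cells."""

    measurement: str
    direction: str  # "positive" | "negative"
    threshold: float

    def __post_init__(self) -> None:
        if self.direction not in ("positive", "negative"):
            raise SchemaError(
                f"gate direction must be 'positive' or 'negative', "
                f"got {self.direction!r}"
            )

    def mask(self, sample: CellSample) -> np.ndarray:
        col = sample.column(self.measurement)
        if self.direction == "positive":
            return col > self.threshold
        return col <= self.threshold


def gate_subpopulation(sample: CellSample, rules: Sequence[GatingRule]) -> CellSample:
    """Apply a conjunctive sequence of gates, e.g. viability-/CD3+/CD4+/CD8-.

    Returns the sub-sample of cells passing *all* rules, with cell order and
    measurement columns unchanged.  Raises :class:`EmptyGateError` if no cell
    survives (rather than returning an invalid empty sample).
    """
    mask = np.ones(sample.n_cells, dtype=bool)
    for rule in rules:
        mask &= rule.mask(sample)
    if not rules:
        return sample
    if not mask.any():
        raise EmptyGateError(
            f"gating removed every cell of sample {sample.sample_id!r}"
        )
    return CellSample(
        sample.sample_id,
        sample.class_label,
        sample.measurement_names,
        sample.values[mask],
    )


def gate_cohort(cohort: Cohort, rules: Sequence[GatingRule]) -> Cohort:
    """Gate every sample of a cohort with the same rule sequence."""
    return Cohort([gate_subpopulation(s, rules) for s in cohort], cohort.class_names)


# ---------------------------------------------------------------------------
# Reading / writing


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","


def _frame_to_cohort(
    df: pd.DataFrame,
    source: str,
    class_map: Mapping[str, str] | None,
    class_names: tuple[str, str] | None,
) -> Cohort:
    if SAMPLE_COL not in df.columns:
        raise ParseError(f"{source}: missing required column {SAMPLE_COL!r}")
    has_label = LABEL_COL in df.columns
    meas = [c for c in df.columns if c not in (SAMPLE_COL, LABEL_COL)]
    if not meas:
        raise ParseError(f"{source}: no measurement columns")
    if len(set(meas)) != len(meas):
        raise ParseError(f"{source}: duplicate measurement columns")

    values = np.empty((len(df), len(meas)), dtype=float)
    for j, col in enumerate(meas):
        num = pd.to_numeric(df[col], errors="coerce")
        bad = num.isna()
        if bad.any():
            row = int(np.argmax(bad.to_numpy()))
            raise ParseError(
                f"{source}: non-numeric or missing value at row {row}, "
                f"column {col!r} (value {df[col].iloc[row]!r})"
            )
        values[:, j] = num.to_numpy(dtype=float)

    sample_ids = df[SAMPLE_COL].astype(str)
    order = list(dict.fromkeys(sample_ids))  # first-appearance order
    samples: list[CellSample] = []
    seen_labels: list[str] = []
    for sid in order:
        sel = (sample_ids == sid).to_numpy()
        if class_map is not None and sid in class_map:
            label = str(class_map[sid])
        elif has_label:
            labels = set(df.loc[sel, LABEL_COL].astype(str))
            if len(labels) != 1:
                raise LabelingError(f"{source}: sample {sid!r} has mixed labels {labels}")
            label = labels.pop()
        else:
            raise LabelingError(
                f"{source}: sample {sid!r} has no class label (no "
                f"{LABEL_COL!r} column and not in class_map)"
            )
        if label not in seen_labels:
            seen_labels.append(label)
        samples.append(CellSample(sid, label, meas, values[sel]))

    if class_names is None:
        if len(seen_labels) != 2:
            raise LabelingError(
                f"{source}: expected exactly 2 classes, found {seen_labels}"
            )
        class_names = (seen_labels[0], seen_labels[1])
    return Cohort(samples, class_names)


def read_cell_table(
    path: str | Path,
    format: str = "long",
    class_map: Mapping[str, str] | None = None,
    class_names: tuple[str, str] | None = None,
) -> Cohort:
    """Read a cohort from the canonical table format.

    Parameters
    ----------
    path : path
        Long-format CSV/TSV file (``format="long"``) or a directory of
        per-sample CSV files named ``<sample_id>.csv`` (``format="per_sample"``).
    format : {"long", "per_sample"}
    class_map : mapping sample_id -> class label, optional
        Required for ``per_sample``; for ``long`` it overrides (or replaces a
        missing) ``class_label`` column.
    class_names : ordered pair of str, optional
        Fixes the class order (first class = positive boundary side).
        Defaults to order of first appearance in the file.
    """
    path = Path(path)
    if format == "long":
        if not path.exists():
            raise ParseError(f"no such file: {path}")
        try:
            df = pd.read_csv(path, sep=_sep_for(path), float_precision="round_trip")
        except pd.errors.EmptyDataError:
            raise ParseError(f"{path}: empty file") from None
        if df.empty:
            raise ParseError(f"{path}: no data rows")
        return _frame_to_cohort(df, str(path), class_map, class_names)
    if format == "per_sample":
        if not path.is_dir():
            raise ParseError(f"per_sample format needs a directory: {path}")
        if class_map is None:
            raise LabelingError("per_sample format requires a class_map")
        files = sorted(p for p in path.iterdir() if p.suffix.lower() in (".csv", ".tsv"))
        if not files:
            raise ParseError(f"{path}: no per-sample tables found")
        frames = []
        for f in files:
            try:
                df = pd.read_csv(f, sep=_sep_for(f), float_precision="round_trip")
            except pd.errors.EmptyDataError:
                raise ParseError(f"{f}: empty file") from None
            df.insert(0, SAMPLE_COL, f.stem)
            frames.append(df)
        return _frame_to_cohort(
            pd.concat(frames, ignore_index=True), str(path), class_map, class_names
        )
    raise ValueError(f"unknown format {format!r}")


def read_excel_table(
    path: str | Path,
    sheet_name: int | str = 0,
    class_map: Mapping[str, str] | None = None,
    class_names: tuple[str, str] | None = None,
) -> Cohort:
    """Adapter for Excel workbooks in the long layout (one sheet, columns
    sample_id, class_label, measurements...).  Useful for supplementary
    tables distributed as spreadsheets; values are taken as-is with no
    fluorescence transform."""
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    try:
        df = pd.read_excel(path, sheet_name=sheet_name)
    except Exception as exc:  # engine errors vary by format
        raise ParseError(f"{path}: could not read workbook ({exc})") from exc
    if df.empty:
        raise ParseError(f"{path}: no data rows")
    return _frame_to_cohort(df, str(path), class_map, class_names)


def write_cell_table(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort to the canonical long CSV/TSV.

    Floats are written with Python's shortest round-tripping repr, so
    ``read_cell_table(write_cell_table(c))`` reproduces ``c`` exactly.
    """
    for s in cohort.samples:  # re-validate in case of in-place mutation
        s.__post_init__()
    cohort.__post_init__()
    path = Path(path)
    df = cohort.to_frame()
    try:
        df.to_csv(path, sep=_sep_for(path), index=False)
    except OSError as exc:
        raise OSError(f"cannot write {path}: {exc}") from exc
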