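"""Cohort health tensor and run configuration.

A cohort is modelled as an ``N x M x K`` real tensor: ``N`` students,
``M`` health criteria (heart rate, blood pressure, ...) and ``K`` time
points per (student, criterion) series.  An optional boolean mask marks
which entries were actually observed; unobserved entries contribute zero
to every inner product downstream, so no imputation model is smuggled in.

Two interchange formats are supported:

* long CSV with header ``student_id,criterion_id,time_index,value``
  (0-based ``time_index``); masked entries are simply absent;
* a dense JSON bundle ``{"students": [...], "criteria": [...], "K": int,
  "values": [[[...]]]}`` with an optional parallel ``"mask"`` field.

Round-trips through either format reproduce the tensor exactly: values
are serialized as shortest round-trip decimal text.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError, SchemaError, ValidationError

__all__ = ["HealthTensor", "RunConfig", "read_tensor", "write_tensor"]

LONG_CSV_COLUMNS = ("student_id", "criterion_id", "time_index", "value")


@dataclass
class HealthTensor:
    """An ``N x M x K`` cohort tensor with identifiers and an observation mask.

    Parameters
    ----------
    student_ids : list of str
        Unique opaque student identifiers, one per tensor row.
    criterion_ids : list of str
        Unique opaque health-criterion identifiers.
    values : ndarray of float, shape (N, M, K)
        Sensor readings; units are criterion-specific and opaque.
    mask : ndarray of bool, shape (N, M, K), optional
        True where the entry was observed.  ``None`` means fully observed.
    """

    student_ids: list[str]
    criterion_ids: list[str]
    values: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self):
        self.student_ids = [str(s) for s in self.student_ids]
        self.criterion_ids = [str(c) for c in self.criterion_ids]
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValidationError(
                f"values must be a 3-d (N, M, K) array, got ndim={self.values.ndim}"
            )
        n, m, k = self.values.shape
        if n < 1 or m < 1 or k < 1:
            raise ValidationError(f"tensor dimensions must be >= 1, got {(n, m, k)}")
        if len(self.student_ids) != n:
            raise ValidationError(
                f"{len(self.student_ids)} student ids for {n} tensor rows"
            )
        if len(self.criterion_ids) != m:
            raise ValidationError(
                f"{len(self.criterion_ids)} criterion ids for {m} tensor columns"
            )
        if len(set(self.student_ids)) != n:
            raise ValidationError("student ids are not unique")
        if len(set(self.criterion_ids)) != m:
            raise ValidationError("criterion ids are not unique")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ValidationError(
                    f"mask shape {self.mask.shape} != values shape {self.values.shape}"
                )
        observed = self.values if self.mask is None else self.values[self.mask]
        if not np.all(np.isfinite(observed)):
            raise ValidationError("observed tensor values must be finite")

    @property
    def n_students(self) -> int:
        return self.values.shape[0]

    @property
    def n_criteria(self) -> int:
        return self.values.shape[1]

    @property
    def num_timepoints(self) -> int:
        return self.values.shape[2]

    def observed_values(self) -> np.ndarray:
        """Values with unobserved entries zeroed; safe for inner products."""
        if self.mask is None:
            return self.values
        return np.where(self.mask, self.values, 0.0)

    def observed_mask(self) -> np.ndarray:
        """A dense boolean mask (all-True when no mask is stored)."""
        if self.mask is None:
            return np.ones(self.values.shape, dtype=bool)
        return self.mask

    def equals(self, other: "HealthTensor") -> bool:
        """Exact equality on ids, shape, mask and observed values."""
        if self.student_ids != other.student_ids:
            return False
        if self.criterion_ids != other.criterion_ids:
            return False
        if self.values.shape != other.values.shape:
            return False
        ma, mb = self.observed_mask(), other.observed_mask()
        if not np.array_equal(ma, mb):
            return False
        return np.array_equal(self.values[ma], other.values[mb])


@dataclass(frozen=True)
class RunConfig:
    """Hashing/detection parameters.

    ``p`` hash tables, ``q`` index repetitions per table, similarity
    threshold ``T`` with ``1 <= T <= q``, and the root seed.  When
    ``per_criterion_planes`` is true an independent random hyperplane is
    drawn per (table, repetition, criterion) instead of one shared
    hyperplane per (table, repetition).
    """

    p: int
    q: int
    T: int
    seed: int = 0
    per_criterion_planes: bool = False

    def __post_init__(self):
        for name in ("p", "q", "T", "seed"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or isinstance(v, bool):
                raise ValidationError(f"{name} must be an integer, got {v!r}")
        if self.p < 1:
            raise ValidationError(f"p must be >= 1, got {self.p}")
        if self.q < 1:
            raise ValidationError(f"q must be >= 1, got {self.q}")
        if not 1 <= self.T <= self.q:
            raise ValidationError(f"T must satisfy 1 <= T <= q={self.q}, got {self.T}")
        if self.seed < 0:
            raise ValidationError(f"seed must be non-negative, got {self.seed}")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            try:
                raw = json.load(fh)
            except json.JSONDecodeError as exc:
                raise ParseError(f"invalid JSON in {path}: {exc}") from exc
        if not isinstance(raw, dict):
            raise SchemaError(f"run config must be a JSON object, got {type(raw).__name__}")
        unknown = set(raw) - {"p", "q", "T", "seed", "per_criterion_planes"}
        if unknown:
            raise SchemaError(f"unknown run-config keys: {sorted(unknown)}")
        missing = {"p", "q", "T"} - set(raw)
        if missing:
            raise SchemaError(f"run config missing required keys: {sorted(missing)}")
        return cls(
            p=raw["p"],
            q=raw["q"],
            T=raw["T"],
            seed=raw.get("seed", 0),
            per_criterion_planes=bool(raw.get("per_criterion_planes", False)),
        )

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "p": self.p,
                    "q": self.q,
                    "T": self.T,
                    "seed": self.seed,
                    "per_criterion_planes": self.per_criterion_planes,
                },
                fh,
                indent=2,
            )
            fh.write("\n")


def _read_long_csv(path: str | Path) -> HealthTensor:
    try:
        frame = pd.read_csv(
            path,
            dtype={"student_id": str, "criterion_id": str},
            float_precision="round_trip",
        )
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"empty file: {path}") from exc
    except (ValueError, pd.errors.ParserError) as exc:
        raise ParseError(f"malformed CSV in {path}: {exc}") from exc
    if list(frame.columns) != list(LONG_CSV_COLUMNS):
        raise SchemaError(
            f"expected columns {list(LONG_CSV_COLUMNS)}, got {list(frame.columns)}"
        )
    if len(frame) == 0:
        raise ParseError(f"no data rows in {path}")

    time_idx = pd.to_numeric(frame["time_index"], errors="coerce")
    bad = time_idx.isna() | (time_idx != time_idx.astype("Int64").astype(float))
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # +1 header, +1 1-based
        raise ParseError("time_index is not an integer", line=line)
    time_idx = time_idx.astype(int)
    vals = pd.to_numeric(frame["value"], errors="coerce")
    nonfinite = ~np.isfinite(vals.to_numpy())
    if nonfinite.any():
        line = int(np.flatnonzero(nonfinite)[0]) + 2
        raise ParseError("value is not a finite number", line=line)

    if (time_idx < 0).any():
        line = int(np.flatnonzero((time_idx < 0).to_numpy())[0]) + 2
        raise ParseError("time_index must be >= 0", line=line)
    k = int(time_idx.max()) + 1

    # first-appearance order keeps read(write(t)) an identity
    students = list(dict.fromkeys(frame["student_id"]))
    criteria = list(dict.fromkeys(frame["criterion_id"]))
    s_pos = {s: i for i, s in enumerate(students)}
    c_pos = {c: j for j, c in enumerate(criteria)}

    values = np.zeros((len(students), len(criteria), k))
    mask = np.zeros((len(students), len(criteria), k), dtype=bool)
    i = frame["student_id"].map(s_pos).to_numpy()
    j = frame["criterion_id"].map(c_pos).to_numpy()
    t = time_idx.to_numpy()
    if len(frame) != len(set(zip(i, j, t))):
        raise SchemaError("duplicate (student, criterion, time) rows")
    values[i, j, t] = vals.to_numpy()
    mask[i, j, t] = True
    tensor = HealthTensor(students, criteria, values, mask)
    if tensor.mask is not None and tensor.mask.all():
        tensor.mask = None
    return tensor


def _check_series_consistency(path: str | Path) -> None:
    """Reject files where students disagree on the number of time points.

    A long CSV is *complete* when every present (student, criterion)
    series covers the same contiguous 0..K-1 range.  Files where one
    student records K time points and another records fewer, with no
    masking intent (i.e. each series is a prefix 0..k_i-1 of differing
    lengths), are ambiguous and rejected.
    """
    frame = pd.read_csv(path, dtype={"student_id": str, "criterion_id": str})
    grouped = frame.groupby(["student_id", "criterion_id"])["time_index"]
    maxima = grouped.max()
    counts = grouped.count()
    prefixes = (counts == maxima + 1).all()
    if prefixes and maxima.nunique() > 1:
        raise SchemaError(
            "inconsistent number of time points across series: "
            f"K in {sorted((maxima + 1).unique().tolist())}"
        )


def _read_dense_json(path: str | Path) -> HealthTensor:
    with open(path, "r", encoding="utf-8") as fh:
        try:
            raw = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ParseError(f"invalid JSON in {path}: {exc}") from exc
    for key in ("students", "criteria", "K", "values"):
        if key not in raw:
            raise SchemaError(f"dense JSON bundle missing key {key!r}")
    k = raw["K"]
    values = np.asarray(raw["values"], dtype=np.float64)
    if values.ndim != 3 or values.shape[2] != k:
        raise SchemaError(
            f"values must be N x M x K={k} nested lists, got shape {values.shape}"
        )
    mask = np.asarray(raw["mask"], dtype=bool) if "mask" in raw else None
    return HealthTensor(raw["students"], raw["criteria"], values, mask)


def read_tensor(path: str | Path, format: str = "long-csv") -> HealthTensor:
    """Read a cohort tensor from ``path``.

    ``format`` is ``"long-csv"`` or ``"dense-json"``.  Malformed rows
    raise :class:`ParseError` naming the line; inconsistent time-point
    counts raise :class:`SchemaError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "long-csv":
        tensor = _read_long_csv(path)
        _check_series_consistency(path)
        return tensor
    if format == "dense-json":
        return _read_dense_json(path)
    raise ValidationError(f"unknown tensor format {format!r}")


def _format_value(v: float) -> str:
    return repr(float(v))


def write_tensor(tensor: HealthTensor, path: str | Path, format: str = "long-csv") -> None:
    """Write ``tensor`` so that :func:`read_tensor` reproduces it exactly.

    Long CSV omits masked triples; dense JSON stores the mask alongside
    the values (masked slots hold 0.0).  A long-CSV round-trip is exact
    provided every student and criterion keeps at least one observed
    entry and the final time index is observed somewhere (otherwise that
    information is simply absent from the file).
    """
    if not isinstance(tensor, HealthTensor):
        raise ValidationError("write_tensor expects a HealthTensor")
    path = Path(path)
    if format == "long-csv":
        mask = tensor.observed_mask()
        with open(path, "w", encoding="utf-8", newline="") as fh:
            fh.write(",".join(LONG_CSV_COLUMNS) + "\n")
            for i, sid in enumerate(tensor.student_ids):
                for j, cid in enumerate(tensor.criterion_ids):
                    for t in range(tensor.num_timepoints):
                        if mask[i, j, t]:
                            fh.write(
                                f"{sid},{cid},{t},{_format_value(tensor.values[i, j, t])}\n"
                            )
    elif format == "dense-json":
        vals = np.where(tensor.observed_mask(), tensor.values, 0.0)
        bundle: dict = {
            "students": tensor.student_ids,
            "criteria": tensor.criterion_ids,
            "K": tensor.num_timepoints,
            "values": vals.tolist(),
        }
        if tensor.mask is not None:
            bundle["mask"] = tensor.mask.tolist()
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(bundle, fh)
            fh.write("\n")
    else:
        raise ValidationError(f"unknown tensor format {format!r}")
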