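"""Random-hyperplane hashing of health curves into decimal indexes.

Each (student, criterion) series ``A`` of length ``K`` is reduced to one
bit: the sign of its inner product with a random hyperplane normal ``B``
whose components are drawn uniformly from ``[-1, 1]``.  The ``M`` bits of
a student (criterion ``c_1`` most significant) are packed into a single
non-negative integer — the student's *health index* — which is what gets
transmitted instead of the raw readings.  The construction is repeated
``q`` times per hash table and over ``p`` independent tables; downstream
similarity only ever compares these integers for equality.

Randomness discipline: one root seed; the hyperplane for slot
(table ``t``, repetition ``z``[, criterion ``j``]) comes from a dedicated
substream keyed by that tuple, so results never depend on construction
order, and the first ``p' <= p`` tables / ``q' <= q`` repetitions of a
larger index coincide bit-for-bit with a freshly built smaller one.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .data_model import HealthTensor, RunConfig
from .errors import ParseError, SchemaError, ValidationError

__all__ = [
    "ProjectionSet",
    "IndexTable",
    "plane_rng",
    "sample_projection",
    "project",
    "binarize",
    "signature_to_index",
    "projection_planes",
    "build_index",
    "subset_index",
]


def plane_rng(seed: int, table: int, repetition: int, criterion: int | None = None) -> np.random.Generator:
    """Deterministic substream for one hyperplane slot.

    Keyed by (table, repetition) for the shared-plane scheme and by
    (table, repetition, criterion) when each criterion draws its own
    plane.  Indices are 0-based.
    """
    key = (table, repetition) if criterion is None else (table, repetition, criterion)
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def sample_projection(K: int, rng: np.random.Generator) -> np.ndarray:
    """Draw a K-dimensional hyperplane normal with components ~ U[-1, 1]."""
    if not isinstance(K, (int, np.integer)) or K < 1:
        raise ValidationError(f"K must be a positive integer, got {K!r}")
    return rng.uniform(-1.0, 1.0, size=int(K))


def project(series: np.ndarray, plane: np.ndarray) -> float:
    """Inner product of a health series with a hyperplane normal.

    Masked series components must already be zeroed by the caller; a
    zero contribution leaves the sign driven by observed data.
    """
    series = np.asarray(series, dtype=np.float64)
    plane = np.asarray(plane, dtype=np.float64)
    if series.shape != plane.shape or series.ndim != 1:
        raise ValidationError(
            f"series and plane must be 1-d vectors of equal length, "
            f"got shapes {series.shape} and {plane.shape}"
        )
    return float(series @ plane)


def binarize(omega: float) -> int:
    """Map a projection value to its hash bit: 1 iff omega > 0.

    A projection of exactly zero maps to 0; the event has measure zero
    for continuous data but a fixed rule keeps hashing total.
    """
    if not math.isfinite(omega):
        raise ValidationError(f"projection value must be finite, got {omega!r}")
    return 1 if omega > 0 else 0


def signature_to_index(bits) -> int:
    """Pack an ordered bit list into its decimal index, first bit most significant.

    ``(1, 1, 1) -> 7``.  Arbitrary precision: M may run to thousands.
    """
    bits = list(bits)
    if not bits:
        raise ValidationError("signature must contain at least one bit")
    value = 0
    for b in bits:
        if b not in (0, 1):
            raise ValidationError(f"signature bits must be 0 or 1, got {b!r}")
        value = (value << 1) | int(b)
    return value


@dataclass(frozen=True)
class ProjectionSet:
    """The random hyperplanes for every (table, repetition[, criterion]) slot.

    ``planes`` has shape (p, q, K) when one plane is shared by all
    criteria of a repetition, or (p, q, M, K) with per-criterion planes.
    """

    planes: np.ndarray
    seed: int
    per_criterion: bool = False

    def __post_init__(self):
        object.__setattr__(self, "planes", np.asarray(self.planes, dtype=np.float64))
        expected = 4 if self.per_criterion else 3
        if self.planes.ndim != expected:
            raise ValidationError(
                f"planes must have {expected} dimensions, got {self.planes.ndim}"
            )
        if self.planes.size and (np.abs(self.planes) > 1.0).any():
            raise ValidationError("hyperplane components must lie in [-1, 1]")

    @property
    def p(self) -> int:
        return self.planes.shape[0]

    @property
    def q(self) -> int:
        return self.planes.shape[1]


def projection_planes(config: RunConfig, M: int, K: int) -> ProjectionSet:
    """Materialize all hyperplanes for a run, reproducibly from the seed."""
    if config.per_criterion_planes:
        planes = np.empty((config.p, config.q, M, K))
        for t in range(config.p):
            for z in range(config.q):
                for j in range(M):
                    planes[t, z, j] = sample_projection(
                        K, plane_rng(config.seed, t, z, j)
                    )
    else:
        planes = np.empty((config.p, config.q, K))
        for t in range(config.p):
            for z in range(config.q):
                planes[t, z] = sample_projection(K, plane_rng(config.seed, t, z))
    return ProjectionSet(planes, seed=config.seed, per_criterion=config.per_criterion_planes)


def _pack_rows(bits: np.ndarray) -> list[int]:
    """Pack each row of an (N, M) bit matrix into an integer, MSB first."""
    m = bits.shape[1]
    pad = (-m) % 8
    packed = np.packbits(bits.astype(np.uint8), axis=1)
    return [int.from_bytes(row.tobytes(), "big") >> pad for row in packed]


@dataclass
class IndexTable:
    """Per-student decimal health indexes for all (table, repetition) slots.

    ``pi[t][i][z]`` is the index of student ``i`` in table ``t``,
    repetition ``z`` — an arbitrary-precision integer in ``[0, 2**M - 1]``.
    Only equality comparisons are ever performed on these values.
    """

    student_ids: list[str]
    pi: list[list[list[int]]]
    p: int
    q: int
    M: int
    seed: int

    def __post_init__(self):
        if len(self.pi) != self.p:
            raise ValidationError(f"expected {self.p} tables, got {len(self.pi)}")
        n = len(self.student_ids)
        bound = 1 << self.M
        for t, table in enumerate(self.pi):
            if len(table) != n:
                raise ValidationError(f"table {t} covers {len(table)} of {n} students")
            for row in table:
                if len(row) != self.q:
                    raise ValidationError(
                        f"expected q={self.q} repetitions, got {len(row)}"
                    )
                for v in row:
                    if not 0 <= v < bound:
                        raise ValidationError(
                            f"index {v} outside [0, 2^{self.M} - 1]"
                        )

    @property
    def n_students(self) -> int:
        return len(self.student_ids)

    def student_vectors(self, i: int) -> list[list[int]]:
        """All index vectors of student ``i``: a p-list of q-lists."""
        return [self.pi[t][i] for t in range(self.p)]

    def to_json(self, path: str | Path) -> None:
        tables = []
        for t in range(self.p):
            tables.append(
                {
                    "table": t,
                    "pi": {
                        sid: [format(v, "x") for v in self.pi[t][i]]
                        for i, sid in enumerate(self.student_ids)
                    },
                }
            )
        payload = {
            "p": self.p,
            "q": self.q,
            "M": self.M,
            "seed": self.seed,
            "tables": tables,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "IndexTable":
        with open(path, "r", encoding="utf-8") as fh:
            try:
                raw = json.load(fh)
            except json.JSONDecodeError as exc:
                raise ParseError(f"invalid JSON in {path}: {exc}") from exc
        for key in ("p", "q", "M", "seed", "tables"):
            if key not in raw:
                raise SchemaError(f"index file missing key {key!r}")
        if len(raw["tables"]) != raw["p"]:
            raise SchemaError(
                f"index file declares p={raw['p']} but holds {len(raw['tables'])} tables"
            )
        student_ids = list(raw["tables"][0]["pi"].keys())
        pi = []
        for entry in sorted(raw["tables"], key=lambda e: e["table"]):
            if list(entry["pi"].keys()) != student_ids:
                raise SchemaError("tables disagree on the student set")
            pi.append([[int(h, 16) for h in entry["pi"][sid]] for sid in student_ids])
        return cls(
            student_ids=student_ids,
            pi=pi,
            p=raw["p"],
            q=raw["q"],
            M=raw["M"],
            seed=raw["seed"],
        )


def build_index(
    tensor: HealthTensor,
    config: RunConfig,
    planes: ProjectionSet | None = None,
) -> IndexTable:
    """Hash a cohort tensor into its full (p, q) index table.

    The output carries only integers in ``[0, 2**M - 1]`` plus identifiers
    and configuration — no raw reading appears in it.  Fully determined
    by (tensor, config.seed); positive rescaling of any series leaves its
    bits unchanged.
    """
    if planes is None:
        planes = projection_planes(config, tensor.n_criteria, tensor.num_timepoints)
    if planes.p < config.p or planes.q < config.q:
        raise ValidationError(
            f"projection set covers (p={planes.p}, q={planes.q}), "
            f"config needs (p={config.p}, q={config.q})"
        )
    vals = tensor.observed_values()  # (N, M, K), masked entries zeroed
    pi: list[list[list[int]]] = []
    for t in range(config.p):
        table_rows: list[list[list[int]]] = [[] for _ in range(tensor.n_students)]
        for z in range(config.q):
            if config.per_criterion_planes:
                omega = np.einsum("imk,mk->im", vals, planes.planes[t, z])
            else:
                omega = vals @ planes.planes[t, z]
            bits = omega > 0  # ties (omega == 0) map to 0
            for i, value in enumerate(_pack_rows(bits)):
                table_rows[i].append(value)
        pi.append(table_rows)
    return IndexTable(
        student_ids=list(tensor.student_ids),
        pi=pi,
        p=config.p,
        q=config.q,
        M=tensor.n_criteria,
        seed=config.seed,
    )


def subset_index(index: IndexTable, p: int, q: int) -> IndexTable:
    """Restrict an index to its first ``p`` tables and ``q`` repetitions.

    Because hyperplane substreams are keyed by (table, repetition), this
    equals an index built from scratch with the smaller configuration.
    """
    if not 1 <= p <= index.p:
        raise ValidationError(f"p must be in [1, {index.p}], got {p}")
    if not 1 <= q <= index.q:
        raise ValidationError(f"q must be in [1, {index.q}], got {q}")
    pi = [[row[:q] for row in index.pi[t]] for t in range(p)]
    return IndexTable(
        student_ids=list(index.student_ids),
        pi=pi,
        p=p,
        q=q,
        M=index.M,
        seed=index.seed,
    )
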