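"""Synthetic wearable-like cohorts with known groups and planted anomalies.

The generator emulates the setting the detector targets: a cohort of
students whose per-criterion sensor curves are shared within latent
health groups.  For each (group, criterion) a smooth baseline curve is
drawn — a constant offset plus a few random harmonics over the K time
points.  Normal students receive their group's curves plus i.i.d.
Gaussian noise; anomalous students are displaced from a group baseline
by ``separation`` times the per-criterion baseline spread along a random
direction curve, so they resemble no group.

Curves are deviations from the population baseline (mean level zero):
sign-projection hashing carries information only through the direction
of a curve, so a large offset common to everyone would make all students
collide.  Real pipelines would center per criterion first; the generator
produces already-centered signals.

Everything is a pure function of (config, seed).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data_model import HealthTensor
from .errors import ValidationError

__all__ = ["GeneratorConfig", "LabeledCohort", "HeldOutEntry", "generate_cohort", "mask_entries"]

# baseline curve scale (per-entry units): across-group offset spread and
# per-harmonic amplitude spread.  Offsets dominate, mimicking stable
# person/group level differences with milder circadian-like wiggles.
OFFSET_SD = 3.0
HARMONIC_SD = 1.0
N_HARMONICS = 3


@dataclass(frozen=True)
class GeneratorConfig:
    """Cohort-generator parameters.

    Defaults describe the reference condition used throughout the test
    suite: 100 students, 20 criteria, 64 time points, 4 latent groups,
    5% planted anomalies, unit-order noise (sd 0.5) on curves whose
    baseline per-entry spread is ~3, and anomalous displacement of 4
    baseline spreads.
    """

    N: int = 100
    M: int = 20
    K: int = 64
    n_groups: int = 4
    anomaly_fraction: float = 0.05
    noise_sd: float = 0.5
    separation: float = 4.0
    seed: int = 0

    def __post_init__(self):
        if self.N < 1 or self.M < 1 or self.K < 1:
            raise ValidationError(f"N, M, K must be >= 1, got {(self.N, self.M, self.K)}")
        if self.n_groups < 1:
            raise ValidationError(f"n_groups must be >= 1, got {self.n_groups}")
        if not 0.0 <= self.anomaly_fraction < 1.0:
            raise ValidationError(
                f"anomaly_fraction must be in [0, 1), got {self.anomaly_fraction}"
            )
        if round(self.N * self.anomaly_fraction) >= self.N:
            raise ValidationError("anomaly_fraction leaves no normal students")
        if self.noise_sd < 0:
            raise ValidationError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.separation <= 0:
            raise ValidationError(f"separation must be > 0, got {self.separation}")
        if self.seed < 0:
            raise ValidationError(f"seed must be non-negative, got {self.seed}")

    @classmethod
    def from_json(cls, path: str | Path) -> "GeneratorConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = json.load(fh)
        if not isinstance(raw, dict):
            raise ValidationError("generator config must be a JSON object")
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"unknown generator-config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class HeldOutEntry:
    """One hidden (student, criterion, time) triple with its true value."""

    student_id: str
    criterion_id: str
    time_index: int
    true_value: float


@dataclass
class LabeledCohort:
    """A generated tensor plus its ground-truth labels."""

    tensor: HealthTensor
    group_of: dict[str, int | str]  # student id -> group index or "anomaly"
    truth_anomalies: list[str]
    config: GeneratorConfig = field(repr=False, default=None)

    def labels_to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(
                {"groups": self.group_of, "anomalies": self.truth_anomalies},
                fh,
                indent=2,
            )
            fh.write("\n")


def _baseline_curves(rng: np.random.Generator, G: int, M: int, K: int) -> np.ndarray:
    """Smooth (G, M, K) baseline curves: offset + low-order harmonics."""
    k = np.arange(K) / K
    offsets = rng.normal(0.0, OFFSET_SD, size=(G, M))
    curves = np.broadcast_to(offsets[:, :, None], (G, M, K)).copy()
    for h in range(1, N_HARMONICS + 1):
        amp = rng.normal(0.0, HARMONIC_SD, size=(G, M))
        phase = rng.uniform(0.0, 2.0 * math.pi, size=(G, M))
        curves += amp[:, :, None] * np.sin(2.0 * math.pi * h * k[None, None, :] + phase[:, :, None])
    return curves


def generate_cohort(config: GeneratorConfig) -> LabeledCohort:
    """Generate a labeled cohort tensor; fully determined by the config."""
    rng = np.random.default_rng(config.seed)
    G, N, M, K = config.n_groups, config.N, config.M, config.K
    baselines = _baseline_curves(rng, G, M, K)

    # per-criterion baseline spread: std of baseline values across groups
    # and time.  Degenerate (constant) criteria fall back to unit spread
    # so planted anomalies never collapse onto a baseline.
    spread = baselines.std(axis=(0, 2))
    spread = np.where(spread > 0, spread, 1.0)

    n_anom = round(N * config.anomaly_fraction)
    anom_idx = set(rng.choice(N, size=n_anom, replace=False).tolist()) if n_anom else set()

    student_ids = [f"s{i + 1}" for i in range(N)]
    criterion_ids = [f"c{j + 1}" for j in range(M)]
    values = np.empty((N, M, K))
    group_of: dict[str, int | str] = {}
    truth: list[str] = []

    normal_rank = 0
    for i in range(N):
        noise = rng.normal(0.0, config.noise_sd, size=(M, K)) if config.noise_sd > 0 else 0.0
        if i in anom_idx:
            base = int(rng.integers(G))
            direction = rng.standard_normal((M, K))
            values[i] = (
                baselines[base]
                + config.separation * spread[:, None] * direction
                + noise
            )
            group_of[student_ids[i]] = "anomaly"
            truth.append(student_ids[i])
        else:
            g = normal_rank % G  # round-robin keeps groups balanced
            normal_rank += 1
            values[i] = baselines[g] + noise
            group_of[student_ids[i]] = g

    tensor = HealthTensor(student_ids, criterion_ids, values)
    return LabeledCohort(tensor=tensor, group_of=group_of, truth_anomalies=truth, config=config)


def mask_entries(
    cohort: LabeledCohort | HealthTensor,
    fraction: float,
    seed: int,
) -> tuple[HealthTensor, list[HeldOutEntry]]:
    """Hide a uniformly random ``floor(N*M*K*fraction)`` of the entries.

    Returns the masked tensor and the held-out triples with their true
    values; the two are disjoint by construction.  Deterministic per seed.
    """
    tensor = cohort.tensor if isinstance(cohort, LabeledCohort) else cohort
    if not 0.0 < fraction < 1.0:
        raise ValidationError(f"fraction must be in (0, 1), got {fraction}")
    rng = np.random.default_rng(seed)
    observed_flat = np.flatnonzero(tensor.observed_mask())
    n_hide = math.floor(tensor.values.size * fraction)
    if n_hide > len(observed_flat):
        raise ValidationError("fraction hides more entries than are observed")
    hidden = rng.choice(observed_flat, size=n_hide, replace=False)
    hidden.sort()

    mask = tensor.observed_mask().copy()
    i, j, t = np.unravel_index(hidden, tensor.values.shape)
    mask[i, j, t] = False
    masked = HealthTensor(
        list(tensor.student_ids), list(tensor.criterion_ids), tensor.values.copy(), mask
    )
    heldout = [
        HeldOutEntry(
            student_id=tensor.student_ids[ii],
            criterion_id=tensor.criterion_ids[jj],
            time_index=int(tt),
            true_value=float(tensor.values[ii, jj, tt]),
        )
        for ii, jj, tt in zip(i, j, t)
    ]
    return masked, heldout
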