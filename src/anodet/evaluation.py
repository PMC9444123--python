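"""Held-out-entry prediction harness: index-based vs plaintext baselines.

The detector itself is binary, so accuracy is operationalized the way
collaborative-filtering studies do it: hide a random fraction of tensor
entries, predict each hidden entry from neighbor students, and score the
predictions with MAE and RMSE.

* ``ano-det`` predicts a hidden (i, j, k) as the plain mean of the
  observed a[i', j, k] over the index-similar neighbors i' (Sim >= T);
  with no informative neighbor it falls back to the cohort mean of
  criterion j at time k, then to the global observed mean.
* ``ucf`` is classical user-based collaborative filtering on the raw
  (plaintext) tensor: Pearson correlation over co-observed entries,
  prediction as the correlation-weighted mean over the top-k positively
  correlated neighbors, same fallbacks.
* ``brute-lsh`` is the ano-det predictor restricted to a single hash
  table (p = 1), a generic one-table LSH comparator.

Timing is recorded per stage but never asserted against absolute
numbers; it is hardware-dependent.
"""

from __future__ import annotations

import time
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .clustering import detect_anomalies, similarity_matrix, threshold_graph
from .data_model import HealthTensor, RunConfig
from .errors import ValidationError
from .lsh import IndexTable, build_index, projection_planes, subset_index
from .synthetic import GeneratorConfig, HeldOutEntry, generate_cohort, mask_entries

__all__ = [
    "EvalReport",
    "mae",
    "rmse",
    "predict_heldout_anodet",
    "predict_heldout_ucf",
    "run_profile",
    "reports_to_frame",
]

REPORT_COLUMNS = [
    "method",
    "p",
    "q",
    "T",
    "seed",
    "mae",
    "rmse",
    "n_heldout",
    "index_seconds",
    "predict_seconds",
    "n_anomalies",
]


def mae(predictions: Sequence[float], truths: Sequence[float]) -> float:
    predictions, truths = _paired(predictions, truths)
    return float(np.mean(np.abs(predictions - truths)))


def rmse(predictions: Sequence[float], truths: Sequence[float]) -> float:
    predictions, truths = _paired(predictions, truths)
    return float(np.sqrt(np.mean((predictions - truths) ** 2)))


def _paired(predictions, truths) -> tuple[np.ndarray, np.ndarray]:
    predictions = np.asarray(predictions, dtype=np.float64)
    truths = np.asarray(truths, dtype=np.float64)
    if predictions.shape != truths.shape or predictions.ndim != 1:
        raise ValidationError(
            f"predictions and truths must be equal-length 1-d sequences, "
            f"got shapes {predictions.shape} and {truths.shape}"
        )
    if predictions.size == 0:
        raise ValidationError("error metrics need at least one pair")
    return predictions, truths


def _heldout_arrays(
    tensor: HealthTensor, heldout: Sequence[HeldOutEntry]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    s_pos = {s: i for i, s in enumerate(tensor.student_ids)}
    c_pos = {c: j for j, c in enumerate(tensor.criterion_ids)}
    try:
        ii = np.array([s_pos[h.student_id] for h in heldout], dtype=np.int64)
        jj = np.array([c_pos[h.criterion_id] for h in heldout], dtype=np.int64)
    except KeyError as exc:
        raise ValidationError(f"held-out entry names unknown id {exc}") from exc
    kk = np.array([h.time_index for h in heldout], dtype=np.int64)
    if (kk < 0).any() or (kk >= tensor.num_timepoints).any():
        raise ValidationError("held-out time index out of range")
    if tensor.observed_mask()[ii, jj, kk].any():
        raise ValidationError("held-out triples must be unobserved in the masked tensor")
    return ii, jj, kk


def _fallback_means(tensor: HealthTensor) -> tuple[np.ndarray, float]:
    """Per-(criterion, time) observed cohort means, global mean where empty."""
    mask = tensor.observed_mask()
    if not mask.any():
        raise ValidationError("tensor has no observed entries")
    sums = np.where(mask, tensor.values, 0.0).sum(axis=0)
    counts = mask.sum(axis=0)
    global_mean = float(tensor.values[mask].mean())
    cohort = np.where(counts > 0, sums / np.maximum(counts, 1), global_mean)
    return cohort, global_mean


def predict_heldout_anodet(
    masked: HealthTensor,
    index: IndexTable,
    T: int,
    heldout: Sequence[HeldOutEntry],
) -> np.ndarray:
    """Neighbor-mean predictions for the held-out entries.

    ``index`` must have been built from the masked tensor, so that the
    hash never sees the hidden values.
    """
    if list(index.student_ids) != list(masked.student_ids):
        raise ValidationError("index and tensor disagree on the student set")
    ii, jj, kk = _heldout_arrays(masked, heldout)
    graph = threshold_graph(similarity_matrix(index), T)
    pos = {s: i for i, s in enumerate(masked.student_ids)}
    neighbors = {
        i: np.array([pos[v] for v in graph.graph.neighbors(s)], dtype=np.int64)
        for i, s in enumerate(masked.student_ids)
    }
    cohort_mean, _ = _fallback_means(masked)
    mask = masked.observed_mask()
    vals = np.where(mask, masked.values, 0.0)

    preds = np.empty(len(heldout), dtype=np.float64)
    for i in np.unique(ii):
        rows = np.flatnonzero(ii == i)
        j, k = jj[rows], kk[rows]
        nb = neighbors[int(i)]
        if nb.size:
            counts = mask[nb][:, j, k].sum(axis=0)
            sums = vals[nb][:, j, k].sum(axis=0)
            preds[rows] = np.where(
                counts > 0, sums / np.maximum(counts, 1), cohort_mean[j, k]
            )
        else:
            preds[rows] = cohort_mean[j, k]
    return preds


def student_correlations(masked: HealthTensor) -> np.ndarray:
    """Pairwise Pearson correlation over co-observed flattened entries.

    Pairs with fewer than two co-observed entries or zero variance get
    correlation 0 (treated as uninformative).  Computed with masked
    cross-product sums so the cost stays O(N^2 * M * K) in BLAS.
    """
    n = masked.n_students
    w = masked.observed_mask().reshape(n, -1).astype(np.float64)
    x = np.where(masked.observed_mask(), masked.values, 0.0).reshape(n, -1)
    n_ab = w @ w.T
    sx = x @ w.T
    sxy = x @ x.T
    sxx = (x * x) @ w.T
    cov = n_ab * sxy - sx * sx.T
    var_a = n_ab * sxx - sx**2
    var_b = var_a.T
    denom_sq = var_a * var_b
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where((denom_sq > 0) & (n_ab >= 2), cov / np.sqrt(np.maximum(denom_sq, 1e-300)), 0.0)
    np.fill_diagonal(r, 0.0)
    return np.clip(r, -1.0, 1.0)


def predict_heldout_ucf(
    masked: HealthTensor,
    heldout: Sequence[HeldOutEntry],
    k_neighbors: int = 10,
) -> np.ndarray:
    """User-based collaborative filtering predictions on the raw tensor."""
    if k_neighbors < 1:
        raise ValidationError(f"k_neighbors must be >= 1, got {k_neighbors}")
    ii, jj, kk = _heldout_arrays(masked, heldout)
    r = student_correlations(masked)
    cohort_mean, _ = _fallback_means(masked)
    mask = masked.observed_mask()

    preds = np.empty(len(heldout), dtype=np.float64)
    for row, (i, j, k) in enumerate(zip(ii, jj, kk)):
        weights = r[i] * mask[:, j, k]
        candidates = np.flatnonzero(weights > 0)
        if candidates.size:
            top = candidates[np.argsort(weights[candidates])[::-1][:k_neighbors]]
            w = weights[top]
            preds[row] = float(np.dot(w, masked.values[top, j, k]) / w.sum())
        else:
            preds[row] = cohort_mean[j, k]
    return preds


@dataclass
class EvalReport:
    """One (method, grid point, seed) evaluation outcome."""

    method: str
    p: int
    q: int
    T: int
    seed: int
    mae: float
    rmse: float
    n_heldout: int
    index_seconds: float
    predict_seconds: float
    n_anomalies: int

    def __post_init__(self):
        if self.rmse + 1e-12 < self.mae:
            raise ValidationError(
                f"rmse ({self.rmse}) < mae ({self.mae}); inconsistent report"
            )


def reports_to_frame(reports: Iterable[EvalReport]) -> pd.DataFrame:
    frame = pd.DataFrame([vars(rep) for rep in reports])
    return frame[REPORT_COLUMNS] if len(frame) else pd.DataFrame(columns=REPORT_COLUMNS)


def run_profile(
    grid: Sequence[tuple[int, int, int]],
    gen_config: GeneratorConfig,
    mask_fraction: float,
    seeds: Sequence[int],
    methods: Sequence[str] = ("ano-det", "ucf"),
) -> list[EvalReport]:
    """Run the full simulate/mask/index/predict/score loop over a grid.

    ``grid`` is a sequence of (p, q, T) triples.  For each seed a cohort
    is generated (generator seed = ``gen_config.seed + seed``), masked,
    and evaluated at every grid point with every requested method.  The
    hash index for a seed is built once at the largest (p, q) on the grid
    and subset per point, which is exact because hyperplane substreams
    are keyed per (table, repetition).
    """
    unknown = set(methods) - {"ano-det", "ucf", "brute-lsh"}
    if unknown:
        raise ValidationError(f"unknown evaluation methods: {sorted(unknown)}")
    grid = [(int(p), int(q), int(T)) for p, q, T in grid]
    for p, q, T in grid:
        RunConfig(p=p, q=q, T=T)  # validates 1 <= T <= q

    reports: list[EvalReport] = []
    p_max = max(p for p, _, _ in grid)
    q_max = max(q for _, q, _ in grid)
    for seed in seeds:
        cohort = generate_cohort(
            GeneratorConfig(**{**vars(gen_config), "seed": gen_config.seed + seed})
        )
        masked, heldout = mask_entries(cohort, mask_fraction, seed=seed)
        truths = np.array([h.true_value for h in heldout])

        t0 = time.perf_counter()
        full_index = build_index(
            masked, RunConfig(p=p_max, q=q_max, T=1, seed=seed)
        )
        full_index_seconds = time.perf_counter() - t0

        ucf_preds: np.ndarray | None = None
        for p, q, T in grid:
            index = subset_index(full_index, p, q)
            graph = threshold_graph(similarity_matrix(index), T)
            n_anomalies = len(detect_anomalies(graph, p=p, seed=seed).anomalies)
            for method in methods:
                t0 = time.perf_counter()
                if method == "ano-det":
                    preds = predict_heldout_anodet(masked, index, T, heldout)
                    idx_secs = full_index_seconds * (p * q) / (p_max * q_max)
                elif method == "brute-lsh":
                    preds = predict_heldout_anodet(
                        masked, subset_index(full_index, 1, q), T, heldout
                    )
                    idx_secs = full_index_seconds * q / (p_max * q_max)
                else:
                    if ucf_preds is None:
                        ucf_preds = predict_heldout_ucf(masked, heldout)
                    preds = ucf_preds
                    idx_secs = 0.0
                predict_seconds = time.perf_counter() - t0
                reports.append(
                    EvalReport(
                        method=method,
                        p=p,
                        q=q,
                        T=T,
                        seed=int(seed),
                        mae=mae(preds, truths),
                        rmse=rmse(preds, truths),
                        n_heldout=len(heldout),
                        index_seconds=idx_secs,
                        predict_seconds=predict_seconds,
                        n_anomalies=n_anomalies,
                    )
                )
    return reports
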