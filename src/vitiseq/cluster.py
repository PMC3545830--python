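"""Profile normalization and run-stability-checked k-means clustering.

Normalization mirrors the classic Cluster 3.0 preprocessing: transcripts
with RPKM below 0.5 at every stage are discarded; each remaining 4-stage row
is multiplied by a scale factor so its sum of squares is exactly 1 (placing
values in [-1, 1]); rows are then centered by subtracting their mean; and
rows whose normalized max-minus-min range falls below 0.5 are filtered out
as insufficiently regulated. Centering does not change a row's range, so
the range filter reads the same before and after that step.

Clustering is plain Lloyd k-means with Euclidean distance, restarted from
many random initializations (k distinct profiles per run). Restarts are
grouped by their final objective value; the best solution is reported
together with how many runs reached it — a solution found only once in a
thousand runs is a fragile optimum, and the result carries that diagnostic
(with a warning below the required repeat count) rather than failing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError


def scale_to_unit_sum_of_squares(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-scale so each row's sum of squares is 1; returns (scaled, factors)."""
    values = np.asarray(values, dtype=float)
    norms = np.sqrt((values**2).sum(axis=-1, keepdims=True))
    if (norms == 0).any():
        raise DataError("cannot scale an all-zero profile")
    return values / norms, 1.0 / norms.squeeze(-1)


def scale_center(values: np.ndarray) -> np.ndarray:
    """The full normalization applied to one or more rows: scale then center."""
    scaled, _ = scale_to_unit_sum_of_squares(np.atleast_2d(np.asarray(values, float)))
    out = scaled - scaled.mean(axis=1, keepdims=True)
    return out if np.asarray(values).ndim > 1 else out[0]


def normalize_and_filter(
    rpkm: pd.DataFrame,
    *,
    all_low_floor: float = 0.5,
    min_range: float = 0.5,
    range_on_normalized: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Normalize 4-stage profiles and filter for differential regulation.

    Returns
    -------
    (profiles, report)
        ``profiles``: normalized values for kept transcripts only.
        ``report``: one row per input transcript with scale_factor, kept
        flag and reason (``all_low`` / ``low_range`` / ``kept``).
    """
    values = rpkm.to_numpy(dtype=float)
    if values.shape[1] != 4:
        raise DataError(f"expected 4 stage columns, got {values.shape[1]}")
    reason = np.full(len(rpkm), "kept", dtype=object)
    scale_factor = np.full(len(rpkm), np.nan)

    all_low = (values < all_low_floor).all(axis=1)
    reason[all_low] = "all_low"

    normalized = np.full_like(values, np.nan)
    live = ~all_low
    if live.any():
        if (values[live] ** 2).sum(axis=1).min() == 0:
            # unreachable when all_low_floor > 0; defensive per contract
            raise DataError("all-zero profile survived the all-low filter")
        scaled, factors = scale_to_unit_sum_of_squares(values[live])
        scale_factor[live] = factors
        normalized[live] = scaled - scaled.mean(axis=1, keepdims=True)
        span_source = normalized[live] if range_on_normalized else values[live]
        span = span_source.max(axis=1) - span_source.min(axis=1)
        low_range = np.flatnonzero(live)[span < min_range]
        reason[low_range] = "low_range"

    kept = reason == "kept"
    profiles = pd.DataFrame(
        normalized[kept], index=rpkm.index[kept], columns=rpkm.columns
    )
    report = pd.DataFrame(
        {
            "transcript_id": rpkm.index,
            "scale_factor": scale_factor,
            "kept": kept,
            "reason": reason,
        }
    ).reset_index(drop=True)
    return profiles, report


@dataclass
class ClusterResult:
    """Outcome of a stability-checked k-means run."""

    k: int
    assignments: pd.Series  # transcript_id -> cluster index
    centroids: np.ndarray  # k x 4
    n_runs: int
    best_objective: float
    times_found: int
    archetype_labels: dict[int, str] = field(default_factory=dict)


def _lloyd(
    X: np.ndarray, k: int, rng: np.random.Generator, max_iter: int = 300
) -> tuple[np.ndarray, np.ndarray, float, list[float]]:
    """One k-means run from a random k-distinct-profiles initialization.

    Empty clusters are re-seeded with the point farthest from its current
    centroid. Returns (assignments, centroids, objective, objective trace);
    the trace is non-increasing across iterations.
    """
    n, d = X.shape
    centroids = X[rng.choice(n, size=k, replace=False)].astype(float).copy()
    assign = np.full(n, -1)
    history: list[float] = []
    x_sq = (X**2).sum(axis=1)
    rows = np.arange(n)
    for _ in range(max_iter):
        d2 = x_sq[:, None] - 2.0 * (X @ centroids.T) + (centroids**2).sum(axis=1)
        new_assign = d2.argmin(axis=1)
        counts = np.bincount(new_assign, minlength=k)
        if (counts == 0).any():
            dmin = d2[rows, new_assign]
            for j in np.flatnonzero(counts == 0):
                far = int(dmin.argmax())
                centroids[j] = X[far]
                new_assign[far] = j
                dmin[far] = 0.0
            counts = np.bincount(new_assign, minlength=k)
        if (new_assign == assign).all():
            break
        assign = new_assign
        for dim in range(d):
            centroids[:, dim] = (
                np.bincount(assign, weights=X[:, dim], minlength=k) / counts
            )
        history.append(float(((X - centroids[assign]) ** 2).sum()))
    objective = history[-1] if history else float(((X - centroids[assign]) ** 2).sum())
    return assign, centroids, objective, history


def kmeans_stable(
    profiles: pd.DataFrame,
    k: int = 20,
    n_runs: int = 1000,
    required_repeats: int = 3,
    seed: int = 0,
    *,
    max_iter: int = 300,
    objective_rtol: float = 1e-8,
) -> ClusterResult:
    """Restarted k-means reporting the best solution and its reproducibility.

    ``times_found`` counts restarts whose final objective matches the best
    one to ``objective_rtol`` relative tolerance (the criterion Cluster 3.0
    uses when reporting that a solution was "found N times"). A count below
    ``required_repeats`` triggers a warning, not an error.
    """
    if k < 1:
        raise ConfigurationError(f"k must be >= 1, got {k}")
    if n_runs < 1:
        raise ConfigurationError(f"n_runs must be >= 1, got {n_runs}")
    X = profiles.to_numpy(dtype=float)
    if len(X) < k:
        raise ConfigurationError(
            f"{len(X)} profiles is fewer than k={k} clusters"
        )
    rng = np.random.default_rng(seed)
    best: tuple[float, np.ndarray, np.ndarray] | None = None
    objectives = np.empty(n_runs)
    for run in range(n_runs):
        assign, centroids, objective, _ = _lloyd(X, k, rng, max_iter)
        objectives[run] = objective
        if best is None or objective < best[0]:
            best = (objective, assign, centroids)
    assert best is not None
    best_obj, assign, centroids = best
    tol = objective_rtol * max(1.0, abs(best_obj))
    times_found = int((objectives <= best_obj + tol).sum())
    if times_found < required_repeats:
        warnings.warn(
            f"best k-means objective {best_obj:.6g} reached in only "
            f"{times_found}/{n_runs} runs (required {required_repeats})",
            stacklevel=2,
        )
    return ClusterResult(
        k=k,
        assignments=pd.Series(assign, index=profiles.index, name="cluster"),
        centroids=centroids,
        n_runs=n_runs,
        best_objective=best_obj,
        times_found=times_found,
    )


def label_archetypes(
    result: ClusterResult,
    templates: dict[str, tuple[float, float, float, float]] | None = None,
    min_correlation: float = 0.8,
) -> ClusterResult:
    """Label each centroid with its best-correlating archetype template.

    Templates are normalized with the same scale-then-center procedure as
    the profiles. A centroid is labeled with the template of highest Pearson
    correlation when that correlation reaches ``min_correlation``, else
    "unlabeled"; exact ties break alphabetically by template name. Labels
    need not be unique across clusters.
    """
    if templates is None:
        from .simulate import ARCHETYPE_TEMPLATES

        templates = ARCHETYPE_TEMPLATES
    if not templates:
        raise ConfigurationError("template set is empty")
    normalized = {name: scale_center(np.asarray(vec, float)) for name, vec in templates.items()}
    labels: dict[int, str] = {}
    for j in range(result.k):
        centroid = result.centroids[j]
        best_name, best_corr = "unlabeled", -np.inf
        for name in sorted(normalized):
            template = normalized[name]
            if np.ptp(centroid) == 0 or np.ptp(template) == 0:
                continue
            corr = float(np.corrcoef(centroid, template)[0, 1])
            if corr > best_corr:
                best_name, best_corr = name, corr
        labels[j] = best_name if best_corr >= min_correlation else "unlabeled"
    return replace(result, archetype_labels=labels)
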