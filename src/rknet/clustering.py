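"""From-scratch K-means (k = 2 by default) for separating tumor-level slices
from irrelevant ones.

The model minimizes the within-cluster sum of squared Euclidean distances

    E = sum_i sum_{x in C_i} ||x - mu_i||^2,

alternating nearest-centroid assignment with the centroid mean update
mu_i = (1/|C_i|) * sum_{x in C_i} x (Lloyd iterations). All policies that the
objective leaves open are pinned down explicitly:

* initialization: k-means++ by default, plain random rows selectable;
  ``n_restarts`` independent runs, best final E kept (ties: earliest run);
* nearest-centroid ties: lowest cluster index;
* empty clusters: the centroid is reseeded at the point farthest from its
  currently assigned centroid, keeping all k clusters populated;
* convergence: assignment fixed point, or |delta E| <= tol, or max_iter.

``exhaustive_kmeans`` provides an independent global-optimum oracle for tiny
instances by enumerating set partitions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Set, Tuple

import numpy as np

from .errors import (
    AmbiguousMappingError,
    InvalidAssignmentError,
    InvalidInputError,
    NoExemplarsError,
    OracleCapError,
    TooFewSamplesError,
)
from .features import EDGE_SLICE, GRID_SLICE, VAR_SLICE, FeatureMatrix, SliceKey

logger = logging.getLogger(__name__)

ORACLE_MAX_ASSIGNMENTS = 120_000  # ~ all 2-partitions of n=17; n<=10 for k=2 is well inside


@dataclass
class ClusterModel:
    k: int
    centroids: np.ndarray
    assignments: np.ndarray
    objective: float
    trace: List[float] = field(default_factory=list)
    seed: int = 0
    n_iter: int = 0
    converged: bool = False

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "centroids": self.centroids.tolist(),
            "assignments": self.assignments.tolist(),
            "objective": self.objective,
            "trace": list(self.trace),
            "seed": self.seed,
            "n_iter": self.n_iter,
            "converged": self.converged,
        }


def _as_array(X) -> np.ndarray:
    values = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=np.float64)
    values = np.asarray(values, dtype=np.float64)
    if values.ndim == 1:
        values = values[:, None]
    return values


def _sq_dists(X: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """(n, k) squared Euclidean distances, computed stably via expansion."""
    diff = X[:, None, :] - centroids[None, :, :]
    return np.einsum("nkd,nkd->nk", diff, diff)


def compute_objective(X, centroids: np.ndarray, assignments: Sequence[int]) -> float:
    """E: sum of squared distances of every row to its assigned centroid."""
    values = _as_array(X)
    centroids = np.asarray(centroids, dtype=np.float64)
    labels = np.asarray(assignments, dtype=np.intp)
    if labels.size and (labels.min() < 0 or labels.max() >= centroids.shape[0]):
        raise InvalidAssignmentError("invalid assignment: label out of range")
    diff = values - centroids[labels]
    return float(np.einsum("nd,nd->", diff, diff))


def update_centroids(X, assignments: Sequence[int], k: int,
                     repair_empty: bool = True) -> np.ndarray:
    """Mean vector per cluster; empty clusters reseeded at the point farthest
    from its assigned centroid (or left at the overall mean if repair is off)."""
    values = _as_array(X)
    labels = np.asarray(assignments, dtype=np.intp)
    if labels.size and (labels.min() < 0 or labels.max() >= k):
        raise InvalidAssignmentError("invalid assignment: label out of range")
    d = values.shape[1]
    centroids = np.zeros((k, d))
    counts = np.bincount(labels, minlength=k)
    for i in range(k):
        if counts[i] > 0:
            centroids[i] = values[labels == i].mean(axis=0)
    empty = [i for i in range(k) if counts[i] == 0]
    if empty:
        if not repair_empty:
            overall = values.mean(axis=0)
            for i in empty:
                centroids[i] = overall
        else:
            taken: Set[int] = set()
            for i in empty:
                dist = np.linalg.norm(values - centroids[labels], axis=1)
                for j in sorted(taken):
                    dist[j] = -np.inf
                far = int(np.argmax(dist))
                centroids[i] = values[far]
                taken.add(far)
    return centroids


def _init_centroids(values: np.ndarray, k: int, method: str,
                    rng: np.random.Generator) -> np.ndarray:
    n = values.shape[0]
    if method == "random":
        idx = rng.choice(n, size=k, replace=False)
        return values[idx].copy()
    if method != "k-means++":
        raise InvalidInputError(f"invalid input: unknown init method {method!r}")
    centroids = np.empty((k, values.shape[1]))
    centroids[0] = values[rng.integers(n)]
    d2 = np.einsum("nd,nd->n", values - centroids[0], values - centroids[0])
    for i in range(1, k):
        total = d2.sum()
        if total <= 0:
            centroids[i] = values[rng.integers(n)]
        else:
            centroids[i] = values[rng.choice(n, p=d2 / total)]
        new_d2 = np.einsum("nd,nd->n", values - centroids[i], values - centroids[i])
        d2 = np.minimum(d2, new_d2)
    return centroids


def _lloyd_pass(values: np.ndarray, k: int, assignments: np.ndarray,
                max_iter: int, tol: float, trace: List[float]) -> Tuple[np.ndarray, np.ndarray, int, bool]:
    """Lloyd iterations from the given assignments to a fixed point."""
    converged = False
    n_iter = 0
    prev_e = None
    centroids = update_centroids(values, assignments, k)
    for n_iter in range(1, max_iter + 1):
        centroids = update_centroids(values, assignments, k)
        new_assignments = np.argmin(_sq_dists(values, centroids), axis=1)
        e = compute_objective(values, centroids, new_assignments)
        trace.append(e)
        if np.array_equal(new_assignments, assignments):
            converged = True
            break
        assignments = new_assignments
        if prev_e is not None and abs(prev_e - e) <= tol:
            # E has plateaued; settle on the mean-centroid fixed point for
            # the current assignments so centroid == cluster mean holds.
            centroids = update_centroids(values, assignments, k)
            e = compute_objective(values, centroids, assignments)
            trace.append(e)
            converged = True
            break
        prev_e = e
    return centroids, assignments, n_iter, converged


def _single_point_moves(values: np.ndarray, assignments: np.ndarray, k: int) -> bool:
    """One sweep of exact single-point reassignments (Hartigan moves).

    Moving row x from cluster a (size n_a) to b changes E by exactly
    n_b/(n_b+1) * ||x - mu_b||^2 - n_a/(n_a-1) * ||x - mu_a||^2; any strictly
    improving move is applied. Lloyd fixed points are not always stable under
    these moves, so a sweep can escape local optima Lloyd cannot, while still
    strictly decreasing the same objective. Returns True if anything moved.
    """
    n = values.shape[0]
    counts = np.bincount(assignments, minlength=k).astype(float)
    sums = np.zeros((k, values.shape[1]))
    for i in range(k):
        if counts[i]:
            sums[i] = values[assignments == i].sum(axis=0)
    moved = False
    for idx in range(n):
        a = int(assignments[idx])
        if counts[a] <= 1:
            continue
        x = values[idx]
        mu_a = sums[a] / counts[a]
        loss_a = counts[a] / (counts[a] - 1) * np.dot(x - mu_a, x - mu_a)
        best_b, best_delta = -1, -1e-12
        for b in range(k):
            if b == a:
                continue
            mu_b = sums[b] / counts[b] if counts[b] else x
            gain_b = counts[b] / (counts[b] + 1) * np.dot(x - mu_b, x - mu_b)
            delta = gain_b - loss_a
            if delta < best_delta:
                best_delta, best_b = delta, b
        if best_b >= 0:
            assignments[idx] = best_b
            sums[a] -= x
            counts[a] -= 1
            sums[best_b] += x
            counts[best_b] += 1
            moved = True
    return moved


def _lloyd(values: np.ndarray, k: int, init: str, rng: np.random.Generator,
           max_iter: int, tol: float) -> Tuple[np.ndarray, np.ndarray, float, List[float], int, bool]:
    centroids = _init_centroids(values, k, init, rng)
    assignments = np.argmin(_sq_dists(values, centroids), axis=1)
    trace: List[float] = []
    total_iter = 0
    converged = False
    # alternate Lloyd passes with exact single-point refinement until both
    # are stable (or the iteration budget runs out)
    for _ in range(max_iter):
        centroids, assignments, n_iter, converged = _lloyd_pass(
            values, k, assignments, max_iter - total_iter, tol, trace)
        total_iter += n_iter
        if not converged or total_iter >= max_iter:
            break
        if not _single_point_moves(values, assignments, k):
            break
        converged = False
    centroids = update_centroids(values, assignments, k)
    e = compute_objective(values, centroids, assignments)
    if not trace or e < trace[-1]:
        trace.append(e)
    return centroids, assignments, trace[-1], trace, total_iter, converged


def kmeans_fit(X, k: int = 2, init_method: str = "k-means++", seed: int = 0,
               max_iter: int = 300, tol: float = 1e-6, n_restarts: int = 10) -> ClusterModel:
    """Fit K-means by Lloyd iterations; best of ``n_restarts`` runs by final E.

    Deterministic given (X, k, init_method, seed): restart r uses the
    generator seeded with (seed, r).
    """
    values = _as_array(X)
    if not np.all(np.isfinite(values)):
        raise InvalidInputError("invalid input: non-finite feature values")
    n = values.shape[0]
    if k < 1 or max_iter < 1 or tol < 0:
        raise InvalidInputError("invalid input: k >= 1, max_iter >= 1, tol >= 0 required")
    if n < k:
        raise TooFewSamplesError(f"too few samples: n={n} < k={k}")

    best = None
    for r in range(max(1, n_restarts)):
        rng = np.random.default_rng([seed, r])
        result = _lloyd(values, k, init_method, rng, max_iter, tol)
        if best is None or result[2] < best[2] - 1e-15:
            best = result

    centroids, assignments, objective, trace, n_iter, converged = best
    return ClusterModel(
        k=k,
        centroids=centroids,
        assignments=assignments.astype(np.intp),
        objective=objective,
        trace=trace,
        seed=seed,
        n_iter=n_iter,
        converged=converged,
    )


def _partitions(n: int, k: int) -> Iterable[np.ndarray]:
    """Restricted-growth strings: canonical labelings of n items into <= k
    non-empty blocks (block j first appears only after block j-1)."""
    labels = np.zeros(n, dtype=np.intp)

    def rec(i: int, max_used: int):
        if i == n:
            yield labels.copy()
            return
        for lab in range(min(max_used + 1, k - 1) + 1):
            labels[i] = lab
            yield from rec(i + 1, max(max_used, lab))

    yield from rec(1, 0)


def exhaustive_kmeans(X, k: int = 2) -> ClusterModel:
    """Globally optimal clustering by brute-force partition enumeration.

    Independent of the Lloyd path: every canonical assignment of rows to at
    most k blocks is scored with mean centroids, and the minimum-E one wins;
    ties break toward the lexicographically smallest assignment vector.
    Capped at ~1.2e5 candidate assignments (n <= 10 for k = 2 is fine).
    """
    values = _as_array(X)
    n = values.shape[0]
    if n < k:
        raise TooFewSamplesError(f"too few samples: n={n} < k={k}")
    n_assignments = k ** (n - 1)  # upper bound on canonical labelings
    if n_assignments > ORACLE_MAX_ASSIGNMENTS:
        raise OracleCapError(
            f"oracle cap exceeded: ~{n_assignments} assignments for n={n}, k={k}"
        )

    best_e = np.inf
    best_labels = None
    for labels in _partitions(n, k):
        # partitions into < k blocks are scored too so degenerate inputs
        # (all rows identical) still get an answer
        n_blocks = int(labels.max()) + 1
        centroids = np.zeros((k, values.shape[1]))
        for i in range(n_blocks):
            centroids[i] = values[labels == i].mean(axis=0)
        for i in range(n_blocks, k):
            centroids[i] = centroids[0]
        e = compute_objective(values, centroids, labels)
        if e < best_e - 1e-12 or (abs(e - best_e) <= 1e-12 and
                                  (best_labels is None or _lex_less(labels, best_labels))):
            best_e = e
            best_labels = labels

    labels = best_labels
    # repair label vectors that used fewer than k blocks (identical rows)
    n_blocks = int(labels.max()) + 1
    if n_blocks < k:
        labels = labels.copy()
        free = [i for i in range(n) if np.sum(labels == labels[i]) > 1]
        for extra, idx in zip(range(n_blocks, k), free):
            labels[idx] = extra
    centroids = update_centroids(values, labels, k, repair_empty=True)
    e = compute_objective(values, centroids, labels)
    return ClusterModel(
        k=k, centroids=centroids, assignments=labels.astype(np.intp),
        objective=e, trace=[e], seed=0, n_iter=1, converged=True,
    )


def _lex_less(a: np.ndarray, b: np.ndarray) -> bool:
    for x, y in zip(a, b):
        if x != y:
            return x < y
    return False


RELEVANT = "relevant"
IRRELEVANT = "irrelevant"


def map_clusters_to_relevance(model: ClusterModel, X: FeatureMatrix, rule: str = "foreground-mass",
                              exemplars: Sequence[SliceKey] | None = None) -> Dict[int, str]:
    """Decide which of the two clusters holds the tumor-level slices.

    Rules:
      * ``foreground-mass`` (default): the cluster whose centroid carries
        more mean intensity / edge energy / local variance in the reference
        extractor's GRID+EDGE+VAR coordinate blocks is relevant. Only valid
        for reference-extractor features.
      * ``exemplar``: the cluster containing the majority of the supplied
        known-relevant slice keys is relevant; ties are an error.
      * ``majority-size``: the smaller cluster is relevant (tumor-level runs
        are a minority of a stack); discouraged, logs a warning.
    """
    if model.k != 2:
        raise InvalidInputError("invalid input: relevance mapping requires k=2")

    if rule == "foreground-mass":
        if X.extractor_name != "reference":
            raise InvalidInputError(
                "invalid input: foreground-mass rule needs reference-extractor features"
            )
        scores = [
            float(model.centroids[i][GRID_SLICE].mean()
                  + model.centroids[i][EDGE_SLICE].mean()
                  + model.centroids[i][VAR_SLICE].mean())
            for i in range(2)
        ]
        rel = 0 if scores[0] >= scores[1] else 1
    elif rule == "exemplar":
        if not exemplars:
            raise NoExemplarsError("no exemplars: exemplar rule needs >=1 exemplar key")
        key_to_row = {key: i for i, key in enumerate(X.row_keys)}
        counts = [0, 0]
        for key in exemplars:
            row = key_to_row.get(tuple(key))
            if row is not None:
                counts[int(model.assignments[row])] += 1
        if sum(counts) == 0:
            raise NoExemplarsError("no exemplars: none of the exemplar keys are in the data")
        if counts[0] == counts[1]:
            raise AmbiguousMappingError(
                f"ambiguous mapping: exemplar counts tie at {counts[0]}"
            )
        rel = 0 if counts[0] > counts[1] else 1
    elif rule == "majority-size":
        logger.warning("majority-size relevance rule is heuristic; prefer "
                       "foreground-mass or exemplar")
        sizes = np.bincount(model.assignments, minlength=2)
        rel = int(np.argmin(sizes))  # ties -> cluster 0
    else:
        raise InvalidInputError(f"invalid input: unknown mapping rule {rule!r}")

    return {rel: RELEVANT, 1 - rel: IRRELEVANT}
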