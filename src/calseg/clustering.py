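"""Weighted k-medoids (PAM) clustering and cluster-quality metrics.

PAM picks k actual sequences (medoids) minimizing the weighted sum of
distances of every sequence to its nearest medoid: a greedy BUILD phase
seeds the medoids, then SWAP repeatedly applies the best strictly
improving medoid/non-medoid exchange until none exists. Operating on
the deduplicated dissimilarity matrix with aggregated weights is exact:
identical sequences always share a medoid.

Quality metrics for choosing k: weighted average silhouette width
(ASW), point-biserial correlation (PBC) between pairwise distances and
the different-cluster indicator, and Hubert's gamma (HG) over
concordant/discordant (within, between) distance pairs. All three lie
in [-1, 1]; higher is better.

Tie-breaking is everywhere by lowest index, making results
deterministic for a given matrix.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from .distance import DissimilarityMatrix

logger = logging.getLogger(__name__)

SWAP_ITERATION_CAP = 500


@dataclass
class ClusterSolution:
    """A fitted k-medoids partition over the unique sequences."""

    k: int
    medoids: np.ndarray     # (k,) unique-sequence indices, ascending
    assignment: np.ndarray  # (u,) cluster ids 0..k-1 (position in medoids)
    objective: float        # weighted sum of distances to assigned medoid
    iterations: int
    converged: bool = True

    def assignment_for(self, index: np.ndarray) -> np.ndarray:
        """Map the per-unique-sequence assignment back to per-woman labels."""
        return self.assignment[index]


@dataclass
class QualityReport:
    """Metric table over a range of k, with the selected solution."""

    table: pd.DataFrame      # columns: k, ASW, PBC, HG
    selected_k: int | None
    criterion: str
    solutions: dict          # k -> ClusterSolution


@njit(cache=True)
def _pam_build(D, w, k):
    u = D.shape[0]
    medoids = np.empty(k, np.int64)
    # first medoid: minimum weighted total distance, lowest index on ties
    best_j, best_c = 0, np.inf
    for j in range(u):
        c = 0.0
        for i in range(u):
            c += w[i] * D[i, j]
        if c < best_c:
            best_c, best_j = c, j
    medoids[0] = best_j
    near = D[:, best_j].copy()
    for m in range(1, k):
        best_j, best_gain = -1, -np.inf
        for j in range(u):
            taken = False
            for t in range(m):
                if medoids[t] == j:
                    taken = True
            if taken:
                continue
            gain = 0.0
            for i in range(u):
                diff = near[i] - D[i, j]
                if diff > 0.0:
                    gain += w[i] * diff
            if gain > best_gain:
                best_gain, best_j = gain, j
        medoids[m] = best_j
        for i in range(u):
            if D[i, best_j] < near[i]:
                near[i] = D[i, best_j]
    return medoids


@njit(cache=True)
def _nearest_two(D, medoids):
    u = D.shape[0]
    k = medoids.shape[0]
    n1 = np.empty(u, np.int64)
    d1 = np.empty(u)
    d2 = np.empty(u)
    for i in range(u):
        b1, b2 = np.inf, np.inf
        bi = -1
        for t in range(k):
            d = D[i, medoids[t]]
            if d < b1:
                b2 = b1
                b1 = d
                bi = t
            elif d < b2:
                b2 = d
        n1[i] = bi
        d1[i] = b1
        d2[i] = b2
    return n1, d1, d2


@njit(cache=True)
def _pam_swap(D, w, medoids, max_iter):
    u = D.shape[0]
    k = medoids.shape[0]
    iterations = 0
    converged = False
    while iterations < max_iter:
        n1, d1, d2 = _nearest_two(D, medoids)
        best_delta = -1e-12
        best_t, best_h = -1, -1
        for t in range(k):
            for h in range(u):
                taken = False
                for s in range(k):
                    if medoids[s] == h:
                        taken = True
                if taken:
                    continue
                delta = 0.0
                for i in range(u):
                    dih = D[i, h]
                    if n1[i] == t:
                        nd = dih if dih < d2[i] else d2[i]
                        delta += w[i] * (nd - d1[i])
                    elif dih < d1[i]:
                        delta += w[i] * (dih - d1[i])
                if delta < best_delta:
                    best_delta = delta
                    best_t, best_h = t, h
        if best_t < 0:
            converged = True
            break
        medoids[best_t] = best_h
        iterations += 1
    return iterations, converged


def _farthest_seed(D: np.ndarray, w: np.ndarray, k: int) -> np.ndarray:
    """Deterministic spread seeding: weighted-most-central point, then
    repeatedly the point farthest from the chosen set."""
    med = [int((w[:, None] * D).sum(axis=0).argmin())]
    for _ in range(k - 1):
        dmin = D[:, med].min(axis=1)
        dmin[med] = -1.0
        med.append(int(dmin.argmax()))
    return np.array(med, dtype=np.int64)


def pam(dissim: DissimilarityMatrix, k: int, seed: int | None = None) -> ClusterSolution:
    """Weighted PAM on the deduplicated matrix.

    SWAP (best strictly-improving medoid/non-medoid exchange, steepest
    descent) is a local search, so it is run from three deterministic
    seedings - greedy BUILD, farthest-point spread, and the k
    largest-weight sequences - and the lowest-objective result is kept
    (BUILD wins ties). Deterministic: seedings are deterministic and all
    ties break to the lowest index, so ``seed`` is accepted for
    interface symmetry but unused.
    """
    D = np.ascontiguousarray(dissim.values, dtype=np.float64)
    w = np.ascontiguousarray(dissim.agg_weights, dtype=np.float64)
    u = D.shape[0]
    if not 1 <= k <= u:
        raise ValueError(f"k={k} outside [1, {u}]")

    starts = (
        _pam_build(D, w, k),
        _farthest_seed(D, w, k),
        np.sort(np.argsort(-w, kind="stable")[:k]).astype(np.int64),
    )
    best = None
    for start in starts:
        medoids = start.copy()
        iterations, converged = _pam_swap(D, w, medoids, SWAP_ITERATION_CAP)
        obj = float(np.sum(w * D[:, medoids].min(axis=1)))
        if best is None or obj < best[0] - 1e-12:
            best = (obj, medoids, iterations, converged)
    _, medoids, iterations, converged = best
    if not converged:
        logger.warning("PAM swap hit the %d-iteration cap", SWAP_ITERATION_CAP)
    order = np.argsort(medoids)
    medoids = medoids[order]
    # nearest-medoid assignment, lowest medoid index on ties
    dmat = D[:, medoids]
    assignment = np.argmin(dmat, axis=1)
    assignment[medoids] = np.arange(k)  # each medoid belongs to itself
    objective = float(np.sum(w * dmat[np.arange(u), assignment]))
    return ClusterSolution(
        k=k,
        medoids=medoids,
        assignment=assignment,
        objective=objective,
        iterations=iterations,
        converged=converged,
    )


def silhouette(dissim: DissimilarityMatrix, solution: ClusterSolution) -> np.ndarray:
    """Weighted silhouette width per unique sequence.

    a_i is the weighted mean distance to the sequence's own cluster with
    its own weight mass excluded from the denominator; b_i the smallest
    weighted mean distance to another cluster. Sequences whose cluster
    carries no other weight (singletons) get width 0.
    """
    if solution.k < 2:
        raise ValueError("silhouette requires k >= 2")
    D = dissim.values
    w = dissim.agg_weights
    assign = solution.assignment
    u = D.shape[0]
    k = solution.k
    # weighted sums of distances to each cluster: (u, k)
    member = np.zeros((u, k))
    member[np.arange(u), assign] = 1.0
    sums = D @ (member * w[:, None])
    cluster_w = member.T @ w  # (k,)
    widths = np.zeros(u)
    for i in range(u):
        c = assign[i]
        own_mass = cluster_w[c] - w[i]
        if own_mass <= 0:
            continue  # singleton: width 0
        a = sums[i, c] / own_mass
        b = np.inf
        for other in range(k):
            if other == c or cluster_w[other] <= 0:
                continue
            b = min(b, sums[i, other] / cluster_w[other])
        denom = max(a, b)
        widths[i] = 0.0 if denom == 0 else (b - a) / denom
    return widths


def _condensed(dissim: DissimilarityMatrix, solution: ClusterSolution):
    """Pairwise (distance, same-cluster, weight) triplets over unique pairs."""
    u = dissim.n_unique
    iu, ju = np.triu_indices(u, k=1)
    d = dissim.values[iu, ju]
    same = solution.assignment[iu] == solution.assignment[ju]
    pw = dissim.agg_weights[iu] * dissim.agg_weights[ju]
    return d, same, pw


def quality_metrics(dissim: DissimilarityMatrix, solution: ClusterSolution):
    """(ASW, PBC, HG) for one solution; 0 with a warning when degenerate."""
    if solution.k < 2:
        raise ValueError("quality metrics require k >= 2")
    w = dissim.agg_weights
    asw = float(np.sum(w * silhouette(dissim, solution)) / w.sum())

    d, same, pw = _condensed(dissim, solution)
    if d.size == 0 or np.all(d == d[0]):
        warnings.warn("degenerate dissimilarity matrix (all distances equal); "
                      "PBC and HG defined as 0")
        return asw, 0.0, 0.0

    # point-biserial: weighted Pearson corr(distance, 1[different cluster])
    y = (~same).astype(np.float64)
    wsum = pw.sum()
    dx = d - np.sum(pw * d) / wsum
    dy = y - np.sum(pw * y) / wsum
    denom = np.sqrt(np.sum(pw * dx * dx) * np.sum(pw * dy * dy))
    if denom == 0:
        warnings.warn("degenerate partition for PBC; defined as 0")
        pbc = 0.0
    else:
        pbc = float(np.sum(pw * dx * dy) / denom)

    # Hubert's gamma over weighted (within, between) distance-pair comparisons
    dw, ww = d[same], pw[same]
    db, wb = d[~same], pw[~same]
    if dw.size == 0 or db.size == 0:
        warnings.warn("no within- or no between-cluster pairs; HG defined as 0")
        hg = 0.0
    else:
        order = np.argsort(db, kind="stable")
        db_sorted = db[order]
        cum = np.concatenate([[0.0], np.cumsum(wb[order])])
        total_b = cum[-1]
        lo = np.searchsorted(db_sorted, dw, side="left")
        hi = np.searchsorted(db_sorted, dw, side="right")
        w_less = cum[lo]            # between-pairs strictly smaller (discordant)
        w_greater = total_b - cum[hi]  # strictly larger (concordant)
        s_plus = float(np.sum(ww * w_greater))
        s_minus = float(np.sum(ww * w_less))
        hg = 0.0 if s_plus + s_minus == 0 else (s_plus - s_minus) / (s_plus + s_minus)
    return asw, pbc, hg


def select_k(
    dissim: DissimilarityMatrix,
    k_range,
    criterion: str = "ASW",
    seed: int | None = None,
) -> QualityReport:
    """Fit PAM for each k, report ASW/PBC/HG, select the criterion argmax.

    Abstains (``selected_k=None``, warning) when the matrix is
    degenerate - e.g. a single archetype with no noise, where every
    split is arbitrary.
    """
    k_range = list(k_range)
    if not k_range:
        raise ValueError("empty k range")
    if criterion not in ("ASW", "PBC", "HG"):
        raise ValueError(f"unknown criterion {criterion!r}")
    u = dissim.n_unique
    if u == 1:
        warnings.warn("only one unique sequence; abstaining from k selection")
        return QualityReport(
            table=pd.DataFrame(columns=["k", "ASW", "PBC", "HG"]),
            selected_k=None, criterion=criterion, solutions={},
        )
    if any(k < 2 or k > u - 1 for k in k_range):
        raise ValueError(f"k range must lie within [2, {u - 1}]")

    off = dissim.values[~np.eye(u, dtype=bool)]
    degenerate = off.size == 0 or np.all(off == off[0])

    rows, solutions = [], {}
    for k in k_range:
        sol = pam(dissim, k, seed=seed)
        asw, pbc, hg = quality_metrics(dissim, sol)
        rows.append({"k": k, "ASW": asw, "PBC": pbc, "HG": hg})
        solutions[k] = sol
    table = pd.DataFrame(rows)
    if degenerate:
        warnings.warn("degenerate dissimilarity matrix; abstaining from k selection")
        selected = None
    else:
        selected = int(table.loc[table[criterion].idxmax(), "k"])
    logger.info("select_k: criterion=%s selected=%s", criterion, selected)
    return QualityReport(table=table, selected_k=selected,
                         criterion=criterion, solutions=solutions)
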