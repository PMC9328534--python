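"""Optimal-matching (OM) distances between state sequences.

OM distance is the minimum total cost of substitutions and
insertions/deletions transforming one sequence into another, the
standard edit distance of social sequence analysis. The analysis uses a
*constant* cost scheme (all substitutions equally costly); defaults are
the canonical substitution cost 2 with indel cost 1.

Identical sequences are deduplicated before the O(u^2 L^2) dynamic
program and their survey weights summed, which is exact for every
weighted computation downstream.

For constant schemes with substitution >= 2*indel (the default), the OM
distance between equal-length sequences reduces to
``indel * (|a| + |b| - 2*LCS(a, b))``: a substitution never beats a
delete+insert pair, so an optimal alignment only matches and indels.
The pairwise kernel exploits this with a bit-parallel longest-common-
subsequence routine; the general dynamic program remains the defining
implementation and the two are cross-checked in the test suite.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass

import numpy as np
from numba import njit

from .states import N_STATES, SEQ_LENGTH

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CostScheme:
    """Substitution matrix (symmetric, zero diagonal) plus indel cost."""

    substitution: np.ndarray  # (5, 5) nonnegative
    indel: float

    def __post_init__(self) -> None:
        sub = np.asarray(self.substitution, dtype=np.float64)
        object.__setattr__(self, "substitution", sub)
        if sub.shape != (N_STATES, N_STATES):
            raise ValueError(f"substitution matrix must be {N_STATES}x{N_STATES}")
        if not np.allclose(sub, sub.T):
            raise ValueError("substitution matrix must be symmetric")
        if np.any(np.diag(sub) != 0):
            raise ValueError("substitution matrix must have zero diagonal")
        if np.any(sub < 0) or self.indel <= 0:
            raise ValueError("costs must be nonnegative, indel positive")

    @classmethod
    def constant(cls, sub: float = 2.0, indel: float = 1.0) -> "CostScheme":
        """Constant scheme: every off-diagonal substitution costs ``sub``."""
        m = np.full((N_STATES, N_STATES), float(sub))
        np.fill_diagonal(m, 0.0)
        return cls(substitution=m, indel=float(indel))

    @property
    def is_constant(self) -> bool:
        off = self.substitution[~np.eye(N_STATES, dtype=bool)]
        return bool(np.all(off == off[0]))

    def describe(self) -> dict:
        return {
            "indel": self.indel,
            "substitution": self.substitution.tolist(),
            "constant": self.is_constant,
        }


@dataclass
class DissimilarityMatrix:
    """Pairwise OM distances between the *unique* sequences of a sample.

    ``index`` maps each input sequence (woman) to its unique-sequence
    row; ``agg_weights`` are the summed survey weights of identical
    sequences, so weighted statistics on the unique rows equal the same
    statistics on the full sample.
    """

    values: np.ndarray       # (u, u) symmetric, zero diagonal
    agg_weights: np.ndarray  # (u,)
    index: np.ndarray        # (n,) woman -> unique row
    unique_states: np.ndarray  # (u, L) int8
    costs: CostScheme

    @property
    def n_unique(self) -> int:
        return self.values.shape[0]

    @property
    def total_weight(self) -> float:
        return float(self.agg_weights.sum())


@njit(cache=True)
def _om_dp(a, b, sub, indel):
    m, n = a.shape[0], b.shape[0]
    prev = np.empty(n + 1)
    cur = np.empty(n + 1)
    for j in range(n + 1):
        prev[j] = j * indel
    for i in range(1, m + 1):
        cur[0] = i * indel
        ai = a[i - 1]
        for j in range(1, n + 1):
            best = prev[j - 1] + sub[ai, b[j - 1]]
            t = prev[j] + indel
            if t < best:
                best = t
            t = cur[j - 1] + indel
            if t < best:
                best = t
            cur[j] = best
        prev, cur = cur, prev
    return prev[n]


@njit(cache=True)
def _pairwise_dp(codes, sub, indel):
    u = codes.shape[0]
    out = np.zeros((u, u))
    for i in range(u):
        for j in range(i + 1, u):
            d = _om_dp(codes[i], codes[j], sub, indel)
            out[i, j] = d
            out[j, i] = d
    return out


@njit(cache=True)
def _pairwise_lcs(codes, indel):
    # bit-parallel LCS (Hyyro): valid for sequence length <= 63
    u, L = codes.shape
    one = np.uint64(1)
    full = (one << np.uint64(L)) - one
    pm = np.zeros((u, N_STATES), dtype=np.uint64)
    for i in range(u):
        for p in range(L):
            pm[i, codes[i, p]] |= one << np.uint64(p)
    out = np.zeros((u, u))
    for i in range(u):
        for j in range(i + 1, u):
            v = full
            for p in range(L):
                t = pm[i, codes[j, p]]
                m = v & t
                v = ((v + m) | (v - m)) & full
            cnt = 0
            x = v
            while x:
                cnt += 1
                x &= x - one
            lcs = L - cnt
            d = indel * (2.0 * L - 2.0 * lcs)
            out[i, j] = d
            out[j, i] = d
    return out


def om_distance(a, b, costs: CostScheme | None = None) -> float:
    """OM edit distance between two state vectors (any lengths)."""
    if costs is None:
        costs = CostScheme.constant()
    a = np.asarray(a, dtype=np.int8)
    b = np.asarray(b, dtype=np.int8)
    for v in (a, b):
        if v.size and (v.min() < 0 or v.max() >= N_STATES):
            raise ValueError("state outside the 5-state alphabet")
    return float(_om_dp(a, b, costs.substitution, costs.indel))


def om_distance_reference(a, b, costs: CostScheme | None = None) -> float:
    """Exhaustive-recursion oracle for :func:`om_distance` (lengths <= 8)."""
    if costs is None:
        costs = CostScheme.constant()
    a = list(a)
    b = list(b)
    if len(a) > 8 or len(b) > 8:
        raise ValueError("reference oracle is limited to sequences of length <= 8")
    sub = costs.substitution
    indel = costs.indel

    def rec(i: int, j: int) -> float:
        if i == len(a):
            return (len(b) - j) * indel
        if j == len(b):
            return (len(a) - i) * indel
        return min(
            rec(i + 1, j + 1) + sub[a[i], b[j]],
            rec(i + 1, j) + indel,
            rec(i, j + 1) + indel,
        )

    return float(rec(0, 0))


def _sequence_array(seqs) -> np.ndarray:
    """Stack StateSequence objects or array-likes into an (n, L) int8 array."""
    rows = [np.asarray(getattr(s, "states", s), dtype=np.int8) for s in seqs]
    return np.vstack(rows)


def pairwise_matrix(seqs, weights=None, costs: CostScheme | None = None) -> DissimilarityMatrix:
    """Deduplicate sequences, sum weights, and compute all OM distances."""
    if costs is None:
        costs = CostScheme.constant()
    arr = _sequence_array(seqs)
    n, L = arr.shape
    if weights is None:
        weights = np.ones(n)
    weights = np.asarray(weights, dtype=np.float64)
    if weights.shape != (n,):
        raise ValueError("weights must be one per sequence")

    uniq, index = np.unique(arr, axis=0, return_inverse=True)
    u = uniq.shape[0]
    agg = np.bincount(index, weights=weights, minlength=u)

    off = costs.substitution[~np.eye(N_STATES, dtype=bool)]
    sub0 = float(off[0])
    if costs.is_constant and sub0 >= 2.0 * costs.indel and L <= 63:
        values = _pairwise_lcs(np.ascontiguousarray(uniq), costs.indel)
    else:
        values = _pairwise_dp(np.ascontiguousarray(uniq), costs.substitution, costs.indel)
    logger.info("pairwise OM matrix: %d sequences -> %d unique", n, u)
    return DissimilarityMatrix(
        values=values,
        agg_weights=agg,
        index=index,
        unique_states=uniq,
        costs=costs,
    )


# ---------------------------------------------------------------------------
# optional persistence (delimited text with a provenance header)


def _matrix_fingerprint(dissim: DissimilarityMatrix) -> str:
    h = hashlib.sha256()
    h.update(dissim.unique_states.tobytes())
    h.update(np.asarray(dissim.costs.substitution).tobytes())
    h.update(np.float64(dissim.costs.indel).tobytes())
    return h.hexdigest()[:16]


def save_matrix(dissim: DissimilarityMatrix, path) -> None:
    header = {
        "fingerprint": _matrix_fingerprint(dissim),
        "costs": dissim.costs.describe(),
        "n_unique": dissim.n_unique,
    }
    with open(path, "w") as fh:
        fh.write("# " + json.dumps(header) + "\n")
        np.savetxt(fh, dissim.values, delimiter=",")
        fh.write("# agg_weights\n")
        np.savetxt(fh, dissim.agg_weights[None, :], delimiter=",")


def load_matrix(path, expected: DissimilarityMatrix) -> DissimilarityMatrix:
    """Reload a persisted matrix, refusing one computed from different
    sequences or costs than ``expected``."""
    with open(path) as fh:
        header = json.loads(fh.readline().lstrip("# "))
    if header["fingerprint"] != _matrix_fingerprint(expected):
        raise ValueError(f"{path}: matrix was computed from different inputs")
    rows = np.loadtxt(path, delimiter=",", comments="#")
    u = header["n_unique"]
    values, agg = rows[:u], rows[u]
    return DissimilarityMatrix(
        values=values,
        agg_weights=agg,
        index=expected.index,
        unique_states=expected.unique_states,
        costs=expected.costs,
    )


def max_possible_distance(costs: CostScheme, length: int = SEQ_LENGTH) -> float:
    """Upper bound on any pairwise distance for equal-length sequences."""
    return length * min(float(costs.substitution.max()), 2.0 * costs.indel)
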