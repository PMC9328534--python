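"""Descriptive statistics used to characterize and label clusters.

For each cluster: the weighted cross-sectional state distribution at
each of the 59 months (the table behind a density plot), mean months
spent in each state, the month-by-month entropy profile, Elzinga's
turbulence, the medoid sequence, and the weighted membership share.

Turbulence of a sequence x is ``T(x) = log2( phi(x) * (s2_max + 1) /
(s2 + 1) )`` where phi(x) counts the distinct subsequences (including
the empty one) of the distinct-successive-states (DSS) form of x, s2 is
the population variance of the spell durations and s2_max the variance
obtained when all slack is concentrated in a single spell,
``(d - 1) * (mean_duration - 1)^2`` for d spells. A constant sequence
has phi = 2 and zero variances, hence turbulence exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calendar_io import StateSequence
from .clustering import ClusterSolution
from .distance import DissimilarityMatrix, _sequence_array
from .states import N_STATES, SEQ_LENGTH, STATE_NAMES, states_to_letters


def state_distribution(seqs, weights=None) -> np.ndarray:
    """Weighted share of each state at each month; rows sum to 1.

    Returns a (59, 5) array: entry (m, s) is the weighted fraction of
    sequences in state s at month m+1.
    """
    arr = _sequence_array(seqs)
    n, L = arr.shape
    if n == 0:
        raise ValueError("no sequences")
    if weights is None:
        weights = np.ones(n)
    weights = np.asarray(weights, dtype=np.float64)
    total = weights.sum()
    out = np.zeros((L, N_STATES))
    for s in range(N_STATES):
        out[:, s] = (weights[:, None] * (arr == s)).sum(axis=0) / total
    return out


def mean_time(seqs, weights=None) -> np.ndarray:
    """Weighted mean months spent in each of the 5 states; sums to 59."""
    arr = _sequence_array(seqs)
    return state_distribution(arr, weights).sum(axis=0)


def cross_sectional_entropy(dist_row, normalize: bool = True) -> float:
    """Shannon entropy of one month's state distribution.

    Normalized by log(5) so 0 = everyone in one state, 1 = uniform.
    """
    p = np.asarray(dist_row, dtype=np.float64)
    if abs(p.sum() - 1.0) > 1e-8:
        raise ValueError("distribution row must sum to 1")
    nz = p[p > 0]
    h = float(-(nz * np.log(nz)).sum())
    return h / np.log(N_STATES) if normalize else h


def entropy_profile(seqs, weights=None, normalize: bool = True) -> np.ndarray:
    dist = state_distribution(seqs, weights)
    return np.array([cross_sectional_entropy(row, normalize) for row in dist])


def spells(seq) -> list[tuple[int, int]]:
    """Run-length encode a sequence into (state, duration) spells."""
    states = np.asarray(getattr(seq, "states", seq))
    out: list[tuple[int, int]] = []
    for s in states:
        if out and out[-1][0] == s:
            out[-1] = (out[-1][0], out[-1][1] + 1)
        else:
            out.append((int(s), 1))
    return out


def dss(seq) -> list[int]:
    """Distinct-successive-states form: the sequence of spell labels."""
    return [s for s, _ in spells(seq)]


def count_distinct_subsequences(symbols) -> int:
    """Number of distinct subsequences of ``symbols``, empty included.

    Standard doubling dynamic program with last-occurrence correction:
    appending symbol c doubles the count, minus the subsequences already
    counted the previous time c appeared.
    """
    symbols = list(symbols)
    counts = [1]  # dp[i] = distinct subsequences of the first i symbols
    last: dict[int, int] = {}
    for i, c in enumerate(symbols, start=1):
        val = 2 * counts[i - 1]
        if c in last:
            val -= counts[last[c] - 1]
        counts.append(val)
        last[c] = i
    return counts[-1]


def turbulence(seq) -> float:
    """Elzinga's turbulence T(x); 1 for a constant sequence."""
    sp = spells(seq)
    durations = np.array([d for _, d in sp], dtype=np.float64)
    phi = count_distinct_subsequences([s for s, _ in sp])
    d = len(durations)
    s2 = float(np.var(durations))  # population variance
    s2_max = (d - 1) * (durations.mean() - 1.0) ** 2
    return float(np.log2(phi * (s2_max + 1.0) / (s2 + 1.0)))


@dataclass
class ClusterDescriptives:
    """Plot-ready per-cluster descriptive tables."""

    distributions: pd.DataFrame  # columns: cluster, month, state, share
    mean_times: pd.DataFrame     # columns: cluster, state, mean_months
    entropies: pd.DataFrame      # columns: cluster, month, entropy
    turbulences: pd.DataFrame    # columns: cluster, mean_turbulence
    medoids: pd.DataFrame        # columns: cluster, medoid (letter string)
    shares: pd.DataFrame         # columns: cluster, share, weight

    def medoid_sequence(self, cluster: int) -> StateSequence:
        row = self.medoids.loc[self.medoids["cluster"] == cluster].iloc[0]
        from .states import letters_to_states

        return StateSequence(
            case_id=f"medoid_{cluster}",
            states=letters_to_states(row["medoid"]),
            start_cmc=0,
        )


def describe_clusters(
    dissim: DissimilarityMatrix,
    solution: ClusterSolution,
) -> ClusterDescriptives:
    """Assemble all descriptives from the deduplicated matrix and solution.

    Statistics are weighted by the aggregated survey weights, so they
    equal the same statistics over the full (duplicated) sample.
    """
    arr = dissim.unique_states
    w = dissim.agg_weights
    total = w.sum()
    dist_rows, mt_rows, ent_rows, turb_rows, med_rows, share_rows = (
        [], [], [], [], [], [])
    for c in range(solution.k):
        mask = solution.assignment == c
        assert mask.any(), "PAM cannot produce an empty cluster"
        cw = w[mask]
        cseqs = arr[mask]
        dist = state_distribution(cseqs, cw)
        for m in range(SEQ_LENGTH):
            for s in range(N_STATES):
                dist_rows.append(
                    {"cluster": c, "month": m + 1, "state": STATE_NAMES[s],
                     "share": dist[m, s]}
                )
        mt = dist.sum(axis=0)
        for s in range(N_STATES):
            mt_rows.append({"cluster": c, "state": STATE_NAMES[s],
                            "mean_months": mt[s]})
        ent = [cross_sectional_entropy(row) for row in dist]
        for m, h in enumerate(ent, start=1):
            ent_rows.append({"cluster": c, "month": m, "entropy": h})
        turb = np.array([turbulence(s) for s in cseqs])
        turb_rows.append(
            {"cluster": c, "mean_turbulence": float(np.sum(cw * turb) / cw.sum())}
        )
        med_rows.append(
            {"cluster": c,
             "medoid": states_to_letters(arr[solution.medoids[c]])}
        )
        share_rows.append(
            {"cluster": c, "share": float(cw.sum() / total),
             "weight": float(cw.sum())}
        )
    return ClusterDescriptives(
        distributions=pd.DataFrame(dist_rows),
        mean_times=pd.DataFrame(mt_rows),
        entropies=pd.DataFrame(ent_rows),
        turbulences=pd.DataFrame(turb_rows),
        medoids=pd.DataFrame(med_rows),
        shares=pd.DataFrame(share_rows),
    )
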