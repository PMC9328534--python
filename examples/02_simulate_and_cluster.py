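"""Generate synthetic calendars and recover the six behavioral clusters.

Draws 1,000 women from the six default archetypes with the published
mixture weights and moderate noise, computes the optimal-matching
dissimilarity matrix, clusters with weighted PAM at k=6, and compares
the recovered partition against the generator's true labels.
"""

import numpy as np

from calseg import (
    GeneratorConfig,
    build_sequences,
    generate,
    pairwise_matrix,
    pam,
    truth_assignment_accuracy,
)

config = GeneratorConfig(n_strata=4, psus_per_stratum=10, women_per_psu=25,
                         seed=42)
records, truth = generate(config)
seqs, _ = build_sequences(records)
weights = np.array([r.weight for r in records])

dissim = pairwise_matrix(seqs, weights)
print(f"{len(seqs)} women -> {dissim.n_unique} unique sequences")

solution = pam(dissim, k=6)
labels = solution.assignment_for(dissim.index)
print(f"PAM objective (weighted distance to medoids): {solution.objective:.1f}")

ari = truth_assignment_accuracy(truth.labels["cluster"], labels)
print(f"adjusted Rand index vs. true labels: {ari:.3f}")

# Weighted share of each recovered cluster (percent):
total = weights.sum()
for c in range(6):
    share = 100 * weights[labels == c].sum() / total
    medoid = "".join("NSLTP"[s] for s in dissim.unique_states[solution.medoids[c]])
    print(f"cluster {c}: {share:5.1f}%  medoid {medoid[:30]}...")

# An ARI near 1 means the clustering reproduces the generating mixture;
# the shares approximate the configured 41.5/24.9/18.1/7.6/5.6/2.3 split.
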