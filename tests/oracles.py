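"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths (no contingency
tables, no vectorization): pair counts are accumulated by looping over all
unordered item pairs, and the indexes are computed from their textbook
pair-count forms.
"""

from __future__ import annotations

import math
from itertools import combinations


def all_partitions(n: int):
    """Every partition of n items as a label tuple (restricted growth strings)."""

    def grow(prefix: list[int], next_label: int):
        if len(prefix) == n:
            yield tuple(prefix)
            return
        for lab in range(next_label + 1):
            yield from grow(prefix + [lab], max(next_label, lab + 1))

    yield from grow([0], 1)


def pair_counts_bruteforce(truth, pred):
    """(a, b, c, d) by explicit loop over all unordered pairs."""
    a = b = c = d = 0
    for i, j in combinations(range(len(truth)), 2):
        same_t = truth[i] == truth[j]
        same_p = pred[i] == pred[j]
        if same_t and same_p:
            a += 1
        elif same_t:
            b += 1
        elif same_p:
            c += 1
        else:
            d += 1
    return a, b, c, d


def indexes_bruteforce(truth, pred):
    """(rand, ari, fm, jaccard) from the brute-force pair counts."""
    a, b, c, d = pair_counts_bruteforce(truth, pred)
    total = a + b + c + d
    rand = (a + d) / total
    jaccard = a / (a + b + c) if (a + b + c) else 0.0
    fm = a / math.sqrt((a + b) * (a + c)) if (a + b) * (a + c) else 0.0
    expected = (a + b) * (a + c) / total
    max_a = ((a + b) + (a + c)) / 2.0
    ari = 1.0 if max_a == expected else (a - expected) / (max_a - expected)
    return rand, ari, fm, jaccard


def reconstruct_scalar(R, E, D, b_E, b_D):
    """Scalar-loop forward pass (no matrix ops): D·sigmoid(E·r + b_E) + b_D."""
    n_genes, n_cells = len(R), len(R[0])
    hidden = len(E)
    out = [[0.0] * n_cells for _ in range(n_genes)]
    for j in range(n_cells):
        h = []
        for a in range(hidden):
            s = b_E[a]
            for i in range(n_genes):
                s += E[a][i] * R[i][j]
            h.append(1.0 / (1.0 + math.exp(-s)))
        for i in range(n_genes):
            s = b_D[i]
            for a in range(hidden):
                s += D[i][a] * h[a]
            out[i][j] = s
    return out
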