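"""Independent brute-force oracles used only by the tests.

These are deliberately naive, transparent implementations kept separate
from the package so they can serve as ground truth: a full-matrix
affine-gap local-alignment dynamic program, and a step-by-step O(n^3)
average-linkage simulator.
"""

from __future__ import annotations

NEG = float("-inf")


def sw_affine_score(a: str, b: str, pair_score, gap_open: float = 11.0, gap_extend: float = 1.0):
    """Optimal Smith-Waterman score with affine gaps (gap of length L
    costs open + L * extend), by the three-state Gotoh recursion over the
    full matrix."""
    n, m = len(a), len(b)
    first = gap_open + gap_extend
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    Ix = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consume a)
    Iy = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consume b)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = pair_score(a[i - 1], b[j - 1])
            M[i][j] = max(0.0, M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1]) + s
            Ix[i][j] = max(M[i - 1][j] - first, Ix[i - 1][j] - gap_extend, Iy[i - 1][j] - first)
            Iy[i][j] = max(M[i][j - 1] - first, Iy[i][j - 1] - gap_extend, Ix[i][j - 1] - first)
            best = max(best, M[i][j], Ix[i][j], Iy[i][j])
    return best


def average_linkage_merges(dist: list[list[float]]):
    """Hand-simulated average linkage on a full distance matrix.

    Clusters are point sets; the inter-cluster distance is the mean over
    all point pairs; the closest pair merges each step (ties broken by the
    smallest cluster-index pair).  Returns the list of merge heights.
    """
    clusters = [[i] for i in range(len(dist))]
    heights = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = sum(dist[p][q] for p in clusters[i] for q in clusters[j]) / (
                    len(clusters[i]) * len(clusters[j])
                )
                if best is None or d < best[0]:
                    best = (d, i, j)
        d, i, j = best
        heights.append(d)
        merged = clusters[i] + clusters[j]
        clusters = [c for idx, c in enumerate(clusters) if idx not in (i, j)] + [merged]
    return heights
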