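"""Independent brute-force oracles used by the tests.

These deliberately avoid the code paths they check: ORFs by exhaustive
six-frame scanning, Ward clustering by a direct Lance-Williams evaluation,
the adjusted Rand index by explicit pair counting, and fragment identity by
exhaustive dynamic-programming local alignment.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np

START = {"ATG", "GTG", "TTG"}
STOP = {"TAA", "TAG", "TGA"}
_COMP = str.maketrans("ACGT", "TGCA")


def brute_force_orfs(seq: str, min_len: int) -> set[tuple[int, int, str, int]]:
    """Exhaustive scan: for every stop codon, the most upstream in-frame start."""
    n = len(seq)
    out = set()
    for strand in ("+", "-"):
        s = seq if strand == "+" else seq.translate(_COMP)[::-1]
        for frame in range(3):
            codons = [(i, s[i : i + 3]) for i in range(frame, n - 2, 3)]
            prev_stop_end = frame
            for i, c in codons:
                if c in STOP:
                    starts = [
                        j for j, cj in codons if prev_stop_end <= j < i and cj in START
                    ]
                    if starts:
                        a, b = min(starts), i + 3
                        if b - a >= min_len:
                            if strand == "-":
                                a, b = n - b, n - a
                            out.add((a, b, strand, frame))
                    prev_stop_end = i + 3
    return out


def lance_williams_ward(X: np.ndarray) -> tuple[list[float], list[frozenset]]:
    """Agglomerative Ward-D2 clustering evaluated directly.

    Returns the merge heights (Euclidean scale) and the merged clades, using
    squared Euclidean distances inside the update.  Ties are broken towards
    the lexicographically smallest cluster pair.  Also reports whether any
    decision was ambiguous (tied) via raising ValueError, so callers can
    reject degenerate fixtures.
    """
    n = X.shape[0]
    clusters: dict[int, frozenset] = {i: frozenset([i]) for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    d2: dict[tuple[int, int], float] = {}
    for i, j in itertools.combinations(range(n), 2):
        d2[(i, j)] = float(np.sum((X[i] - X[j]) ** 2))
    heights: list[float] = []
    clades: list[frozenset] = []
    next_id = n
    active = set(range(n))
    while len(active) > 1:
        pairs = sorted((k for k in d2 if k[0] in active and k[1] in active), key=lambda k: (d2[k], k))
        best = pairs[0]
        if len(pairs) > 1 and abs(d2[pairs[1]] - d2[best]) < 1e-12:
            raise ValueError("tied merge decision; fixture degenerate")
        i, j = best
        h2 = d2[best]
        heights.append(np.sqrt(h2))
        merged = clusters[i] | clusters[j]
        clades.append(merged)
        ni, nj = sizes[i], sizes[j]
        new = next_id
        next_id += 1
        for k in list(active):
            if k in (i, j):
                continue
            nk = sizes[k]
            dik = d2[tuple(sorted((i, k)))]
            djk = d2[tuple(sorted((j, k)))]
            d2[(k, new)] = ((ni + nk) * dik + (nj + nk) * djk - nk * h2) / (ni + nj + nk)
        active -= {i, j}
        active.add(new)
        clusters[new] = merged
        sizes[new] = ni + nj
    return heights, clades


def pair_counting_ari(labels_a: list, labels_b: list) -> float:
    """Adjusted Rand index from the explicit pair-count contingency table."""
    assert len(labels_a) == len(labels_b)
    n = len(labels_a)
    from collections import Counter

    contingency = Counter(zip(labels_a, labels_b))
    a_counts = Counter(labels_a)
    b_counts = Counter(labels_b)
    index = sum(comb(v, 2) for v in contingency.values())
    sum_a = sum(comb(v, 2) for v in a_counts.values())
    sum_b = sum(comb(v, 2) for v in b_counts.values())
    total = comb(n, 2)
    expected = sum_a * sum_b / total
    max_index = (sum_a + sum_b) / 2
    if max_index == expected:
        return 1.0
    return (index - expected) / (max_index - expected)


def _semiglobal_edit_distance(query: str, target: str) -> int:
    """Exhaustive DP: minimal edit distance of the whole query against any
    infix of the target (free leading/trailing target gaps), unit costs."""
    q = np.frombuffer(query.encode(), dtype=np.uint8)
    t = np.frombuffer(target.encode(), dtype=np.uint8)
    prev = np.zeros(t.size + 1, dtype=np.int32)  # free start anywhere in target
    idx = np.arange(t.size + 1, dtype=np.int32)
    for i in range(1, q.size + 1):
        cur = np.empty_like(prev)
        cur[0] = i
        cur[1:] = np.minimum(prev[:-1] + (t != q[i - 1]), prev[1:] + 1)
        # horizontal (query-gap) relaxation: cur[j] = min_k<=j cur[k] + (j - k)
        cur = np.minimum(cur, np.minimum.accumulate(cur - idx) + idx)
        prev = cur
    return int(prev.min())


def dp_fragment_identity(frag: str, reference: str) -> float:
    """Normalised edit similarity of the best semi-global alignment of the
    fragment against the reference, best of both strands."""
    best = min(
        _semiglobal_edit_distance(frag, reference),
        _semiglobal_edit_distance(frag.translate(_COMP)[::-1], reference),
    )
    return max(0.0, 100.0 * (len(frag) - best) / len(frag))
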