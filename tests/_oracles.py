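"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive and written without reference to the
package's own implementations: per-peptide loops, exhaustive enumeration and
O(n^3) clustering, so that agreement between the two routes is meaningful.
"""

from __future__ import annotations

import itertools
from collections import defaultdict


# ---------------------------------------------------------------------------
# shared spectral-count distribution (per-peptide loop)
# ---------------------------------------------------------------------------

def distribute_counts_loop(peptides):
    """``peptides`` is a list of (count, owner_tuple).  Returns
    {owner: (unique, assigned_share)} by looping peptide by peptide."""
    unique = defaultdict(float)
    for count, owners in peptides:
        if len(owners) == 1:
            unique[owners[0]] += count
        else:
            for o in owners:
                unique.setdefault(o, 0.0)
    assigned = defaultdict(float)
    for count, owners in peptides:
        if len(owners) == 1:
            continue
        total = sum(unique[o] for o in owners)
        for o in owners:
            share = count / len(owners) if total == 0 else count * unique[o] / total
            assigned[o] += share
    return {o: (unique[o], assigned[o]) for o in unique}


# ---------------------------------------------------------------------------
# UPGMA (exhaustive pair averaging)
# ---------------------------------------------------------------------------

def upgma_merges(dist, labels):
    """UPGMA by repeatedly merging the closest pair, recomputing average
    distances from the original matrix.

    ``dist`` is a full symmetric matrix (list of lists) over ``labels``.
    Returns a list of merge events ``(members_a, members_b, height)`` with
    members as frozensets of labels, ties broken by the lexicographically
    smallest member pair.
    """
    index = {lab: i for i, lab in enumerate(labels)}

    def avg(ca, cb):
        return sum(dist[index[x]][index[y]] for x in ca for y in cb) / (len(ca) * len(cb))

    clusters = [frozenset([lab]) for lab in labels]
    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters, key=sorted), 2):
            d = avg(a, b)
            key = (d, sorted(a | b))
            if best is None or key < best[0]:
                best = (key, a, b)
        key, a, b = best
        merges.append((a, b, key[0]))
        clusters = [c for c in clusters if c not in (a, b)] + [a | b]
    return merges


# ---------------------------------------------------------------------------
# global affine alignment with free end gaps
# ---------------------------------------------------------------------------

NEG = float("-inf")


def gotoh_score(a, b, sub, gap_open, gap_extend):
    """Three-state affine-gap global alignment score with unpenalized end
    gaps; a gap run of length L costs gap_open + gap_extend * L.

    ``sub`` maps (x, y) -> score.  Independent re-derivation used to check
    the aligner; validated against :func:`enumerate_score` on tiny inputs.
    """
    first = gap_open + gap_extend
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (a residue over gap)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = 0.0  # leading gap, free
    for j in range(1, m + 1):
        Y[0][j] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = sub[(a[i - 1], b[j - 1])]
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] - first, X[i - 1][j] - gap_extend,
                          Y[i - 1][j] - first)
            Y[i][j] = max(M[i][j - 1] - first, Y[i][j - 1] - gap_extend,
                          X[i][j - 1] - first)
    best = NEG
    for i in range(n + 1):  # free trailing gap in b
        best = max(best, M[i][m], X[i][m], Y[i][m])
    for j in range(m + 1):  # free trailing gap in a
        best = max(best, M[n][j], X[n][j], Y[n][j])
    return best


def enumerate_score(a, b, sub, gap_open, gap_extend):
    """Maximum score over ALL global alignments, enumerated explicitly.

    Gap runs cost gap_open + gap_extend * L except runs touching either end
    of the alignment, which are free.  Exponential; only for tiny inputs.
    """
    best = NEG

    def score(columns):
        total = 0.0
        runs = []  # (which_seq_gapped, start, end)
        current = None
        for k, (x, y) in enumerate(columns):
            if x == "-" or y == "-":
                which = "a" if x == "-" else "b"
                if current and current[0] == which and current[2] == k - 1:
                    current = (which, current[1], k)
                else:
                    if current:
                        runs.append(current)
                    current = (which, k, k)
            else:
                total += sub[(x, y)]
                if current:
                    runs.append(current)
                    current = None
        if current:
            runs.append(current)
        for which, start, end in runs:
            if start == 0 or end == len(columns) - 1:
                continue  # end gap, free
            total -= gap_open + gap_extend * (end - start + 1)
        return total

    def walk(i, j, columns):
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, score(columns))
            return
        if i < len(a) and j < len(b):
            walk(i + 1, j + 1, columns + [(a[i], b[j])])
        if i < len(a):
            walk(i + 1, j, columns + [(a[i], "-")])
        if j < len(b):
            walk(i, j + 1, columns + [("-", b[j])])

    walk(0, 0, [])
    return best
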