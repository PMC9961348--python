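"""Independent brute-force references used to cross-check the package.

Everything here is deliberately written as plain double loops / textbook
dynamic programming, independent of the implementation paths it checks.
"""

from __future__ import annotations

import numpy as np

ACIDIC = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
BASIC = {"LYS": ("NZ",), "ARG": ("NE", "NH1", "NH2")}


def brute_salt_bridges(structure, coords, cutoff):
    """Exhaustive double loop over acidic-O / basic-N atom pairs."""
    residues = list(structure.residue_index.items())
    hits = []
    for ref_a, (sa, ea) in residues:
        name_a = str(structure.residue_names[sa])
        if name_a not in ACIDIC:
            continue
        for ref_b, (sb, eb) in residues:
            name_b = str(structure.residue_names[sb])
            if name_b not in BASIC:
                continue
            best = np.inf
            for i in range(sa, ea):
                if structure.names[i] not in ACIDIC[name_a]:
                    continue
                for j in range(sb, eb):
                    if structure.names[j] not in BASIC[name_b]:
                        continue
                    d = float(np.linalg.norm(coords[i] - coords[j]))
                    best = min(best, d)
            if best <= cutoff:
                hits.append(((ref_a, ref_b), best))
    return hits


def brute_contact_count(coords_a, coords_b, cutoff):
    count = 0
    for a in coords_a:
        for b in coords_b:
            if np.linalg.norm(a - b) <= cutoff:
                count += 1
    return count


def gromos_reference(values, cutoff):
    """Greedy neighbor-count clustering, straightforward loop version."""
    n = len(values)
    unassigned = set(range(n))
    labels = [0] * n
    centroids, sizes = [], []
    label = 0
    while unassigned:
        label += 1
        best_frame, best_count = None, -1
        for f in sorted(unassigned):
            count = sum(
                1 for g in unassigned if g != f and values[f][g] <= cutoff
            )
            if count > best_count:
                best_frame, best_count = f, count
        members = {best_frame} | {
            g for g in unassigned if values[best_frame][g] <= cutoff
        }
        for m in members:
            labels[m] = label
        centroids.append(best_frame)
        sizes.append(len(members))
        unassigned -= members
    return labels, centroids, sizes


def gotoh_score(seq_a, seq_b, matrix, open_gap=10.0, extend_gap=1.0):
    """Optimal global affine-gap alignment score (Gotoh DP), end gaps penalized."""
    n, m = len(seq_a), len(seq_b)
    neg = -1e9
    M = np.full((n + 1, m + 1), neg)
    X = np.full((n + 1, m + 1), neg)  # gap in seq_b (consume a)
    Y = np.full((n + 1, m + 1), neg)  # gap in seq_a (consume b)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -open_gap - extend_gap * (i - 1)
    for j in range(1, m + 1):
        Y[0, j] = -open_gap - extend_gap * (j - 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = matrix[seq_a[i - 1], seq_b[j - 1]]
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] - open_gap, X[i - 1, j] - extend_gap,
                          Y[i - 1, j] - open_gap)
            Y[i, j] = max(M[i, j - 1] - open_gap, Y[i, j - 1] - extend_gap,
                          X[i, j - 1] - open_gap)
    return float(max(M[n, m], X[n, m], Y[n, m]))
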