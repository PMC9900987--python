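"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive — per-voxel loops, exhaustive
enumeration, quadratic recomputation — and shares no code with the package
paths it validates.
"""

import itertools

import numpy as np


def brute_median_filter(volume: np.ndarray, kernel: int = 3) -> np.ndarray:
    """Median filter by sorting every reflected neighborhood explicitly."""
    half = kernel // 2
    # edge-repeating reflection (a b c | c b a), matching the filter's
    # documented border policy
    padded = np.pad(volume, half, mode="symmetric")
    out = np.empty_like(volume)
    for z in range(volume.shape[0]):
        for y in range(volume.shape[1]):
            for x in range(volume.shape[2]):
                neigh = padded[z:z + kernel, y:y + kernel, x:x + kernel]
                out[z, y, x] = np.median(neigh)
    return out


def brute_two_means_wcss(values: np.ndarray, high_mask: np.ndarray) -> float:
    a, b = values[high_mask], values[~high_mask]
    w = float(((a - a.mean()) ** 2).sum()) if a.size else 0.0
    if b.size:
        w += float(((b - b.mean()) ** 2).sum())
    return w


def brute_optimal_split_wcss(values: np.ndarray) -> float:
    """Minimum WCSS over all contiguous splits of the sorted values."""
    v = np.sort(np.asarray(values, dtype=float))
    best = np.inf
    for k in range(1, len(v)):
        lo, hi = v[:k], v[k:]
        w = ((lo - lo.mean()) ** 2).sum() + ((hi - hi.mean()) ** 2).sum()
        best = min(best, float(w))
    return best


def brute_agglomerative_merges(profiles: np.ndarray, metric: str = "euclidean"):
    """Average-linkage agglomeration recomputing all pairwise distances at
    every step; returns the merged leaf-sets in order."""

    def dist(i, j):
        a, b = profiles[i], profiles[j]
        if metric == "euclidean":
            return float(np.linalg.norm(a - b))
        ac, bc = a - a.mean(), b - b.mean()
        denom = np.linalg.norm(ac) * np.linalg.norm(bc)
        return 1.0 - float(ac @ bc) / denom if denom else 1.0

    clusters = [frozenset([i]) for i in range(len(profiles))]
    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            d = float(
                np.mean(
                    [dist(i, j) for i in clusters[a] for j in clusters[b]]
                )
            )
            if best is None or d < best[0] - 1e-12:
                best = (d, a, b)
        _, a, b = best
        merged = clusters[a] | clusters[b]
        merges.append(merged)
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)]
        clusters.append(merged)
    return merges


def linkage_merge_sets(linkage_matrix: np.ndarray, n: int):
    """Leaf-sets of every merge recorded in a scipy linkage matrix."""
    members = {i: frozenset([i]) for i in range(n)}
    out = []
    for step, (a, b, *_rest) in enumerate(linkage_matrix):
        merged = members[int(a)] | members[int(b)]
        members[n + step] = merged
        out.append(merged)
    return out


def brute_gate(z: np.ndarray, genes: list, cells: np.ndarray, module: list):
    """Per-gene z>0 cell sets, intersected one gene at a time."""
    result = set(cells)
    for g in module:
        row = z[genes.index(g)]
        result &= {c for c, v in zip(cells, row) if v > 0}
    return result


def brute_backmap(labels2d: np.ndarray, coloring, neutral, background):
    """Pixel-by-pixel label -> color lookup."""
    out = np.zeros(labels2d.shape + (3,), dtype=float)
    for y in range(labels2d.shape[0]):
        for x in range(labels2d.shape[1]):
            lab = int(labels2d[y, x])
            if lab == 0:
                out[y, x] = background
            else:
                out[y, x] = coloring.get(lab, neutral)
    return out
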