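"""Exhaustive average-linkage agglomeration, used as a test oracle."""

import numpy as np


def brute_force_average_linkage(dist: np.ndarray):
    """Enumerate merges on a small square distance matrix.

    Returns [(id_a, id_b, height), ...] with scipy's cluster-id
    convention (new clusters numbered from n upward) and the
    average-linkage inter-cluster distance recomputed from scratch at
    every step.
    """
    n = dist.shape[0]
    clusters = {i: [i] for i in range(n)}
    next_id = n
    merges = []
    d = {(i, j): dist[i, j] for i in range(n) for j in range(i + 1, n)}
    while len(clusters) > 1:
        (i, j), h = min(d.items(), key=lambda kv: (kv[1], kv[0]))
        members = clusters.pop(i) + clusters.pop(j)
        for key in list(d):
            if i in key or j in key:
                del d[key]
        for cid, mem in clusters.items():
            val = np.mean([dist[a, b] for a in members for b in mem])
            d[tuple(sorted((cid, next_id)))] = val
        clusters[next_id] = members
        merges.append((i, j, h))
        next_id += 1
    return merges
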