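"""Independent brute-force oracles used only by the tests.

These deliberately avoid the code paths they check: flood fill is a plain
BFS, the greedy matcher below re-derives pairs by repeated minimum search
over the full distance matrix, and maximum-cardinality matching comes from
scipy's bipartite matcher on the thresholded adjacency.
"""

from collections import deque

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import maximum_bipartite_matching

NEIGHBORS_6 = [
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if abs(dz) + abs(dy) + abs(dx) == 1
]
NEIGHBORS_26 = [
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) != (0, 0, 0)
]


def flood_fill_count(mask, connectivity):
    """Number of connected foreground components by breadth-first search."""
    mask = np.asarray(mask, dtype=bool)
    neighbors = NEIGHBORS_26 if connectivity == 26 else NEIGHBORS_6
    seen = np.zeros_like(mask, dtype=bool)
    count = 0
    for start in zip(*np.nonzero(mask)):
        if seen[start]:
            continue
        count += 1
        queue = deque([start])
        seen[start] = True
        while queue:
            z, y, x = queue.popleft()
            for dz, dy, dx in neighbors:
                nz, ny, nx = z + dz, y + dy, x + dx
                if (
                    0 <= nz < mask.shape[0]
                    and 0 <= ny < mask.shape[1]
                    and 0 <= nx < mask.shape[2]
                    and mask[nz, ny, nx]
                    and not seen[nz, ny, nx]
                ):
                    seen[nz, ny, nx] = True
                    queue.append((nz, ny, nx))
    return count


def greedy_match_by_repeated_minimum(coords_a, coords_b, ids_a, ids_b, d_max):
    """Greedy one-to-one matching, recomputed naively.

    Repeatedly take the globally smallest remaining distance < d_max (ties:
    lower A id, then lower B id) and remove both endpoints.
    """
    coords_a = np.atleast_2d(np.asarray(coords_a, dtype=float))
    coords_b = np.atleast_2d(np.asarray(coords_b, dtype=float))
    if coords_a.size == 0 or coords_b.size == 0:
        return []
    dist = np.sqrt(
        ((coords_a[:, None, :] - coords_b[None, :, :]) ** 2).sum(axis=2)
    )
    alive_a = list(range(len(coords_a)))
    alive_b = list(range(len(coords_b)))
    pairs = []
    while alive_a and alive_b:
        best = None
        for i in alive_a:
            for j in alive_b:
                d = dist[i, j]
                if d >= d_max:
                    continue
                key = (d, ids_a[i], ids_b[j])
                if best is None or key < best[0]:
                    best = (key, i, j)
        if best is None:
            break
        _, i, j = best
        pairs.append((int(ids_a[i]), int(ids_b[j]), float(dist[i, j])))
        alive_a.remove(i)
        alive_b.remove(j)
    return pairs


def max_cardinality_pairs(coords_a, coords_b, d_max):
    """Size of the maximum one-to-one matching under the distance cutoff."""
    coords_a = np.atleast_2d(np.asarray(coords_a, dtype=float))
    coords_b = np.atleast_2d(np.asarray(coords_b, dtype=float))
    if coords_a.size == 0 or coords_b.size == 0:
        return 0
    dist = np.sqrt(((coords_a[:, None, :] - coords_b[None, :, :]) ** 2).sum(axis=2))
    adj = csr_matrix((dist < d_max).astype(int))
    matching = maximum_bipartite_matching(adj, perm_type="column")
    return int((matching >= 0).sum())
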