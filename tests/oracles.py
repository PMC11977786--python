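"""Independent brute-force oracles used only by the tests.

These deliberately avoid the library code paths they check: connected
components by breadth-first flood fill, surface distances by exhaustive
all-pairs search, percentiles by sort-and-interpolate, signed-rank p-values
by full enumeration of sign assignments, Spearman by explicit mid-ranks.
"""

from collections import deque
from itertools import product

import numpy as np


def flood_fill_components(mask: np.ndarray, connectivity: int) -> list[set]:
    """BFS connected components of a boolean 3D mask; list of voxel-index sets."""
    offsets = [
        off for off in product((-1, 0, 1), repeat=3)
        if off != (0, 0, 0) and {6: 1, 18: 2, 26: 3}[connectivity] >= sum(abs(o) for o in off)
    ]
    remaining = {tuple(ix) for ix in np.argwhere(mask)}
    comps = []
    while remaining:
        seed = next(iter(remaining))
        remaining.discard(seed)
        comp = {seed}
        queue = deque([seed])
        while queue:
            v = queue.popleft()
            for off in offsets:
                nb = tuple(a + b for a, b in zip(v, off))
                if nb in remaining:
                    remaining.discard(nb)
                    comp.add(nb)
                    queue.append(nb)
        comps.append(comp)
    return comps


def border_voxels_6(mask: np.ndarray) -> list[tuple]:
    """Surface voxels: foreground with at least one 6-neighbour outside."""
    out = []
    for z, y, x in np.argwhere(mask):
        for dz, dy, dx in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
            nz, ny, nx = z + dz, y + dy, x + dx
            if not (0 <= nz < mask.shape[0] and 0 <= ny < mask.shape[1] and 0 <= nx < mask.shape[2]) \
                    or not mask[nz, ny, nx]:
                out.append((z, y, x))
                break
    return out


def all_pairs_directed_distances(a: np.ndarray, b: np.ndarray, spacing) -> np.ndarray:
    """For each border voxel of a: min Euclidean mm distance to b's border."""
    sp = np.asarray(spacing, float)
    pa = np.array(border_voxels_6(a), float) * sp
    pb = np.array(border_voxels_6(b), float) * sp
    return np.array([np.sqrt(((pb - p) ** 2).sum(axis=1)).min() for p in pa])


def percentile_linear(values, q) -> float:
    """Sort-and-index linear-interpolation percentile."""
    v = np.sort(np.asarray(values, float))
    if len(v) == 1:
        return float(v[0])
    pos = (len(v) - 1) * q / 100.0
    lo = int(np.floor(pos))
    hi = int(np.ceil(pos))
    frac = pos - lo
    return float(v[lo] * (1 - frac) + v[hi] * frac)


def wilcoxon_enumerate_p(diffs) -> float:
    """Two-sided signed-rank p by enumerating every sign assignment (n <= 12)."""
    d = np.asarray(diffs, float)
    d = d[d != 0]
    n = len(d)
    assert 0 < n <= 12
    absd = np.abs(d)
    order = np.argsort(absd, kind="stable")
    ranks = np.empty(n)
    sorted_abs = absd[order]
    raw = np.arange(1, n + 1, dtype=float)
    for v in np.unique(sorted_abs):
        sel = sorted_abs == v
        raw[sel] = raw[sel].mean()
    ranks[order] = raw
    w_obs = ranks[d > 0].sum()
    ws = []
    for signs in product((0, 1), repeat=n):
        ws.append(sum(r for r, s in zip(ranks, signs) if s))
    ws = np.asarray(ws)
    p_le = (ws <= w_obs + 1e-12).mean()
    p_ge = (ws >= w_obs - 1e-12).mean()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def spearman_by_hand(x, y) -> float:
    """Mid-rank transform then explicit product-moment correlation."""
    def midranks(v):
        v = np.asarray(v, float)
        out = np.empty(len(v))
        order = np.argsort(v, kind="stable")
        sv = v[order]
        raw = np.arange(1, len(v) + 1, dtype=float)
        for u in np.unique(sv):
            sel = sv == u
            raw[sel] = raw[sel].mean()
        out[order] = raw
        return out

    rx, ry = midranks(x), midranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx * rx).sum() * (ry * ry).sum()))
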