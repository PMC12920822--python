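"""Texture-matrix builders on discretized gray-level volumes.

All builders take a positive-integer level array (0 outside the mask) plus the
binary mask, and return raw nonnegative integer count structures:

* GLCM   -- (13, Ng, Ng) symmetric co-occurrence counts, one per unique
            3D direction at Chebyshev distance 1;
* GLRLM  -- (13, Ng, Lmax) run-length counts per direction;
* GLSZM  -- (Ng, Zmax) 26-connected constant-level zone-size counts;
* GLDM   -- (Ng, Jmax) 26-neighbourhood dependence counts, dependence size
            j = 1 + number of neighbours within ``alpha`` of the center level
            (the center voxel counts itself, so j >= 1);
* NGTDM  -- per-level (n_i, p_i, s_i) with s_i the summed absolute deviation
            from the 26-neighbourhood mean.

Everything is vectorized numpy; independent brute-force oracles live in the
test suite and must agree exactly.
"""

from __future__ import annotations

from itertools import product

import numpy as np
from scipy import ndimage

__all__ = [
    "DIRECTIONS_13",
    "OFFSETS_26",
    "glcm_matrix",
    "glrlm_matrix",
    "glszm_matrix",
    "gldm_matrix",
    "ngtdm_table",
]

#: the 13 unique 3D directions (positive lexicographic half of the 26-neighbourhood)
DIRECTIONS_13: tuple[tuple[int, int, int], ...] = tuple(
    d for d in product((-1, 0, 1), repeat=3) if d > (0, 0, 0)
)

#: all 26 neighbour offsets
OFFSETS_26: tuple[tuple[int, int, int], ...] = tuple(
    d for d in product((-1, 0, 1), repeat=3) if d != (0, 0, 0)
)


def _pair_slices(offset, shape):
    """(src, dst) slice tuples so that arr[dst] is arr[src] shifted by +offset."""
    src, dst = [], []
    for d, n in zip(offset, shape):
        if d >= 0:
            src.append(slice(0, n - d))
            dst.append(slice(d, n))
        else:
            src.append(slice(-d, n))
            dst.append(slice(0, n + d))
    return tuple(src), tuple(dst)


def _num_levels(levels: np.ndarray, mask: np.ndarray) -> int:
    return int(levels[mask].max())


def glcm_matrix(levels: np.ndarray, mask: np.ndarray, distance: int = 1) -> np.ndarray:
    """Symmetric co-occurrence counts, shape (13, Ng, Ng)."""
    mask = np.asarray(mask) > 0
    ng = _num_levels(levels, mask)
    out = np.zeros((len(DIRECTIONS_13), ng, ng), dtype=np.int64)
    for k, direction in enumerate(DIRECTIONS_13):
        offset = tuple(distance * d for d in direction)
        src, dst = _pair_slices(offset, levels.shape)
        valid = mask[src] & mask[dst]
        a = levels[src][valid] - 1
        b = levels[dst][valid] - 1
        np.add.at(out[k], (a, b), 1)
        np.add.at(out[k], (b, a), 1)
    return out


def _forward_run_lengths(levels, mask, direction):
    """For every voxel: length of the maximal same-level in-mask run starting
    there and walking along +direction; plus the run-start indicator."""
    shape = levels.shape
    src, dst = _pair_slices(direction, shape)
    same = np.zeros(shape, dtype=bool)
    same[src] = mask[src] & mask[dst] & (levels[src] == levels[dst])
    f = mask.astype(np.int64)
    p = next(ax for ax, d in enumerate(direction) if d != 0)  # d[p] == +1 by construction
    # resolve f[v] = 1 + f[v+direction] when same[v], sweeping the primary axis backwards
    cur_rest, nbr_rest = [], []
    for ax in range(3):
        if ax == p:
            cur_rest.append(None)
            nbr_rest.append(None)
            continue
        d = direction[ax]
        n = shape[ax]
        if d == 0:
            cur_rest.append(slice(None))
            nbr_rest.append(slice(None))
        elif d > 0:
            cur_rest.append(slice(0, n - d))
            nbr_rest.append(slice(d, n))
        else:
            cur_rest.append(slice(-d, n))
            nbr_rest.append(slice(0, n + d))
    for i in range(shape[p] - 2, -1, -1):
        cur = tuple(i if ax == p else cur_rest[ax] for ax in range(3))
        nbr = tuple(i + 1 if ax == p else nbr_rest[ax] for ax in range(3))
        s = same[cur]
        f[cur] = np.where(s, 1 + f[nbr], f[cur])
    # start voxels: in mask and not a continuation of the run from v-direction
    continued = np.zeros(shape, dtype=bool)
    continued[dst] = same[src]
    start = mask & ~continued
    return f, start


def glrlm_matrix(levels: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Run-length counts, shape (13, Ng, Lmax)."""
    mask = np.asarray(mask) > 0
    ng = _num_levels(levels, mask)
    per_dir = []
    lmax = 1
    for direction in DIRECTIONS_13:
        f, start = _forward_run_lengths(levels, mask, direction)
        g = levels[start] - 1
        length = f[start]
        lmax = max(lmax, int(length.max()) if length.size else 1)
        per_dir.append((g, length))
    out = np.zeros((len(DIRECTIONS_13), ng, lmax), dtype=np.int64)
    for k, (g, length) in enumerate(per_dir):
        np.add.at(out[k], (g, length - 1), 1)
    return out


_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def glszm_matrix(levels: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Zone-size counts (26-connected constant-level zones), shape (Ng, Zmax)."""
    mask = np.asarray(mask) > 0
    ng = _num_levels(levels, mask)
    zones: list[tuple[int, np.ndarray]] = []
    zmax = 1
    for g in np.unique(levels[mask]):
        lab, n = ndimage.label((levels == g) & mask, structure=_STRUCT_26)
        if n == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        zones.append((int(g), sizes))
        zmax = max(zmax, int(sizes.max()))
    out = np.zeros((ng, zmax), dtype=np.int64)
    for g, sizes in zones:
        np.add.at(out[g - 1], sizes - 1, 1)
    return out


def gldm_matrix(levels: np.ndarray, mask: np.ndarray, alpha: int = 0) -> np.ndarray:
    """Dependence counts, shape (Ng, Jmax); j = 1 + #dependent neighbours."""
    mask = np.asarray(mask) > 0
    ng = _num_levels(levels, mask)
    dep = np.zeros(levels.shape, dtype=np.int64)
    for offset in OFFSETS_26:
        src, dst = _pair_slices(offset, levels.shape)
        ok = mask[src] & mask[dst] & (np.abs(levels[src] - levels[dst]) <= alpha)
        dep[src] += ok
    j = dep[mask] + 1
    g = levels[mask] - 1
    out = np.zeros((ng, int(j.max())), dtype=np.int64)
    np.add.at(out, (g, j - 1), 1)
    return out


def ngtdm_table(levels: np.ndarray, mask: np.ndarray) -> dict[str, np.ndarray]:
    """Neighbourhood gray-tone difference table.

    Returns arrays indexed by gray level 1..Ng: counts ``n``, probabilities
    ``p`` (over voxels possessing >=1 in-mask neighbour), and summed absolute
    differences ``s`` between the level and the 26-neighbourhood mean level.
    """
    mask = np.asarray(mask) > 0
    ng = _num_levels(levels, mask)
    nbr_sum = np.zeros(levels.shape, dtype=np.float64)
    nbr_cnt = np.zeros(levels.shape, dtype=np.int64)
    for offset in OFFSETS_26:
        src, dst = _pair_slices(offset, levels.shape)
        ok = mask[dst]
        nbr_sum[src] += np.where(ok, levels[dst], 0)
        nbr_cnt[src] += ok
    valid = mask & (nbr_cnt > 0)
    lv = levels[valid]
    abar = nbr_sum[valid] / nbr_cnt[valid]
    diff = np.abs(lv - abar)
    n = np.bincount(lv - 1, minlength=ng).astype(np.int64)
    s = np.bincount(lv - 1, weights=diff, minlength=ng)
    total = n.sum()
    p = n / total if total > 0 else np.zeros(ng)
    return {"n": n, "p": p, "s": s}
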