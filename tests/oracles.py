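"""Independent brute-force reference implementations for texture matrices.

Pure-python nested loops, deliberately naive: these are the oracles the
vectorized builders must match exactly on small random inputs.
"""

from itertools import product

import numpy as np

DIRS_13 = [d for d in product((-1, 0, 1), repeat=3) if d > (0, 0, 0)]
OFFS_26 = [d for d in product((-1, 0, 1), repeat=3) if d != (0, 0, 0)]


def _in(shape, v):
    return all(0 <= v[i] < shape[i] for i in range(3))


def bf_glcm(levels, mask, distance=1):
    """Symmetric co-occurrence counts per direction, (13, Ng, Ng)."""
    mask = np.asarray(mask) > 0
    ng = int(levels[mask].max())
    out = np.zeros((13, ng, ng), dtype=np.int64)
    shape = levels.shape
    for k, d in enumerate(DIRS_13):
        off = tuple(distance * c for c in d)
        for v in np.argwhere(mask):
            w = tuple(v + off)
            if _in(shape, w) and mask[w]:
                a, b = levels[tuple(v)] - 1, levels[w] - 1
                out[k, a, b] += 1
                out[k, b, a] += 1
    return out


def bf_glrlm(levels, mask):
    """Maximal straight same-level runs per direction, (13, Ng, Lmax)."""
    mask = np.asarray(mask) > 0
    ng = int(levels[mask].max())
    shape = levels.shape
    runs_per_dir = []
    lmax = 1
    for d in DIRS_13:
        runs = []
        for v in np.argwhere(mask):
            v = tuple(v)
            prev = tuple(np.array(v) - d)
            if _in(shape, prev) and mask[prev] and levels[prev] == levels[v]:
                continue  # not a run start
            length = 1
            cur = np.array(v)
            while True:
                nxt = cur + d
                if _in(shape, nxt) and mask[tuple(nxt)] \
                        and levels[tuple(nxt)] == levels[v]:
                    length += 1
                    cur = nxt
                else:
                    break
            runs.append((levels[v], length))
            lmax = max(lmax, length)
        runs_per_dir.append(runs)
    out = np.zeros((13, ng, lmax), dtype=np.int64)
    for k, runs in enumerate(runs_per_dir):
        for g, length in runs:
            out[k, g - 1, length - 1] += 1
    return out


def bf_glszm(levels, mask):
    """26-connected constant-level zones, (Ng, Zmax)."""
    mask = np.asarray(mask) > 0
    ng = int(levels[mask].max())
    seen = np.zeros(mask.shape, dtype=bool)
    zones = []
    for v in np.argwhere(mask):
        v = tuple(v)
        if seen[v]:
            continue
        g = levels[v]
        stack, comp = [v], set()
        seen[v] = True
        while stack:
            cur = stack.pop()
            comp.add(cur)
            for d in OFFS_26:
                w = tuple(np.array(cur) + d)
                if _in(mask.shape, w) and mask[w] and not seen[w] and levels[w] == g:
                    seen[w] = True
                    stack.append(w)
        zones.append((g, len(comp)))
    zmax = max(s for _, s in zones)
    out = np.zeros((ng, zmax), dtype=np.int64)
    for g, s in zones:
        out[g - 1, s - 1] += 1
    return out


def bf_gldm(levels, mask, alpha=0):
    """Dependence counts with size j = 1 + #neighbours within alpha, (Ng, Jmax)."""
    mask = np.asarray(mask) > 0
    ng = int(levels[mask].max())
    entries = []
    jmax = 1
    for v in np.argwhere(mask):
        v = tuple(v)
        dep = 0
        for d in OFFS_26:
            w = tuple(np.array(v) + d)
            if _in(mask.shape, w) and mask[w] \
                    and abs(int(levels[w]) - int(levels[v])) <= alpha:
                dep += 1
        entries.append((levels[v], dep + 1))
        jmax = max(jmax, dep + 1)
    out = np.zeros((ng, jmax), dtype=np.int64)
    for g, j in entries:
        out[g - 1, j - 1] += 1
    return out


def bf_ngtdm(levels, mask):
    """Per-level (n, p, s) from 26-neighbourhood mean levels."""
    mask = np.asarray(mask) > 0
    ng = int(levels[mask].max())
    n = np.zeros(ng, dtype=np.int64)
    s = np.zeros(ng)
    for v in np.argwhere(mask):
        v = tuple(v)
        nbrs = []
        for d in OFFS_26:
            w = tuple(np.array(v) + d)
            if _in(mask.shape, w) and mask[w]:
                nbrs.append(levels[w])
        if not nbrs:
            continue
        g = levels[v]
        n[g - 1] += 1
        s[g - 1] += abs(g - float(np.mean(nbrs)))
    total = n.sum()
    p = n / total if total else np.zeros(ng)
    return {"n": n, "p": p, "s": s}
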