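"""Independent brute-force oracles for the texture matrices.

Everything here is written as plain triple loops over voxels, without
reusing any counting code from the package: pair counting for the
co-occurrence matrix, explicit run walking for the run-length matrix,
flood fill for size zones, and neighbour counting for the dependence
matrix.  Intended for tiny regions only.
"""

from itertools import product

import numpy as np

DIRS_13 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
]
OFFS_26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]


def _inside(shape, v):
    return all(0 <= c < s for c, s in zip(v, shape))


def bf_glcm(levels, mask, n_bins):
    """Symmetric co-occurrence counts per direction: (13, Ng, Ng)."""
    shape = levels.shape
    out = np.zeros((13, n_bins, n_bins))
    for k, d in enumerate(DIRS_13):
        for v in product(*map(range, shape)):
            w = tuple(c + o for c, o in zip(v, d))
            if mask[v] and _inside(shape, w) and mask[w]:
                i, j = levels[v] - 1, levels[w] - 1
                out[k, i, j] += 1
                out[k, j, i] += 1
    return out


def bf_glrlm(levels, mask, n_bins):
    """Run-length counts per direction, padded to a common max length."""
    shape = levels.shape
    runs_per_dir = []
    max_run = 1
    for d in DIRS_13:
        runs = []
        for v in product(*map(range, shape)):
            if not mask[v]:
                continue
            prev = tuple(c - o for c, o in zip(v, d))
            if (
                _inside(shape, prev)
                and mask[prev]
                and levels[prev] == levels[v]
            ):
                continue  # not a run start
            length = 1
            cur = v
            while True:
                nxt = tuple(c + o for c, o in zip(cur, d))
                if _inside(shape, nxt) and mask[nxt] and levels[nxt] == levels[cur]:
                    length += 1
                    cur = nxt
                else:
                    break
            runs.append((levels[v], length))
            max_run = max(max_run, length)
        runs_per_dir.append(runs)
    out = np.zeros((13, n_bins, max_run))
    for k, runs in enumerate(runs_per_dir):
        for lvl, length in runs:
            out[k, lvl - 1, length - 1] += 1
    return out


def bf_glszm(levels, mask, n_bins):
    """Size-zone counts via explicit 26-connected flood fill."""
    shape = levels.shape
    seen = np.zeros(shape, dtype=bool)
    zones = []
    for v in product(*map(range, shape)):
        if not mask[v] or seen[v]:
            continue
        lvl = levels[v]
        stack = [v]
        seen[v] = True
        size = 0
        while stack:
            cur = stack.pop()
            size += 1
            for o in OFFS_26:
                w = tuple(c + d for c, d in zip(cur, o))
                if (
                    _inside(shape, w)
                    and mask[w]
                    and not seen[w]
                    and levels[w] == lvl
                ):
                    seen[w] = True
                    stack.append(w)
        zones.append((lvl, size))
    max_size = max(s for _, s in zones)
    out = np.zeros((n_bins, max_size))
    for lvl, size in zones:
        out[lvl - 1, size - 1] += 1
    return out


def bf_gldm(levels, mask, n_bins, alpha=0):
    """Dependence counts: column d holds voxels with d dependent neighbours."""
    shape = levels.shape
    out = np.zeros((n_bins, 27))
    for v in product(*map(range, shape)):
        if not mask[v]:
            continue
        dep = 0
        for o in OFFS_26:
            w = tuple(c + d for c, d in zip(v, o))
            if _inside(shape, w) and mask[w] and abs(levels[w] - levels[v]) <= alpha:
                dep += 1
        out[levels[v] - 1, dep] += 1
    return out


def bf_confusion(y_true, y_pred):
    """Count-by-enumeration confusion cells."""
    tp = fp = tn = fn = 0
    for t, p in zip(y_true, y_pred):
        if p == 1 and t == 1:
            tp += 1
        elif p == 1 and t == 0:
            fp += 1
        elif p == 0 and t == 0:
            tn += 1
        else:
            fn += 1
    return tp, fp, tn, fn
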