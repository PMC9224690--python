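"""Construction of the four 3D texture matrices from a discretized region.

All builders take an integer level array (1..n_bins inside the mask, 0
outside) plus the boolean mask, and return raw *count* matrices; the
feature formulas normalize as needed.  Conventions:

* GLCM / GLRLM: the 13 unique 3D directions (half of the 26-neighbourhood,
  unique up to sign); GLCM matrices are symmetrized (both voxel orders
  counted), matching the reference "original" radiomics definitions.
* GLSZM: zones are 26-connected components of equal grey level.
* GLDM: distance-1 neighbourhood (26 neighbours), dependence tolerance
  ``alpha`` (default 0).  The stored dependence size is the number of
  dependent neighbours **plus one** (so an isolated voxel has dependence 1),
  keeping the small-dependence emphases finite.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

#: The 13 unique 3D offsets (one representative per +/- pair).
DIRECTIONS_13: tuple[tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
)
assert len(DIRECTIONS_13) == 13

#: All 26 neighbour offsets.
OFFSETS_26: tuple[tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
)


def _aligned_slices(shape, offset):
    """Slice pairs (src, dst) such that src voxel v aligns with v+offset."""
    src, dst = [], []
    for size, d in zip(shape, offset):
        if d >= 0:
            src.append(slice(0, size - d))
            dst.append(slice(d, size))
        else:
            src.append(slice(-d, size))
            dst.append(slice(0, size + d))
    return tuple(src), tuple(dst)


def glcm_matrices(levels: np.ndarray, mask: np.ndarray, n_bins: int) -> np.ndarray:
    """Symmetric co-occurrence count matrices, shape (13, n_bins, n_bins)."""
    levels = np.asarray(levels)
    mask = np.asarray(mask, dtype=bool)
    out = np.zeros((len(DIRECTIONS_13), n_bins, n_bins), dtype=np.float64)
    for k, off in enumerate(DIRECTIONS_13):
        src, dst = _aligned_slices(levels.shape, off)
        valid = mask[src] & mask[dst]
        i = levels[src][valid] - 1
        j = levels[dst][valid] - 1
        if i.size:
            c = np.bincount(i * n_bins + j, minlength=n_bins * n_bins)
            c = c.reshape(n_bins, n_bins).astype(np.float64)
            out[k] = c + c.T
    return out


def glrlm_matrices(levels: np.ndarray, mask: np.ndarray, n_bins: int) -> np.ndarray:
    """Run-length count matrices, shape (13, n_bins, max_run).

    A run is a maximal set of consecutive in-mask voxels of equal level
    along one direction; each run is counted once (at its start voxel).
    """
    levels = np.asarray(levels)
    mask = np.asarray(mask, dtype=bool)
    shape = levels.shape
    per_dir = []
    max_run = 1
    for off in DIRECTIONS_13:
        # same[v] true when v and v+off are both in-mask with equal level
        same = np.zeros(shape, dtype=bool)
        src, dst = _aligned_slices(shape, off)
        same[src] = mask[src] & mask[dst] & (levels[src] == levels[dst])
        # run starts: in-mask voxels not continued from v-off
        prev_same = np.zeros(shape, dtype=bool)
        # v is continued from v-off  <=>  same[v-off]
        psrc, pdst = _aligned_slices(shape, off)
        prev_same[pdst] = same[psrc]
        starts = mask & ~prev_same
        coords = np.argwhere(starts)
        lengths = np.ones(len(coords), dtype=np.int64)
        lvl = levels[starts]
        cur = coords.copy()
        active = np.ones(len(coords), dtype=bool)
        off_arr = np.asarray(off)
        while active.any():
            idx = tuple(cur[active].T)
            cont = same[idx]
            act_idx = np.flatnonzero(active)
            lengths[act_idx[cont]] += 1
            active[act_idx[~cont]] = False
            cur[active] += off_arr
        if lengths.size:
            max_run = max(max_run, int(lengths.max()))
        per_dir.append((lvl, lengths))
    out = np.zeros((len(DIRECTIONS_13), n_bins, max_run), dtype=np.float64)
    for k, (lvl, lengths) in enumerate(per_dir):
        if lvl.size:
            np.add.at(out[k], (lvl - 1, lengths - 1), 1.0)
    return out


def glszm_matrix(levels: np.ndarray, mask: np.ndarray, n_bins: int) -> np.ndarray:
    """Size-zone count matrix, shape (n_bins, max_zone_size)."""
    levels = np.asarray(levels)
    mask = np.asarray(mask, dtype=bool)
    structure = np.ones((3,) * levels.ndim, dtype=int)
    zones = []  # (level, size)
    max_size = 1
    for lvl in np.unique(levels[mask]):
        lab, n = ndimage.label((levels == lvl) & mask, structure=structure)
        if n == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        for s in sizes:
            zones.append((int(lvl), int(s)))
            max_size = max(max_size, int(s))
    out = np.zeros((n_bins, max_size), dtype=np.float64)
    for lvl, s in zones:
        out[lvl - 1, s - 1] += 1.0
    return out


def gldm_matrix(
    levels: np.ndarray, mask: np.ndarray, n_bins: int, alpha: int = 0
) -> np.ndarray:
    """Dependence count matrix, shape (n_bins, 27).

    Column d (0-based) holds the number of in-mask voxels of each level with
    dependence size d+1, where dependence size = 1 + the number of 26-
    neighbours inside the mask whose level differs by at most ``alpha``.
    """
    levels = np.asarray(levels)
    mask = np.asarray(mask, dtype=bool)
    dep = np.zeros(levels.shape, dtype=np.int64)
    for off in OFFSETS_26:
        src, dst = _aligned_slices(levels.shape, off)
        ok = mask[src] & mask[dst] & (np.abs(levels[src] - levels[dst]) <= alpha)
        dep[src] += ok
    n_dep = 27  # dependence sizes 1..27 (centre + up to 26 neighbours)
    out = np.zeros((n_bins, n_dep), dtype=np.float64)
    i = levels[mask] - 1
    d = dep[mask]  # 0..26 -> dependence size d+1 -> column d
    np.add.at(out, (i, d), 1.0)
    return out
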