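"""Encoding a patient's feature columns as the 224x224 network input.

The selected Z-scored feature columns form an 86 x m grid (rows = the 86
features in canonical order, columns = the selected (ROI, modality) pairs
in ROI-major, modality-minor order, 1 <= m <= 8).  The grid is treated as
a greyscale image and resampled to 224 x 224 by bilinear interpolation
with the half-pixel-centre convention (align-corners = false), so the map
is linear in the grid values and every output pixel row maps back to a
unique source feature row for importance attribution.  Nearest-neighbour
resampling is available as an ablation switch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features.names import FEATURE_NAMES, MODALITIES, N_FEATURES, column_name
from .features.table import FeatureTable

IMAGE_SIZE = 224


def resize_matrix(n_out: int, n_in: int, mode: str = "bilinear") -> np.ndarray:
    """(n_out, n_in) interpolation matrix, half-pixel-centre convention.

    Output coordinate r maps to source coordinate (r + 0.5) * n_in / n_out
    - 0.5, clamped to the valid range (edge pixels replicate).
    """
    src = (np.arange(n_out) + 0.5) * n_in / n_out - 0.5
    M = np.zeros((n_out, n_in))
    if mode == "nearest":
        idx = np.clip(np.round(src), 0, n_in - 1).astype(int)
        M[np.arange(n_out), idx] = 1.0
        return M
    if mode != "bilinear":
        raise ValueError(f"unknown resize mode {mode!r}")
    s = np.clip(src, 0, n_in - 1)
    lo = np.floor(s).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    w = s - lo
    M[np.arange(n_out), lo] += 1 - w
    M[np.arange(n_out), hi] += w
    return M


def row_of_pixel(pixel_row: int, n_rows: int = N_FEATURES, size: int = IMAGE_SIZE) -> int:
    """Source feature row whose cell contains the given image pixel row."""
    return int(np.clip((pixel_row + 0.5) * n_rows / size, 0, n_rows - 1))


@dataclass
class PseudoImage:
    """A 224x224 greyscale encoding of one patient's feature grid."""

    pixels: np.ndarray
    source_grid: np.ndarray
    column_labels: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if self.pixels.shape != (IMAGE_SIZE, IMAGE_SIZE):
            raise ValueError(f"pixels must be {IMAGE_SIZE}x{IMAGE_SIZE}")
        if self.source_grid.shape[0] != N_FEATURES:
            raise ValueError("source grid must have 86 rows")

    @property
    def m(self) -> int:
        return self.source_grid.shape[1]


def selected_pairs(
    rois: tuple[str, ...], modalities: tuple[str, ...]
) -> tuple[tuple[str, str], ...]:
    """(ROI, modality) pairs in the fixed column order (ROI major)."""
    mods = tuple(m for m in MODALITIES if m in modalities)
    if set(mods) != set(modalities):
        raise ValueError(f"unknown modalities: {set(modalities) - set(mods)}")
    return tuple((roi, mod) for roi in rois for mod in mods)


def assemble_grid(
    table: FeatureTable,
    patient,
    rois: tuple[str, ...],
    modalities: tuple[str, ...],
) -> np.ndarray:
    """The 86 x m grid of one patient's selected feature columns."""
    if table.normalization_state != "zscored":
        raise ValueError("assemble_grid requires a Z-scored table")
    pairs = selected_pairs(rois, modalities)
    cols = np.empty((N_FEATURES, len(pairs)))
    for j, (roi, mod) in enumerate(pairs):
        names = [column_name(f, roi, mod) for f in FEATURE_NAMES]
        missing = [n for n in names if n not in table.data.columns]
        if missing:
            raise KeyError(f"table lacks columns for pair ({roi}, {mod})")
        cols[:, j] = table.data.loc[patient, names].to_numpy(dtype=np.float64)
    return cols


def to_pseudo_image(
    grid: np.ndarray,
    column_labels: tuple[tuple[str, str], ...] = (),
    mode: str = "bilinear",
) -> PseudoImage:
    """Resample an 86 x m grid to the fixed 224 x 224 network input."""
    grid = np.asarray(grid, dtype=np.float64)
    if grid.ndim != 2 or grid.shape[0] != N_FEATURES:
        raise ValueError(f"grid must be 86 x m, got {grid.shape}")
    if not np.isfinite(grid).all():
        raise ValueError("grid contains non-finite values")
    m = grid.shape[1]
    if not 1 <= m <= 8:
        raise ValueError(f"grid column count m={m} outside 1..8")
    R = resize_matrix(IMAGE_SIZE, N_FEATURES, mode)
    C = resize_matrix(IMAGE_SIZE, m, mode)
    pixels = R @ grid @ C.T
    if not column_labels:
        column_labels = tuple(("?", f"col{j}") for j in range(m))
    return PseudoImage(pixels=pixels, source_grid=grid, column_labels=column_labels)


def pseudo_images_for(
    table: FeatureTable,
    patients,
    rois: tuple[str, ...],
    modalities: tuple[str, ...],
    mode: str = "bilinear",
) -> np.ndarray:
    """Stack of pseudo-images (n, 224, 224) for a list of patients."""
    pairs = selected_pairs(rois, modalities)
    out = np.empty((len(patients), IMAGE_SIZE, IMAGE_SIZE), dtype=np.float32)
    for k, patient in enumerate(patients):
        grid = assemble_grid(table, patient, rois, modalities)
        out[k] = to_pseudo_image(grid, pairs, mode).pixels.astype(np.float32)
    return out
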