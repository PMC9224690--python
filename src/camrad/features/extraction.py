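"""Per-patient feature extraction: discretization and the 86-feature vector.

A patient is a :class:`VolumeWithMasks`: co-registered intensity volumes
for up to four MR modalities (T1WI, T2WI, T1CE, ADC) plus two nested
binary ROIs — the whole tumor (WT, parenchyma + edema) and the tumor core
(TC, contrast-enhancing parenchyma).  ``extract_all`` produces one
86-feature vector per (ROI, modality) pair; with both ROIs and all four
modalities that is 8 x 86 = 688 values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import firstorder, matrices, texture
from .names import (
    FEATURE_NAMES,
    GLCM_NAMES,
    GLDM_NAMES,
    GLRLM_NAMES,
    GLSZM_NAMES,
    MODALITIES,
    ROIS,
)

#: Minimum foreground voxels for stable 3D texture statistics (a 3x3x3 core).
MIN_MASK_VOXELS = 27


@dataclass
class ExtractionSettings:
    """Discretization and matrix parameters shared by all texture families.

    n_bins : fixed grey-level bin count (equal-width over the masked range).
    gldm_alpha : dependence tolerance; neighbours within ``alpha`` levels of
        the centre count as dependent.
    """

    n_bins: int = 32
    gldm_alpha: int = 0


@dataclass
class VolumeWithMasks:
    """One patient's co-registered volumes and nested ROI masks."""

    patient_id: str
    volumes: dict[str, np.ndarray]
    masks: dict[str, np.ndarray]
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def validate(self) -> None:
        shapes = {v.shape for v in self.volumes.values()}
        shapes |= {m.shape for m in self.masks.values()}
        if len(shapes) != 1:
            raise ValueError(
                f"patient {self.patient_id}: volumes and masks must share one "
                f"shape, got {sorted(shapes)}"
            )
        for roi, m in self.masks.items():
            n = int(np.count_nonzero(m))
            if n < MIN_MASK_VOXELS:
                raise ValueError(
                    f"patient {self.patient_id}: mask {roi!r} has {n} voxels, "
                    f"fewer than the {MIN_MASK_VOXELS} required for 3D texture "
                    "statistics"
                )
        if "TC" in self.masks and "WT" in self.masks:
            tc = self.masks["TC"].astype(bool)
            wt = self.masks["WT"].astype(bool)
            if np.any(tc & ~wt):
                raise ValueError(
                    f"patient {self.patient_id}: tumor core mask is not "
                    "contained in the whole-tumor mask"
                )

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))


def discretize(volume: np.ndarray, mask: np.ndarray, n_bins: int = 32) -> np.ndarray:
    """Equal-width grey-level discretization of the masked intensities.

    Returns an integer array with levels 1..n_bins inside the mask and 0
    outside.  A constant region maps to level 1 everywhere in-mask.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("discretize: empty mask")
    x = np.asarray(volume, dtype=np.float64)
    lo = x[mask].min()
    hi = x[mask].max()
    levels = np.zeros(x.shape, dtype=np.int64)
    if hi == lo:
        levels[mask] = 1
        return levels
    width = (hi - lo) / n_bins
    lv = np.floor((x[mask] - lo) / width).astype(np.int64) + 1
    np.clip(lv, 1, n_bins, out=lv)
    levels[mask] = lv
    return levels


def glcm_features(levels, mask, n_bins: int) -> dict[str, float]:
    """22 direction-averaged co-occurrence features."""
    counts = matrices.glcm_matrices(levels, mask, n_bins)
    out = texture.glcm_features_from_counts(counts)
    assert tuple(out) == GLCM_NAMES
    return out


def gldm_features(levels, mask, n_bins: int, alpha: int = 0) -> dict[str, float]:
    """14 grey-level dependence features."""
    counts = matrices.gldm_matrix(levels, mask, n_bins, alpha=alpha)
    out = texture.gldm_features_from_counts(counts)
    assert tuple(out) == GLDM_NAMES
    return out


def glrlm_features(levels, mask, n_bins: int) -> dict[str, float]:
    """16 direction-averaged run-length features."""
    counts = matrices.glrlm_matrices(levels, mask, n_bins)
    n_vox = int(np.count_nonzero(mask))
    out = texture.glrlm_features_from_counts(counts, n_vox)
    assert tuple(out) == GLRLM_NAMES
    return out


def glszm_features(levels, mask, n_bins: int) -> dict[str, float]:
    """16 size-zone features (26-connected zones)."""
    counts = matrices.glszm_matrix(levels, mask, n_bins)
    n_vox = int(np.count_nonzero(mask))
    out = texture.glszm_features_from_counts(counts, n_vox)
    assert tuple(out) == GLSZM_NAMES
    return out


@dataclass
class FeatureVector:
    """86 named feature values for one (ROI, modality) pair."""

    values: dict[str, float]
    roi: str
    modality: str
    settings: ExtractionSettings = field(default_factory=ExtractionSettings)

    def __post_init__(self) -> None:
        if tuple(self.values) != FEATURE_NAMES:
            raise ValueError("FeatureVector requires the 86 features in fixed order")

    def as_array(self) -> np.ndarray:
        return np.array(list(self.values.values()), dtype=np.float64)


def extract_features(
    volume: np.ndarray,
    mask: np.ndarray,
    settings: ExtractionSettings | None = None,
    voxel_volume: float = 1.0,
) -> dict[str, float]:
    """All 86 features of one volume/mask pair, in the canonical order."""
    settings = settings or ExtractionSettings()
    mask = np.asarray(mask, dtype=bool)
    levels = discretize(volume, mask, settings.n_bins)
    blocks = {
        "firstorder": firstorder.first_order_features(
            volume, mask, n_bins=settings.n_bins, voxel_volume=voxel_volume
        ),
        "gldm": gldm_features(levels, mask, settings.n_bins, alpha=settings.gldm_alpha),
        "glcm": glcm_features(levels, mask, settings.n_bins),
        "glrlm": glrlm_features(levels, mask, settings.n_bins),
        "glszm": glszm_features(levels, mask, settings.n_bins),
    }
    out = {
        name: blocks[name.split("_", 1)[0]][name.split("_", 1)[1]]
        for name in FEATURE_NAMES
    }
    bad = [k for k, v in out.items() if not np.isfinite(v)]
    if bad:
        raise AssertionError(f"non-finite features: {bad}")
    return out


def extract_all(
    patient: VolumeWithMasks,
    settings: ExtractionSettings | None = None,
    rois: tuple[str, ...] = ROIS,
    modalities: tuple[str, ...] = MODALITIES,
) -> list[FeatureVector]:
    """One :class:`FeatureVector` per (ROI, modality) pair, ROI-major order."""
    settings = settings or ExtractionSettings()
    patient.validate()
    out = []
    for roi in rois:
        if roi not in patient.masks:
            raise KeyError(f"patient {patient.patient_id}: missing mask {roi!r}")
        for mod in modalities:
            if mod not in patient.volumes:
                raise KeyError(
                    f"patient {patient.patient_id}: missing modality {mod!r}"
                )
            try:
                values = extract_features(
                    patient.volumes[mod],
                    patient.masks[roi],
                    settings,
                    voxel_volume=patient.voxel_volume,
                )
            except ValueError as err:
                raise ValueError(f"patient {patient.patient_id}: {err}") from err
            out.append(FeatureVector(values, roi=roi, modality=mod, settings=settings))
    return out
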