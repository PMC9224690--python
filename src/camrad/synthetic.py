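"""Synthetic cohorts with known class structure.

Two generators make every downstream stage testable without patient data:

``generate_phantom_cohort``
    3D image phantoms: four co-registered "modality" volumes per patient
    with two nested ellipsoidal ROI masks (whole tumor and tumor core).
    The class label modulates the grey-level *texture* of the lesion —
    variance and spatial autocorrelation length differ between classes —
    so the signal is visible to the radiomics stage, not only to the
    classifier.  Defaults emulate the study cohort: 111 patients, 56
    positive (label 1) / 55 negative.

``generate_feature_cohort``
    A patients x 688 feature table directly: standard-normal noise with a
    mean shift of ``effect_size`` (Cohen's d units) added to a chosen set
    of (feature, region-modality) cells for label-1 patients.  This
    bypasses image extraction to unit-test the classifier and importance
    stages with exactly known informative cells.

Randomness: one seed per cohort; per-patient streams are derived from
``(seed, patient_index)`` seed sequences so the cohort is reproducible
regardless of generation order.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .features.extraction import VolumeWithMasks
from .features.names import MODALITIES, ROIS, all_column_names
from .features.table import FeatureTable

log = logging.getLogger(__name__)

#: Class-conditional lesion texture: label 1 lesions have higher grey-level
#: variance and a longer spatial autocorrelation length than label 0.
DEFAULT_TEXTURE_PARAMS = {
    0: {"mean": 2.0, "sd": 1.0, "corr_len": 0.6},
    1: {"mean": 2.0, "sd": 1.8, "corr_len": 1.6},
}

#: Multiplicative per-modality intensity scales (modalities differ in
#: brightness but share the lesion's class-dependent texture).
MODALITY_SCALE = {"T1WI": 1.0, "T2WI": 1.3, "T1CE": 1.6, "ADC": 0.8}


@dataclass
class SyntheticSpec:
    """Cohort-level parameters of both generators.

    Defaults are the emulated study conditions: 111 patients with 56
    positives, four modalities, 64x64x32 voxel volumes, lesion radii of
    8-14 voxels, and — for feature cohorts — a standardized mean shift of
    ``effect_size`` on ``informative_features`` over unit-variance noise.
    """

    n_patients: int = 111
    n_positive: int = 56
    modalities: tuple[str, ...] = MODALITIES
    rois: tuple[str, ...] = ROIS
    volume_shape: tuple[int, int, int] = (64, 64, 32)
    lesion_radius_range: tuple[float, float] = (8.0, 14.0)
    texture_params_by_class: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_TEXTURE_PARAMS.items()}
    )
    informative_features: frozenset[tuple[int, int]] = frozenset()
    effect_size: float = 2.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.n_positive < self.n_patients:
            raise ValueError("require 0 < n_positive < n_patients")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if 2 * self.lesion_radius_range[1] + 2 >= min(self.volume_shape):
            raise ValueError(
                f"lesion diameter up to {2 * self.lesion_radius_range[1]} voxels "
                f"does not fit volume_shape {self.volume_shape}"
            )

    @property
    def n_pairs(self) -> int:
        return len(self.rois) * len(self.modalities)

    @property
    def labels(self) -> np.ndarray:
        """Cohort labels: the first ``n_positive`` patients are label 1."""
        y = np.zeros(self.n_patients, dtype=np.int64)
        y[: self.n_positive] = 1
        return y


def informative_rows(
    features: "list[int] | np.ndarray", n_pairs: int = 8
) -> frozenset[tuple[int, int]]:
    """Plant whole feature rows: each feature informative in every column."""
    return frozenset((int(f), p) for f in features for p in range(n_pairs))


def _patient_rng(spec: SyntheticSpec, index: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed, index])


def _ellipsoid(shape, center, radii) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    d = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    return d <= 1.0


def _textured_field(rng, shape, params, noise_sd) -> np.ndarray:
    """Smoothed Gaussian field with the requested sd and correlation length."""
    raw = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(raw, sigma=params["corr_len"])
    sd = smooth.std()
    if sd > 0:
        smooth = smooth / sd
    return params["mean"] + params["sd"] * noise_sd * smooth


def generate_phantom(spec: SyntheticSpec, index: int, label: int) -> VolumeWithMasks:
    """One phantom patient: 4 modality volumes + nested WT/TC masks."""
    rng = _patient_rng(spec, index)
    shape = spec.volume_shape
    lo, hi = spec.lesion_radius_range
    radii = rng.uniform(lo, hi, size=3)
    # keep the lesion inside the volume on every axis
    radii = np.minimum(radii, (np.asarray(shape) - 4) / 2.0)
    center = np.asarray(shape) / 2.0 + rng.uniform(-2, 2, size=3)
    wt = _ellipsoid(shape, center, radii)
    tc = _ellipsoid(shape, center, radii * 0.55)
    params = spec.texture_params_by_class[int(label)]
    volumes = {}
    for mod in spec.modalities:
        scale = MODALITY_SCALE.get(mod, 1.0)
        background = 0.2 * spec.noise_sd * rng.standard_normal(shape)
        lesion = _textured_field(rng, shape, params, spec.noise_sd)
        vol = background
        vol[wt] = lesion[wt] * scale
        vol[tc] += 0.5 * scale  # core enhancement
        volumes[mod] = vol.astype(np.float64)
    return VolumeWithMasks(
        patient_id=f"P{index:03d}",
        volumes=volumes,
        masks={"WT": wt, "TC": tc},
        spacing=(1.0, 1.0, 1.0),
    )


def generate_phantom_cohort(
    spec: SyntheticSpec,
) -> list[tuple[VolumeWithMasks, int]]:
    """The full phantom cohort as (patient, label) pairs."""
    labels = spec.labels
    return [
        (generate_phantom(spec, i, int(labels[i])), int(labels[i]))
        for i in range(spec.n_patients)
    ]


def generate_feature_cohort(spec: SyntheticSpec) -> tuple[FeatureTable, np.ndarray]:
    """A raw feature table with planted class signal, plus labels.

    Non-informative cells are N(0, noise_sd^2); informative cells get an
    additional ``effect_size * noise_sd`` mean shift for label-1 patients.
    """
    n_cols = 86 * spec.n_pairs
    for f, p in spec.informative_features:
        if not (0 <= f < 86 and 0 <= p < spec.n_pairs):
            raise ValueError(f"informative cell ({f}, {p}) outside the 86x"
                             f"{spec.n_pairs} grid")
    if not spec.informative_features and spec.effect_size > 0:
        warnings.warn(
            "effect_size > 0 but no informative features: no signal generated",
            stacklevel=2,
        )
    rng = np.random.default_rng([spec.seed, 10**6])
    labels = spec.labels
    X = rng.standard_normal((spec.n_patients, n_cols)) * spec.noise_sd
    shift = spec.effect_size * spec.noise_sd
    for f, p in sorted(spec.informative_features):
        col = p * 86 + f
        X[labels == 1, col] += shift
    columns = all_column_names(spec.rois, spec.modalities)
    index = [f"P{i:03d}" for i in range(spec.n_patients)]
    table = FeatureTable(pd.DataFrame(X, index=index, columns=columns))
    return table, labels


# ---------------------------------------------------------------------------
# Disk output (CLI `simulate`)


def save_phantom_cohort(cohort, out_dir) -> None:
    """Write volumes/masks as NIfTI plus a labels CSV under ``out_dir``."""
    import nibabel as nib

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for patient, label in cohort:
        pdir = out / patient.patient_id
        pdir.mkdir(exist_ok=True)
        affine = np.diag(list(patient.spacing) + [1.0])
        for mod, vol in patient.volumes.items():
            nib.save(nib.Nifti1Image(vol.astype(np.float32), affine),
                     pdir / f"{mod}.nii.gz")
        for roi, m in patient.masks.items():
            nib.save(nib.Nifti1Image(m.astype(np.uint8), affine),
                     pdir / f"mask_{roi}.nii.gz")
        rows.append({"patient_id": patient.patient_id, "label": label})
    pd.DataFrame(rows).to_csv(out / "labels.csv", index=False)


def load_phantom_cohort(in_dir) -> list[tuple[VolumeWithMasks, int]]:
    """Read a cohort written by :func:`save_phantom_cohort`."""
    import nibabel as nib

    root = Path(in_dir)
    labels = pd.read_csv(root / "labels.csv").set_index("patient_id")["label"]
    cohort = []
    for pid, label in labels.items():
        pdir = root / str(pid)
        volumes = {
            f.name.removesuffix(".nii.gz"): np.asarray(nib.load(f).dataobj, float)
            for f in sorted(pdir.glob("*.nii.gz"))
            if not f.name.startswith("mask_")
        }
        masks = {
            f.name.removesuffix(".nii.gz").removeprefix("mask_"): (
                np.asarray(nib.load(f).dataobj) > 0
            )
            for f in sorted(pdir.glob("mask_*.nii.gz"))
        }
        spacing = tuple(np.diag(nib.load(next(iter(pdir.glob("*.nii.gz")))).affine)[:3])
        cohort.append(
            (VolumeWithMasks(str(pid), volumes, masks, spacing), int(label))
        )
    return cohort


def save_labels(labels: np.ndarray, index, path) -> None:
    pd.DataFrame({"patient_id": index, "label": labels}).to_csv(path, index=False)
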