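"""Canonical feature names, ordering, and column-label scheme.

The pipeline extracts 86 "original" radiomics features per (ROI, modality)
pair: 18 first-order intensity statistics plus four 3D texture-matrix
families (14 GLDM, 22 GLCM, 16 GLRLM, 16 GLSZM).  The ordering below is
load-bearing: row *i* of the pseudo-image grid fed to the network is feature
*i*, so importance rankings are only meaningful if the order never changes.
Blocks follow the feature-class listing order (first-order, GLDM, GLCM,
GLRLM, GLSZM), alphabetical within each block.
"""

from __future__ import annotations

FIRSTORDER_NAMES = (
    "10Percentile",
    "90Percentile",
    "Energy",
    "Entropy",
    "InterquartileRange",
    "Kurtosis",
    "Maximum",
    "Mean",
    "MeanAbsoluteDeviation",
    "Median",
    "Minimum",
    "Range",
    "RobustMeanAbsoluteDeviation",
    "RootMeanSquared",
    "Skewness",
    "TotalEnergy",
    "Uniformity",
    "Variance",
)

GLDM_NAMES = (
    "DependenceEntropy",
    "DependenceNonUniformity",
    "DependenceNonUniformityNormalized",
    "DependenceVariance",
    "GrayLevelNonUniformity",
    "GrayLevelVariance",
    "HighGrayLevelEmphasis",
    "LargeDependenceEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
    "LowGrayLevelEmphasis",
    "SmallDependenceEmphasis",
    "SmallDependenceHighGrayLevelEmphasis",
    "SmallDependenceLowGrayLevelEmphasis",
)

GLCM_NAMES = (
    "Autocorrelation",
    "ClusterProminence",
    "ClusterShade",
    "ClusterTendency",
    "Contrast",
    "Correlation",
    "DifferenceAverage",
    "DifferenceEntropy",
    "DifferenceVariance",
    "Id",
    "Idm",
    "Idmn",
    "Idn",
    "Imc1",
    "Imc2",
    "InverseVariance",
    "JointAverage",
    "JointEnergy",
    "JointEntropy",
    "MaximumProbability",
    "SumEntropy",
    "SumSquares",
)

GLRLM_NAMES = (
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance",
    "HighGrayLevelRunEmphasis",
    "LongRunEmphasis",
    "LongRunHighGrayLevelEmphasis",
    "LongRunLowGrayLevelEmphasis",
    "LowGrayLevelRunEmphasis",
    "RunEntropy",
    "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized",
    "RunPercentage",
    "RunVariance",
    "ShortRunEmphasis",
    "ShortRunHighGrayLevelEmphasis",
    "ShortRunLowGrayLevelEmphasis",
)

GLSZM_NAMES = (
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance",
    "HighGrayLevelZoneEmphasis",
    "LargeAreaEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
    "LargeAreaLowGrayLevelEmphasis",
    "LowGrayLevelZoneEmphasis",
    "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized",
    "SmallAreaEmphasis",
    "SmallAreaHighGrayLevelEmphasis",
    "SmallAreaLowGrayLevelEmphasis",
    "ZoneEntropy",
    "ZonePercentage",
    "ZoneVariance",
)

FEATURE_CLASSES = (
    ("firstorder", FIRSTORDER_NAMES),
    ("gldm", GLDM_NAMES),
    ("glcm", GLCM_NAMES),
    ("glrlm", GLRLM_NAMES),
    ("glszm", GLSZM_NAMES),
)

#: All 86 feature names as "<class>_<name>", in the fixed row order.
FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{cls}_{name}" for cls, names in FEATURE_CLASSES for name in names
)

N_FEATURES = len(FEATURE_NAMES)
assert N_FEATURES == 86

ROIS = ("WT", "TC")
MODALITIES = ("T1WI", "T2WI", "T1CE", "ADC")

#: All 8 (ROI, modality) pairs, ROI-major, in the fixed column order.
REGION_MODALITY_PAIRS: tuple[tuple[str, str], ...] = tuple(
    (roi, mod) for roi in ROIS for mod in MODALITIES
)


def column_name(feature: str, roi: str, modality: str) -> str:
    """Feature-table column label, e.g. ``glcm_Contrast__WT_T1CE``."""
    return f"{feature}__{roi}_{modality}"


def all_column_names(
    rois: tuple[str, ...] = ROIS, modalities: tuple[str, ...] = MODALITIES
) -> list[str]:
    """Column labels for every (ROI, modality) block, 86 features per block.

    Blocks are ordered ROI-major, modality-minor; inside a block the 86
    features follow :data:`FEATURE_NAMES`.  With both ROIs and all four
    modalities this yields the full 688-column layout.
    """
    return [
        column_name(f, roi, mod)
        for roi in rois
        for mod in modalities
        for f in FEATURE_NAMES
    ]


def parse_column_name(col: str) -> tuple[str, str, str]:
    """Invert :func:`column_name` into (feature, ROI, modality)."""
    feature, region = col.split("__")
    roi, modality = region.split("_")
    return feature, roi, modality
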