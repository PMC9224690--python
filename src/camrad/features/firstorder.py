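"""First-order (intensity histogram) features.

All statistics are computed over the masked voxels only.  Entropy and
uniformity are computed on the discretized grey-level histogram (same
equal-width binning as the texture matrices); everything else uses raw
intensities.  Degenerate-region conventions: a zero-variance region has
skewness = kurtosis = 0 and entropy = 0, so every vector stays finite.
"""

from __future__ import annotations

import logging

import numpy as np

from .names import FIRSTORDER_NAMES

log = logging.getLogger(__name__)

_EPS = np.spacing(1.0)


def first_order_features(
    volume: np.ndarray,
    mask: np.ndarray,
    n_bins: int = 32,
    voxel_volume: float = 1.0,
) -> dict[str, float]:
    """The 18 first-order statistics of the masked intensities.

    Parameters
    ----------
    volume : 3D float array of intensities.
    mask : 3D boolean array, same shape; must select at least one voxel.
    n_bins : histogram bin count for entropy/uniformity.
    voxel_volume : physical voxel volume in mm^3 (TotalEnergy scale).
    """
    x = np.asarray(volume, dtype=np.float64)[np.asarray(mask, dtype=bool)]
    if x.size == 0:
        raise ValueError("first_order_features: empty mask")

    n = x.size
    mean = float(x.mean())
    var = float(x.var())  # population variance
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])

    # discretized histogram probabilities for entropy / uniformity
    lo, hi = float(x.min()), float(x.max())
    if hi > lo:
        edges = np.linspace(lo, hi, n_bins + 1)
        counts, _ = np.histogram(x, bins=edges)
    else:
        counts = np.array([n])
    p = counts[counts > 0] / n
    entropy = float(-(p * np.log2(p)).sum()) if p.size > 1 else 0.0
    uniformity = float((p**2).sum())

    if var > 0:
        m2 = var
        m3 = float(((x - mean) ** 3).mean())
        m4 = float(((x - mean) ** 4).mean())
        skewness = m3 / m2**1.5
        kurtosis = m4 / m2**2
    else:
        skewness = 0.0
        kurtosis = 0.0
        log.debug("zero-variance region: skewness/kurtosis set to 0")

    robust = x[(x >= p10) & (x <= p90)]
    rmad = float(np.abs(robust - robust.mean()).mean()) if robust.size else 0.0

    energy = float((x**2).sum())
    values = {
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Energy": energy,
        "Entropy": entropy,
        "InterquartileRange": float(p75 - p25),
        "Kurtosis": kurtosis,
        "Maximum": float(x.max()),
        "Mean": mean,
        "MeanAbsoluteDeviation": float(np.abs(x - mean).mean()),
        "Median": float(p50),
        "Minimum": float(x.min()),
        "Range": float(x.max() - x.min()),
        "RobustMeanAbsoluteDeviation": rmad,
        "RootMeanSquared": float(np.sqrt(energy / n)),
        "Skewness": skewness,
        "TotalEnergy": voxel_volume * energy,
        "Uniformity": uniformity,
        "Variance": var,
    }
    assert set(values) == set(FIRSTORDER_NAMES)
    return values
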