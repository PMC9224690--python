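"""Two-rater ROI fusion.

When two raters outline the same lesion independently, the contours are
fused automatically only if they agree closely; otherwise the case is
flagged for adjudication by a third rater.  Disagreement is measured as
the symmetric-difference volume divided by the union volume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class FusionResult:
    fused: np.ndarray | None
    difference: float
    needs_adjudication: bool


def fuse_masks(
    mask_a: np.ndarray, mask_b: np.ndarray, tolerance: float = 0.05
) -> FusionResult:
    """Fuse two rater masks if their relative difference is below tolerance.

    Returns a :class:`FusionResult`; ``fused`` is the voxelwise union when
    the fraction ``|A xor B| / |A or B|`` is strictly below ``tolerance``,
    else ``None`` with ``needs_adjudication`` set.
    """
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    union = a | b
    n_union = int(union.sum())
    if n_union == 0:
        raise ValueError("fuse_masks: both masks are empty")
    diff = int((a ^ b).sum()) / n_union
    if diff < tolerance:
        return FusionResult(fused=union, difference=diff, needs_adjudication=False)
    return FusionResult(fused=None, difference=diff, needs_adjudication=True)
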