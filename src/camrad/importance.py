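"""Class-activation-map feature importance.

Because the head output is aligned cell-for-cell with the 86 x m feature
grid, the per-cell class probabilities form a class-activation map whose
rows are features.  A feature's importance is its mean activation over a
validation set and over the m grid columns; the top-k (default 10) of the
ranking is reported.

Two aggregation statistics are offered:

``class_prob``
    mean probability of a fixed class of interest (default class 1) over
    all validation samples.
``true_class_prob``
    mean probability assigned to each sample's *own* label.  This scores
    how much a row supports the correct decision irrespective of class,
    and is robust on balanced validation sets where the fixed-class
    average can wash out (see docs/methods.md).
``margin``
    mean signed log-odds: (2y-1) * log(p1/p0) per cell.  Pre-softmax in
    spirit — it keeps ranking resolution when per-cell probabilities
    saturate near 0/1 on a well-fitted model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features.names import FEATURE_NAMES
from .nn.resnet import CamModel


@dataclass
class ImportanceRanking:
    """Per-feature scores and the descending-score order (ties by row order)."""

    scores: dict[str, float]
    k: int = 10
    class_of_interest: int = 1
    order: list[str] = field(init=False)

    def __post_init__(self) -> None:
        if set(self.scores) != set(FEATURE_NAMES):
            raise ValueError("scores must cover all 86 features")
        vals = np.array([self.scores[f] for f in FEATURE_NAMES])
        # stable sort on negated scores keeps the fixed feature order on ties
        idx = np.argsort(-vals, kind="stable")
        self.order = [FEATURE_NAMES[i] for i in idx]

    def top_k(self, k: int | None = None) -> list[str]:
        return self.order[: (k or self.k)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self.order) + 1),
                "feature": self.order,
                "score": [self.scores[f] for f in self.order],
            }
        )


def activation_map(model: CamModel, image: np.ndarray) -> np.ndarray:
    """Per-cell softmax probabilities (86, m, 2) for one pseudo-image."""
    image = np.asarray(image, dtype=np.float32)
    if image.ndim != 2:
        raise ValueError("activation_map expects a single 224x224 image")
    return model.cell_probabilities(image)[0]


def rank_features(
    model: CamModel,
    validation_images: np.ndarray,
    validation_labels: np.ndarray | None = None,
    class_of_interest: int = 1,
    statistic: str = "class_prob",
    k: int = 10,
) -> ImportanceRanking:
    """Importance ranking over a validation set.

    score(feature i) = mean over validation samples and grid columns of the
    chosen per-cell probability at row i.  Scores lie in [0, 1] and do not
    depend on the sample order.
    """
    images = np.asarray(validation_images, dtype=np.float32)
    if images.ndim == 2:
        images = images[None]
    if len(images) == 0:
        raise ValueError("validation set is empty")
    probs = model.cell_probabilities(images)  # (N, 86, m, 2)
    if statistic == "class_prob":
        per_sample = probs[..., class_of_interest]
    elif statistic == "true_class_prob":
        if validation_labels is None:
            raise ValueError("true_class_prob requires validation labels")
        y = np.asarray(validation_labels, dtype=np.int64)
        per_sample = np.take_along_axis(
            probs, y[:, None, None, None], axis=-1
        )[..., 0]
    elif statistic == "margin":
        if validation_labels is None:
            raise ValueError("margin requires validation labels")
        y = np.asarray(validation_labels, dtype=np.int64)
        p1 = np.clip(probs[..., 1], 1e-8, 1 - 1e-8)
        per_sample = (2 * y[:, None, None] - 1) * np.log(p1 / (1 - p1))
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    scores = per_sample.mean(axis=(0, 2))  # over samples and columns
    return ImportanceRanking(
        scores=dict(zip(FEATURE_NAMES, map(float, scores))),
        k=k,
        class_of_interest=class_of_interest,
    )


def column_breakdown(
    model: CamModel,
    validation_images: np.ndarray,
    class_of_interest: int = 1,
) -> pd.DataFrame:
    """Per-(feature, column) mean activation, 86 rows x m columns."""
    images = np.asarray(validation_images, dtype=np.float32)
    if images.ndim == 2:
        images = images[None]
    probs = model.cell_probabilities(images)[..., class_of_interest]
    return pd.DataFrame(probs.mean(axis=0), index=FEATURE_NAMES)


def plot_importance(ranking: ImportanceRanking, k: int | None = None, ax=None):
    """Horizontal bar chart of the top-k importance scores."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    top = ranking.top_k(k)
    pos = np.arange(len(top))[::-1]
    ax.barh(pos, [ranking.scores[f] for f in top])
    ax.set_yticks(pos)
    ax.set_yticklabels(top)
    ax.set_xlabel("mean class-activation score")
    return ax
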