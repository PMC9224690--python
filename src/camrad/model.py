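"""Model/Results facade: the full pipeline behind a two-object API.

``CamNet`` holds a raw feature table, labels, and the (ROI, modality)
selection; ``fit`` runs stratified k-fold cross-validation — Z-scoring
refit on each fold's training rows, pseudo-image encoding, network
training — and returns a ``CamNetResults`` with pooled validation
predictions, the metric panel, per-fold details, the trained fold models,
and class-activation-map feature importance.

    >>> table, labels = generate_feature_cohort(spec)
    >>> res = CamNet(table, labels, rois=("TC",), modalities=("T1CE", "ADC"),
    ...              train_config=TrainConfig(epochs=30)).fit(seed=0)
    >>> res.auc, res.summary()
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .evaluation import (
    FoldPlan,
    MetricsRow,
    auc,
    combination_label,
    confusion_metrics,
    make_folds,
    roc_points,
)
from .features.names import MODALITIES, ROIS
from .features.table import FeatureTable
from .imaging import pseudo_images_for
from .importance import ImportanceRanking, rank_features
from .nn.resnet import CamModel, build_model
from .nn.training import TrainConfig, predict_patient, train


class CamNet:
    """Radiomics-to-image residual-network classifier (model object).

    Parameters
    ----------
    table : FeatureTable or DataFrame
        Raw (un-normalized) patients x columns radiomics table.
    labels : array of {0,1}, aligned with the table rows.
    rois, modalities : the (ROI, modality) selection; the grid has
        m = len(rois) * len(modalities) columns (1..8).
    train_config : TrainConfig, optional.
    head : "cam" (default) or "classic" (avgpool+FC ablation).
    normalize : "per-fold" (default; Z-score statistics fit on each fold's
        training rows) or "global" (fit once on all rows).
    """

    def __init__(
        self,
        table,
        labels,
        rois: tuple[str, ...] = ROIS,
        modalities: tuple[str, ...] = MODALITIES,
        train_config: TrainConfig | None = None,
        head: str = "cam",
        normalize: str = "per-fold",
        resize_mode: str = "bilinear",
    ):
        if isinstance(table, pd.DataFrame):
            table = FeatureTable(table)
        if table.normalization_state != "raw":
            raise ValueError("CamNet expects a raw table; it normalizes per fold")
        if normalize not in ("per-fold", "global"):
            raise ValueError(f"unknown normalize {normalize!r}")
        self.table = table
        self.labels = np.asarray(labels, dtype=np.int64)
        if len(self.labels) != table.n_patients:
            raise ValueError("labels length does not match the table")
        self.rois = tuple(rois)
        self.modalities = tuple(modalities)
        self.train_config = train_config or TrainConfig()
        self.head = head
        self.normalize = normalize
        self.resize_mode = resize_mode

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, labels, **kw) -> "CamNet":
        return cls(FeatureTable(df), labels, **kw)

    @property
    def m(self) -> int:
        return len(self.rois) * len(self.modalities)

    def _images(self, table: FeatureTable, idx: np.ndarray) -> np.ndarray:
        patients = [table.data.index[i] for i in idx]
        return pseudo_images_for(
            table, patients, self.rois, self.modalities, self.resize_mode
        )

    def fit(self, n_folds: int = 5, seed: int = 0) -> "CamNetResults":
        """Cross-validated training; deterministic given ``seed``."""
        plan = make_folds(self.labels, k=n_folds, seed=seed)
        if self.normalize == "global":
            global_z = self.table.zscore_normalize()
        n = self.table.n_patients
        pooled_scores = np.full(n, np.nan)
        fold_rows = []
        fold_models: list[CamModel] = []
        loss_histories = []
        for f, (train_idx, val_idx) in enumerate(plan):
            z = (
                global_z
                if self.normalize == "global"
                else self.table.zscore_normalize(fit_rows=train_idx)
            )
            x_train = self._images(z, train_idx)
            x_val = self._images(z, val_idx)
            fold_seed = int(np.random.SeedSequence([seed, f]).generate_state(1)[0]
                            % (2**31))
            model = build_model(self.m, head=self.head, seed=fold_seed)
            cfg = self.train_config.replace(seed=fold_seed)
            history = train(model, x_train, self.labels[train_idx], cfg)
            scores = self._scores(model, x_val)
            pooled_scores[val_idx] = scores
            fold_rows.append(
                {
                    "fold": f,
                    "n_train": len(train_idx),
                    "n_val": len(val_idx),
                    "auc": auc(self.labels[val_idx], scores),
                    **{
                        k: v
                        for k, v in confusion_metrics(
                            self.labels[val_idx], scores
                        ).items()
                        if k in ("acc", "f1", "sens", "spec", "ppv", "npv", "mcc")
                    },
                    "final_loss": history[-1],
                }
            )
            fold_models.append(model)
            loss_histories.append(history)
        return CamNetResults(
            model_spec=self,
            plan=plan,
            pooled_scores=pooled_scores,
            fold_metrics=pd.DataFrame(fold_rows),
            fold_models=fold_models,
            loss_histories=loss_histories,
            seed=seed,
        )

    def _scores(self, model: CamModel, images: np.ndarray) -> np.ndarray:
        if self.head == "cam":
            return predict_patient(model, images)
        from .nn.resnet import softmax

        logits = model.forward(images[..., None], train=False)
        return softmax(logits)[:, 1]


@dataclass
class CamNetResults:
    """Cross-validated fit results: predictions, metrics, importance."""

    model_spec: CamNet
    plan: FoldPlan
    pooled_scores: np.ndarray
    fold_metrics: pd.DataFrame
    fold_models: list[CamModel]
    loss_histories: list[list[float]] = field(repr=False, default_factory=list)
    seed: int = 0

    # -- headline metrics ----------------------------------------------------

    @property
    def labels(self) -> np.ndarray:
        return self.model_spec.labels

    @property
    def auc(self) -> float:
        """Headline AUC: mean of the per-fold validation AUCs.

        Patient scores from independently trained folds are not on a
        common calibration scale, so the fold-averaged AUC (the natural
        companion of "average accuracy") is the headline number; the
        pooled-prediction AUC remains available as ``pooled_auc``.
        """
        return float(self.fold_metrics["auc"].mean())

    @property
    def pooled_auc(self) -> float:
        """AUC of the pooled cross-validated predictions (diagnostic)."""
        return auc(self.labels, self.pooled_scores)

    @property
    def accuracy(self) -> float:
        """Average accuracy: mean of the per-fold validation accuracies."""
        return float(self.fold_metrics["acc"].mean())

    @property
    def metrics_row(self) -> MetricsRow:
        cm = confusion_metrics(self.labels, self.pooled_scores)
        return MetricsRow(
            roi="+".join(self.model_spec.rois),
            modalities=self.model_spec.modalities,
            auc=self.auc,
            acc=self.accuracy,
            f1=cm["f1"], sens=cm["sens"], spec=cm["spec"],
            ppv=cm["ppv"], npv=cm["npv"], mcc=cm["mcc"],
            fold_metrics=self.fold_metrics,
        )

    def roc(self) -> np.ndarray:
        return roc_points(self.labels, self.pooled_scores)

    def plot_roc(self, ax=None, label: str | None = None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4.5, 4.5))
        pts = self.roc()
        name = label or combination_label(self.model_spec.modalities)
        ax.plot(pts[:, 0], pts[:, 1], label=f"{name} (AUC={self.auc:.2f})")
        ax.plot([0, 1], [0, 1], "k--", lw=0.8)
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        ax.legend(loc="lower right")
        return ax

    # -- importance ----------------------------------------------------------

    def rank_features(
        self,
        class_of_interest: int = 1,
        statistic: str = "margin",
        k: int = 10,
    ) -> ImportanceRanking:
        """Fold-averaged class-activation-map importance ranking.

        Each fold model scores its own validation images; per-feature
        scores are averaged across folds before ranking.  The default
        statistic is the signed log-odds margin, which keeps ranking
        resolution on well-fitted (saturated) models; the probability
        statistics of :func:`camrad.importance.rank_features` are
        available through ``statistic``.
        """
        all_scores = []
        for model, (_, val_idx) in zip(self.fold_models, self.plan):
            z = (
                self.model_spec.table.zscore_normalize()
                if self.model_spec.normalize == "global"
                else self.model_spec.table.zscore_normalize(
                    fit_rows=np.setdiff1d(
                        np.arange(len(self.labels)), val_idx
                    )
                )
            )
            images = self.model_spec._images(z, val_idx)
            r = rank_features(
                model,
                images,
                self.labels[val_idx],
                class_of_interest=class_of_interest,
                statistic=statistic,
                k=k,
            )
            all_scores.append(r.scores)
        mean_scores = {
            f: float(np.mean([s[f] for s in all_scores])) for f in all_scores[0]
        }
        return ImportanceRanking(mean_scores, k=k, class_of_interest=class_of_interest)

    # -- reporting -----------------------------------------------------------

    def summary(self) -> str:
        spec = self.model_spec
        row = self.metrics_row
        lines = [
            "CamNet cross-validation results",
            "=" * 46,
            f"ROI(s):        {', '.join(spec.rois)}",
            f"Modalities:    {combination_label(spec.modalities)}",
            f"Grid:          86 x {spec.m}   head: {spec.head}",
            f"Patients:      {len(self.labels)} "
            f"({int(self.labels.sum())} positive)",
            f"Folds:         {self.plan.k} (seed {self.seed})",
            f"Epochs/LR:     {spec.train_config.epochs} / "
            f"{spec.train_config.learning_rate}",
            "-" * 46,
            f"AUC (mean of folds):  {row.auc:.3f}",
            f"ACC (mean):    {row.acc:.3f}",
            f"F1:   {row.f1:.3f}   SENS: {row.sens:.3f}   SPEC: {row.spec:.3f}",
            f"PPV:  {row.ppv:.3f}   NPV:  {row.npv:.3f}   MCC:  {row.mcc:.3f}",
            "=" * 46,
        ]
        return "\n".join(lines)
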