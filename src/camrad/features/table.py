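"""The patient x feature table and its Z-score normalization.

Rows are patients, columns are (feature, ROI, modality) triples named
``<class>_<feature>__<ROI>_<modality>`` and ordered ROI-major,
modality-minor, with the 86 features in canonical order inside each block
(688 columns for both ROIs x four modalities).  Z-scoring is fit on an
explicit row subset (normally the training rows of the active fold) so
validation rows never leak into the statistics; population standard
deviation (ddof=0) is used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .extraction import FeatureVector
from .names import all_column_names, column_name

log = logging.getLogger(__name__)


@dataclass
class FeatureTable:
    """A patients-by-columns radiomics table with normalization state."""

    data: pd.DataFrame
    normalization_state: str = "raw"  # "raw" | "zscored"
    train_stats: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.normalization_state not in ("raw", "zscored"):
            raise ValueError(f"bad normalization_state {self.normalization_state!r}")

    @property
    def n_patients(self) -> int:
        return len(self.data)

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    @classmethod
    def from_feature_vectors(
        cls, per_patient: dict[str, list[FeatureVector]]
    ) -> "FeatureTable":
        """Assemble the table from ``extract_all`` outputs per patient."""
        rows = {}
        for pid, vectors in per_patient.items():
            row = {}
            for fv in vectors:
                for fname, value in fv.values.items():
                    row[column_name(fname, fv.roi, fv.modality)] = value
            rows[pid] = row
        df = pd.DataFrame.from_dict(rows, orient="index")
        rois = tuple(dict.fromkeys(fv.roi for fv in next(iter(per_patient.values()))))
        mods = tuple(
            dict.fromkeys(fv.modality for fv in next(iter(per_patient.values())))
        )
        df = df[all_column_names(rois, mods)]
        return cls(df)

    def zscore_normalize(self, fit_rows=None) -> "FeatureTable":
        """Return a Z-scored copy; statistics fit on ``fit_rows`` only.

        ``fit_rows`` is a positional index array (default: all rows).
        Columns that are constant across the fit rows are set to 0 with a
        logged warning, and their recorded sd is 0.
        """
        if self.normalization_state != "raw":
            raise ValueError("table is already normalized")
        if fit_rows is None:
            fit_rows = np.arange(self.n_patients)
        fit_rows = np.asarray(fit_rows)
        if fit_rows.size == 0:
            raise ValueError("fit_rows must be nonempty")
        values = self.data.to_numpy(dtype=np.float64)
        mu = values[fit_rows].mean(axis=0)
        sd = values[fit_rows].std(axis=0)  # population sd
        degenerate = sd == 0
        if degenerate.any():
            log.warning(
                "zscore_normalize: %d constant column(s) set to 0", degenerate.sum()
            )
        safe_sd = np.where(degenerate, 1.0, sd)
        z = (values - mu) / safe_sd
        z[:, degenerate] = 0.0
        stats = pd.DataFrame({"mean": mu, "sd": sd}, index=self.data.columns)
        return FeatureTable(
            pd.DataFrame(z, index=self.data.index, columns=self.data.columns),
            normalization_state="zscored",
            train_stats=stats,
        )

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index_label="patient_id")

    @classmethod
    def from_csv(cls, path, normalization_state: str = "raw") -> "FeatureTable":
        df = pd.read_csv(path, index_col="patient_id")
        df.index.name = None
        return cls(df, normalization_state=normalization_state)
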