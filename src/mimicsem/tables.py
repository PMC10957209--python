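"""Typed containers for the two halves of a participant-level dataset.

A study dataset consists of a cognition table (five task scores measuring a
single latent cognitive factor, possibly with missing entries) and a brain
feature table (region-by-metric structural measures, one column per
``<metric>_<region>`` pair, plus optional covariate columns such as total
intracranial volume and sex).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: metric labels per tissue used throughout the package
GRAY_METRICS = ("CT", "SA", "GMV")
WHITE_METRICS = ("FA", "MD", "WMV")


def parse_feature_name(name: str) -> tuple[str, str]:
    """Split ``<metric>_<region>`` into its metric and region parts."""
    metric, sep, region = name.partition("_")
    if not sep or not region:
        raise ValueError(f"feature column {name!r} does not parse as <metric>_<region>")
    return metric, region


def tissue_of_metric(metric: str) -> str:
    if metric in GRAY_METRICS:
        return "gray"
    if metric in WHITE_METRICS:
        return "white"
    return "none"


@dataclass
class CognitionTable:
    """n-by-5 task-score matrix with an explicit missingness mask."""

    scores: pd.DataFrame  # float columns, NaN marks missing

    def __post_init__(self) -> None:
        self.scores = self.scores.astype(float)

    @property
    def task_names(self) -> list[str]:
        return list(self.scores.columns)

    @property
    def n(self) -> int:
        return len(self.scores)

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.scores.isna()

    @property
    def missing_rate(self) -> float:
        return float(self.scores.isna().to_numpy().mean())


@dataclass
class BrainFeatureTable:
    """n-by-p predictor matrix with per-column tissue/metric/region metadata.

    ``covariates`` holds non-feature columns (TIV, sex) aligned row-wise.
    """

    features: pd.DataFrame
    covariates: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.features = self.features.astype(float)

    @property
    def feature_names(self) -> list[str]:
        return list(self.features.columns)

    @property
    def n(self) -> int:
        return len(self.features)

    def schema(self) -> pd.DataFrame:
        """Tidy per-column metadata table (name, tissue, metric, region)."""
        rows = []
        for name in self.features.columns:
            metric, region = parse_feature_name(name)
            rows.append(
                {"name": name, "tissue": tissue_of_metric(metric), "metric": metric, "region": region}
            )
        return pd.DataFrame(rows)

    def columns_for(self, tissue: str | None = None, metric: str | None = None) -> list[str]:
        """Feature names filtered by tissue and/or metric."""
        out = []
        for name in self.features.columns:
            m, _ = parse_feature_name(name)
            if metric is not None and m != metric:
                continue
            if tissue is not None and tissue_of_metric(m) != tissue:
                continue
            out.append(name)
        return out


def assemble_frame(
    cognition: CognitionTable,
    brain: BrainFeatureTable | None = None,
    include_covariates: bool = True,
) -> pd.DataFrame:
    """Column-concatenate cognition, features and covariates into one frame."""
    parts = [cognition.scores.reset_index(drop=True)]
    if brain is not None:
        parts.append(brain.features.reset_index(drop=True))
        if include_covariates and not brain.covariates.empty:
            parts.append(brain.covariates.reset_index(drop=True))
    return pd.concat(parts, axis=1)


def standardize_columns(frame: pd.DataFrame, columns: list[str] | None = None) -> pd.DataFrame:
    """Return a copy with the given columns scaled to mean 0, SD 1.

    SDs use the ML convention (ddof=0) so standardized sample moments are
    exactly a correlation matrix.  Missing entries are ignored when the
    moments are computed and stay missing afterwards.
    """
    out = frame.copy()
    cols = list(frame.columns) if columns is None else columns
    for c in cols:
        x = out[c].to_numpy(dtype=float)
        mu = np.nanmean(x)
        sd = np.nanstd(x)
        if sd == 0.0 or not np.isfinite(sd):
            raise ValueError(f"column {c!r} has zero variance and cannot be standardized")
        out[c] = (x - mu) / sd
    return out
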