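"""Stability selection: repeat the regularized selection over random
subsamples and report per-predictor survival percentages.

Each iteration draws a simple random subsample without replacement
(mirroring a repeated model-building draw), standardizes all modeled
variables within the subsample, runs the BIC-selected lasso path, and
records which paths survive with exact nonzero estimates.  Iterations are
seeded individually (base_seed + b) so serial and parallel execution give
identical reports.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lasso import fit_path
from .model import MimicModelSpec
from .tables import parse_feature_name, standardize_columns, tissue_of_metric


@dataclass
class StabilityReport:
    """Per-predictor survival percentages over B subsample regularizations."""

    predictor_names: list[str]
    survival_pct: pd.Series
    B: int
    subsample_fraction: float
    base_seed: int
    n_failed: int = 0
    survivor_sets: list | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name in self.predictor_names:
            try:
                metric, region = parse_feature_name(name)
                tissue = tissue_of_metric(metric)
            except ValueError:
                metric, region, tissue = "none", name, "none"
            rows.append(
                {
                    "predictor": name,
                    "tissue": tissue,
                    "metric": metric,
                    "region": region,
                    "survival_pct": float(self.survival_pct[name]),
                    "B": self.B,
                    "fraction": self.subsample_fraction,
                }
            )
        return pd.DataFrame(rows)


def run_stability(
    data: pd.DataFrame,
    spec: MimicModelSpec,
    B: int = 1000,
    fraction: float = 0.15,
    base_seed: int = 0,
    n_lambda: int = 30,
    keep_sets: bool = False,
) -> StabilityReport:
    """Survival percentages of each structural path over ``B`` subsamples.

    Failed iterations are logged and excluded from the denominator; the
    report carries the failure count.
    """
    if B < 1:
        raise ValueError("B must be at least 1")
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    names = list(spec.indicators) + list(spec.predictors)
    frame = data[names].reset_index(drop=True)
    n = len(frame)
    m = int(np.floor(fraction * n))
    if m <= spec.n_free_conditional():
        raise ValueError(
            f"subsample size {m} does not exceed the free parameter count "
            f"{spec.n_free_conditional()}"
        )

    counts = pd.Series(0.0, index=list(spec.predictors))
    n_ok = 0
    n_failed = 0
    sets = [] if keep_sets else None
    for b in range(1, B + 1):
        rng = np.random.default_rng(base_seed + b)
        idx = rng.choice(n, size=m, replace=False)
        sub = frame.iloc[idx]
        try:
            sub = standardize_columns(sub, names)
            path = fit_path(sub, spec, n_lambda=n_lambda)
            surv = set(path.surviving)
        except Exception as exc:
            n_failed += 1
            warnings.warn(f"stability iteration {b} failed: {exc}")
            continue
        n_ok += 1
        for p in surv:
            counts[p] += 1.0
        if sets is not None:
            sets.append(sorted(surv))
    if n_ok == 0:
        raise RuntimeError("every stability iteration failed")
    pct = 100.0 * counts / n_ok
    return StabilityReport(
        predictor_names=list(spec.predictors),
        survival_pct=pct,
        B=n_ok,
        subsample_fraction=fraction,
        base_seed=base_seed,
        n_failed=n_failed,
        survivor_sets=sets,
    )


def compare_contexts(
    report_single_tissue: StabilityReport, report_combined: StabilityReport
) -> pd.DataFrame:
    """Align survival percentages across two model contexts.

    Typical use: the same region's survival in a one-tissue model versus a
    model that also includes the other tissue's metrics; a drop indicates
    information that becomes redundant once the other tissue is present.
    """
    shared = [p for p in report_single_tissue.predictor_names if p in set(report_combined.predictor_names)]
    if not shared:
        raise ValueError("reports share no predictors; cannot align")
    out = pd.DataFrame(
        {
            "predictor": shared,
            "survival_single": [float(report_single_tissue.survival_pct[p]) for p in shared],
            "survival_combined": [float(report_combined.survival_pct[p]) for p in shared],
        }
    )
    out["delta"] = out["survival_combined"] - out["survival_single"]
    return out
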