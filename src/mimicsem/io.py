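"""Dataset readers/writers, schema validation and report serialization.

File conventions: CSV/TSV with a header and an ``id`` column; missing
entries marked ``NA`` (configurable).  Feature columns follow the
``<metric>_<region>`` naming convention.  Every output file begins with a
``# seed=<seed>`` comment so any table can be traced to the run that
produced it; readers in this package skip ``#`` comment lines.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .tables import BrainFeatureTable, CognitionTable, parse_feature_name, tissue_of_metric

KNOWN_METRICS = {"CT", "SA", "GMV", "FA", "MD", "WMV"}


@dataclass
class ColumnSchema:
    """Role and anatomy annotation of one input column."""

    name: str
    role: str  # indicator | predictor | covariate | id | sex
    tissue: str = "none"
    metric: str = "none"
    region: str = ""


def infer_schema(
    cognition_columns: list[str],
    brain_columns: list[str],
    covariate_columns: list[str] = (),
) -> list[ColumnSchema]:
    """Default schema: cognition columns are indicators; brain columns
    parsing as ``<metric>_<region>`` with a known metric are predictors;
    anything else is a covariate (``sex`` gets its dedicated role)."""
    schema = [ColumnSchema(c, "indicator") for c in cognition_columns]
    for c in brain_columns:
        try:
            metric, region = parse_feature_name(c)
        except ValueError:
            metric, region = "none", ""
        if metric in KNOWN_METRICS:
            schema.append(ColumnSchema(c, "predictor", tissue_of_metric(metric), metric, region))
        elif c.lower() == "sex":
            schema.append(ColumnSchema(c, "sex"))
        else:
            schema.append(ColumnSchema(c, "covariate"))
    for c in covariate_columns:
        schema.append(ColumnSchema(c, "covariate"))
    return schema


def _read_table(path, na_values) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(
        path, sep=sep, na_values=list(na_values), keep_default_na=True,
        comment="#", float_precision="round_trip",
    )
    if "id" not in df.columns:
        raise ValueError(f"{path.name}: no 'id' column")
    if df["id"].duplicated().any():
        dup = df["id"][df["id"].duplicated()].iloc[0]
        raise ValueError(f"{path.name}: duplicate id {dup!r}")
    return df.set_index("id")


def read_dataset(
    cognition_path,
    brain_path,
    na_values=("NA", "NaN", ""),
    require_counts: tuple[int, int] | None = None,
) -> tuple[CognitionTable, BrainFeatureTable]:
    """Load and validate the two halves of a dataset, aligned by id.

    Raises explicit errors on duplicate ids, unparseable numerics,
    zero-variance predictors, and (when ``require_counts`` is given)
    region counts per metric that do not match the expected
    (gray, white) atlas sizes.
    """
    cog = _read_table(cognition_path, na_values)
    brn = _read_table(brain_path, na_values)
    if not cog.index.equals(brn.index):
        common = cog.index.intersection(brn.index)
        if len(common) == 0:
            raise ValueError("cognition and brain tables share no ids")
        cog = cog.loc[common]
        brn = brn.loc[common]

    for name, df in (("cognition", cog), ("brain", brn)):
        for col in df.columns:
            if col.lower() == "sex":
                continue
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = df[col].notna() & coerced.isna()
            if bad.any():
                row = df.index[bad][0]
                raise ValueError(
                    f"{name} column {col!r}: unparseable numeric value "
                    f"{df.loc[row, col]!r} at id {row!r}"
                )
            df[col] = coerced if col.lower() != "sex" else df[col]

    schema = infer_schema(list(cog.columns), list(brn.columns))
    pred_cols = [s.name for s in schema if s.role == "predictor"]
    cov_cols = [s.name for s in schema if s.role in {"covariate", "sex"} and s.name in brn.columns]

    for col in pred_cols:
        v = brn[col].to_numpy(dtype=float)
        if np.isnan(v).any():
            raise ValueError(f"predictor column {col!r} contains missing values")
        if np.nanstd(v) == 0.0:
            raise ValueError(f"predictor column {col!r} has zero variance")

    if require_counts is not None:
        want = {"gray": require_counts[0], "white": require_counts[1]}
        counts: dict[tuple[str, str], int] = {}
        for s in schema:
            if s.role == "predictor":
                counts[(s.tissue, s.metric)] = counts.get((s.tissue, s.metric), 0) + 1
        for (tissue, metric), k in counts.items():
            if k != want[tissue]:
                raise ValueError(
                    f"metric {metric} has {k} regions, expected {want[tissue]} for {tissue} matter"
                )

    cognition = CognitionTable(cog.reset_index(drop=True))
    brain = BrainFeatureTable(
        brn[pred_cols].reset_index(drop=True),
        covariates=brn[cov_cols].reset_index(drop=True) if cov_cols else pd.DataFrame(index=range(len(brn))),
    )
    return cognition, brain


# --------------------------------------------------------------------------
# configuration files
# --------------------------------------------------------------------------


def load_study_config(path):
    """Build a StudyConfig from a YAML or JSON file.

    Unknown keys are rejected so typos fail loudly; list-valued
    ``stability_contexts`` is coerced to a tuple.
    """
    from .pipeline import StudyConfig

    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path.name}: expected a mapping of StudyConfig fields")
    valid = set(StudyConfig.__dataclass_fields__)
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"{path.name}: unknown configuration keys {sorted(unknown)}")
    if "stability_contexts" in data:
        data["stability_contexts"] = tuple(data["stability_contexts"])
    return StudyConfig(**data)


# --------------------------------------------------------------------------
# report writing
# --------------------------------------------------------------------------


def _write_csv(path: Path, frame: pd.DataFrame, seed: int) -> None:
    with open(path, "w") as fh:
        fh.write(f"# seed={seed}\n")
        frame.to_csv(fh, index=False)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_report(report, outdir) -> dict:
    """Serialize a StudyReport to a deterministic file set.

    Writes a model-fit CSV, per-ROI CSV, survival CSV (omitted with a note
    when the stability stage did not run) and a JSON summary; returns a
    manifest listing each file with its SHA-256 checksum.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = report.seed
    files: dict[str, Path] = {}
    notes: list[str] = []

    fit_rows = []
    if report.measurement_fit is not None:
        row = {"model": "measurement_cfa", **vars(report.measurement_fit)}
        fit_rows.append(row)
    for name, fx in report.model_fits.items():
        if fx is None:
            notes.append(f"model {name} was degenerate (empty survivor set)")
            continue
        fit_rows.append({"model": name, **vars(fx)})
    files["model_fits.csv"] = outdir / "model_fits.csv"
    _write_csv(files["model_fits.csv"], pd.DataFrame(fit_rows), seed)

    if report.per_roi_estimates is not None and len(report.per_roi_estimates):
        files["per_roi_estimates.csv"] = outdir / "per_roi_estimates.csv"
        _write_csv(files["per_roi_estimates.csv"], report.per_roi_estimates, seed)

    if report.stability:
        surv = pd.concat(
            [rep.to_frame().assign(model=name) for name, rep in report.stability.items()],
            ignore_index=True,
        )
        files["survival.csv"] = outdir / "survival.csv"
        _write_csv(files["survival.csv"], surv, seed)
    else:
        notes.append("stability stage not run; survival.csv omitted")

    if report.lrt_results is not None and len(report.lrt_results):
        files["lrt_results.csv"] = outdir / "lrt_results.csv"
        _write_csv(files["lrt_results.csv"], report.lrt_results, seed)

    summary = {
        "seed": seed,
        "overlap_class": report.overlap_class,
        "r2_table": json.loads(report.r2_table.reset_index().to_json(orient="records")),
        "survivors": {k: list(v) for k, v in report.survivors.items()},
        "notes": notes,
    }
    files["summary.json"] = outdir / "summary.json"
    files["summary.json"].write_text(json.dumps(summary, indent=1, sort_keys=True))

    manifest = {
        "seed": seed,
        "files": {name: {"path": str(p), "sha256": _sha256(p)} for name, p in files.items()},
        "notes": notes,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
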