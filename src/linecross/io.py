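"""Readers, writers and the end-to-end batch pipeline.

Dataset files are plain CSV with header ``cohort,sire,dam,mean,se,n``
(sire/dam blank for the base lines; ``se``/``n`` optional).  A companion
metadata CSV carries ``dataset_id,species,trait,trait_class,clade,
divergence,parent_sex_known,weighted``.  The batch pipeline never aborts
on a bad dataset: failures are logged in a machine-readable skip ledger
and the rest of the batch proceeds, because exclusions are part of the
result.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .compare import DatasetRecord
from .config import PipelineConfig
from .design import CohortSpec, PedigreeError
from .model import LineCrossModel, LineCrossResults
from .summary import ArchitectureSummary

logger = logging.getLogger("linecross")

__all__ = [
    "read_dataset",
    "write_dataset",
    "cohorts_from_frame",
    "read_metadata",
    "run_pipeline",
    "PipelineOutput",
]

REQUIRED_COLUMNS = ("cohort", "sire", "dam", "mean")


def cohorts_from_frame(frame: pd.DataFrame) -> tuple[list[CohortSpec], bool]:
    """Validate a cohort table; returns (cohorts, weighted flag).

    The dataset is weighted only when every cohort reports a standard
    error; otherwise the whole dataset falls back to unweighted mode (the
    reader logs the fallback, mirroring how studies that omit uncertainty
    measures must be handled).
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    has_se = "se" in frame.columns
    cohorts: list[CohortSpec] = []
    seen: set[str] = set()
    for idx, row in frame.iterrows():
        rowno = idx + 2  # 1-based with header
        label = str(row["cohort"]).strip()
        if not label or label.lower() == "nan":
            raise ValueError(f"row {rowno}: empty cohort label")
        if label in seen:
            raise ValueError(f"row {rowno}: duplicate cohort label {label!r}")
        seen.add(label)
        sire = _opt_str(row["sire"])
        dam = _opt_str(row["dam"])
        try:
            mean = float(row["mean"])
        except (TypeError, ValueError):
            raise ValueError(f"row {rowno}: bad mean {row['mean']!r}") from None
        if np.isnan(mean):
            raise ValueError(f"row {rowno}: missing mean for cohort {label!r}")
        se = _opt_float(row["se"]) if has_se else None
        n = _opt_int(row["n"]) if "n" in frame.columns else None
        try:
            cohorts.append(
                CohortSpec(label=label, sire=sire, dam=dam, mean=mean, se=se, n=n)
            )
        except ValueError as exc:
            raise ValueError(f"row {rowno}: {exc}") from None
    weighted = has_se and all(c.se is not None for c in cohorts)
    if not weighted:
        logger.info("dataset lacks SEs for some cohorts: unweighted mode")
    return cohorts, weighted


def _opt_str(value) -> str | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    s = str(value).strip()
    return s or None


def _opt_float(value) -> float | None:
    if value is None or value == "":
        return None
    v = float(value)
    return None if np.isnan(v) else v


def _opt_int(value) -> int | None:
    v = _opt_float(value)
    return None if v is None else int(v)


def read_dataset(path: str | Path) -> tuple[list[CohortSpec], bool]:
    """Read one dataset CSV; returns (cohorts, weighted flag)."""
    frame = pd.read_csv(path, dtype={"cohort": str, "sire": str, "dam": str})
    try:
        return cohorts_from_frame(frame)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from None


def write_dataset(cohorts: Sequence[CohortSpec], path: str | Path) -> None:
    """Write cohorts back to the CSV dialect `read_dataset` consumes."""
    rows = [
        {
            "cohort": c.label,
            "sire": c.sire or "",
            "dam": c.dam or "",
            "mean": c.mean,
            "se": "" if c.se is None else c.se,
            "n": "" if c.n is None else c.n,
        }
        for c in cohorts
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


METADATA_COLUMNS = (
    "dataset_id", "species", "trait", "trait_class", "clade",
    "divergence", "parent_sex_known", "weighted",
)


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the companion metadata CSV, indexed by dataset_id."""
    meta = pd.read_csv(path)
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"{path}: missing metadata columns: {missing}")
    for col in ("parent_sex_known", "weighted"):
        meta[col] = meta[col].astype(bool)
    return meta.set_index("dataset_id", drop=False)


@dataclass
class PipelineOutput:
    """Everything the batch pipeline produces."""

    summaries: pd.DataFrame
    records: list[DatasetRecord]
    results: dict[str, LineCrossResults] = field(default_factory=dict)
    skipped: list[dict] = field(default_factory=list)

    @property
    def n_informative(self) -> int:
        return int(self.summaries["informative"].sum())

    @property
    def n_datasets(self) -> int:
        return len(self.summaries)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.summaries.to_csv(out / "summaries.tsv", sep="\t", index=False)
        report = {
            "n_datasets": self.n_datasets,
            "n_informative": self.n_informative,
            "skipped": self.skipped,
        }
        (out / "report.json").write_text(json.dumps(report, indent=1))
        for dataset_id, res in self.results.items():
            res.to_effect_records().to_csv(
                out / f"{dataset_id}.effects.tsv", sep="\t", index=False
            )
            (out / f"{dataset_id}.report.json").write_text(
                json.dumps(res.report(), indent=1)
            )


def run_pipeline(
    dataset_paths: Sequence[str | Path] | dict[str, pd.DataFrame],
    metadata: pd.DataFrame | str | Path,
    config: PipelineConfig | None = None,
    keep_results: bool = False,
) -> PipelineOutput:
    """Run the full per-dataset analysis over a batch.

    ``dataset_paths`` is either a list of CSV paths (dataset_id = file
    stem) or a mapping of dataset_id to cohort DataFrame.  For each
    dataset: select the model set from ``parent_sex_known``, build the
    C-matrix, enumerate/screen/fit candidate models, model-average, apply
    the significance gate, and summarize.  Per-dataset failures are logged
    and skipped; the batch always completes.
    """
    config = config or PipelineConfig()
    if isinstance(metadata, (str, Path)):
        metadata = read_metadata(metadata)
    if isinstance(dataset_paths, dict):
        frames = dict(dataset_paths)
    else:
        frames = {Path(p).stem: p for p in dataset_paths}

    rows = []
    records: list[DatasetRecord] = []
    results: dict[str, LineCrossResults] = {}
    skipped: list[dict] = []
    for dataset_id, source in frames.items():
        try:
            if isinstance(source, pd.DataFrame):
                cohorts, weighted = cohorts_from_frame(source)
            else:
                cohorts, weighted = read_dataset(source)
            meta = metadata.loc[dataset_id] if dataset_id in metadata.index else None
            parent_sex_known = bool(meta["parent_sex_known"]) if meta is not None else True
            model_set = config.resolve_model_set(parent_sex_known)
            model = LineCrossModel(
                cohorts, model_set=model_set, config=config, weighted=weighted
            )
            res = model.fit()
        except (ValueError, PedigreeError) as exc:
            logger.warning("skipping dataset %s: %s", dataset_id, exc)
            skipped.append({"dataset_id": dataset_id, "reason": str(exc)})
            continue
        summary = res.architecture
        rows.append(
            {
                "dataset_id": dataset_id,
                **summary.as_dict(),
                "model_space_size": res.model_space_size,
                "confidence_set_size": res.n_confidence,
            }
        )
        if keep_results:
            results[dataset_id] = res
        if meta is not None and summary.informative:
            records.append(
                DatasetRecord(
                    dataset_id=dataset_id,
                    species=str(meta["species"]),
                    trait=str(meta["trait"]),
                    trait_class=str(meta["trait_class"]),
                    clade=str(meta["clade"]),
                    divergence=str(meta["divergence"]),
                    summary=summary,
                )
            )
    summaries = pd.DataFrame(
        rows,
        columns=[
            "dataset_id", "prop_additive", "prop_dominance", "prop_epistatic",
            "informative", "n_significant", "model_space_size",
            "confidence_set_size",
        ],
    )
    return PipelineOutput(
        summaries=summaries, records=records, results=results, skipped=skipped
    )
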