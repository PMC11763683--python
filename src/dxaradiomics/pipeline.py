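"""End-to-end pipeline: simulate -> segment -> extract -> resample -> bench.

A run is fully described by a :class:`RunConfig`; rerunning the same config
reproduces every artefact byte for byte.  Each stage persists its outputs
under the run directory::

    images/       annotated cohort PNGs + manifest.csv
    masks/        segmentation masks (binary PNG) + manifest.csv
    features/     nine feature dataset CSVs + labels
    resampled/    45 resampled training CSVs (with an `origin` column)
    report/       benchmark report CSV and the best-per-row summary

The single global seed is expanded deterministically into independent
per-stage seeds, so one number reproduces the whole run.
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from . import bench, resampling, segmentation
from .features import assemble_datasets, extract_cohort
from .synthetic import CohortSpec, generate_cohort, write_cohort

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "load_report",
           "summarise_report", "stage_seeds"]

_STAGES = ("simulate", "segment", "extract", "resample", "bench")


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and offending sample id."""

    def __init__(self, stage: str, sample_id: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed on sample {sample_id!r}: {cause}")
        self.stage = stage
        self.sample_id = sample_id
        self.cause = cause


@dataclass
class RunConfig:
    """Serialisable description of one pipeline run."""

    n_patients: int = 60
    degraded_fraction: float = 0.13
    image_height: int = 300
    image_width: int = 280
    texture_separation: float = 4.0
    seed: int = 0
    n_levels: int = 32
    neighbourhood: int = 5
    min_segment: int = 10
    k_smote: int = 5
    k_enn: int = 3
    train_fraction: float = 0.70
    folds: int = 5
    classifiers: tuple[str, ...] = ("LR", "SVM", "XGB")
    reduced_grids: bool = True
    outdir: str = "run"

    def cohort_spec(self, seed: int) -> CohortSpec:
        return CohortSpec(
            n_patients=self.n_patients,
            degraded_fraction=self.degraded_fraction,
            image_height=self.image_height,
            image_width=self.image_width,
            texture_separation=self.texture_separation,
            seed=seed,
        )

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["classifiers"] = list(self.classifiers)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "classifiers" in d:
            d["classifiers"] = tuple(d["classifiers"])
        return cls(**d)


def stage_seeds(seed: int) -> dict[str, int]:
    """Expand the global seed into one deterministic sub-seed per stage."""
    ss = np.random.SeedSequence(seed)
    states = [int(c.generate_state(1)[0] % (2 ** 31)) for c in ss.spawn(len(_STAGES))]
    return dict(zip(_STAGES, states))


def _write_mask_png(mask: np.ndarray, path: Path) -> None:
    Image.fromarray(mask.astype(np.uint8) * 255, mode="L").save(path)


def run_pipeline(config: RunConfig) -> pd.DataFrame:
    """Execute all five stages, persisting every intermediate artefact;
    returns the benchmark report."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    seeds = stage_seeds(config.seed)

    # 1. simulate
    cohort = generate_cohort(config.cohort_spec(seeds["simulate"]))
    write_cohort(cohort, out)

    # 2. segment
    masks_dir = out / "masks"
    masks_dir.mkdir(exist_ok=True)
    masks = []
    with open(masks_dir / "manifest.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["sample_id", "mask", "n_pixels"])
        for im in cohort:
            try:
                mask = segmentation.build_mask(
                    im.pixels, neighbourhood=config.neighbourhood,
                    min_segment=config.min_segment)
            except segmentation.SegmentationError as exc:
                raise PipelineError("segment", im.sample_id, exc) from exc
            masks.append(mask)
            _write_mask_png(mask, masks_dir / f"{im.sample_id}.png")
            w.writerow([im.sample_id, f"{im.sample_id}.png", int(mask.sum())])

    # 3. extract
    feats_dir = out / "features"
    feats_dir.mkdir(exist_ok=True)
    try:
        table = extract_cohort((im.pixels for im in cohort), masks,
                               n_levels=config.n_levels)
    except Exception as exc:
        raise PipelineError("extract", "<cohort>", exc) from exc
    table.index = [im.sample_id for im in cohort]
    table["label"] = [1 if im.label == "degraded" else 0 for im in cohort]
    datasets = assemble_datasets(table)
    for name, df in datasets.items():
        df.to_csv(feats_dir / f"{name}.csv", index_label="sample_id")

    # 4. split + resample (test partitions are never resampled)
    res_dir = out / "resampled"
    res_dir.mkdir(exist_ok=True)
    split = bench.SplitSpec(train_fraction=config.train_fraction,
                            seed=seeds["resample"])
    train_tables, test_tables = {}, {}
    for name, df in datasets.items():
        train_tables[name], test_tables[name] = bench.stratified_split(df, split)
    resampled = resampling.build_resampled_matrix(
        train_tables, seed=seeds["resample"], k=config.k_smote,
        k_enn=config.k_enn)
    with open(res_dir / "manifest.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["dataset", "technique", "file", "n_rows", "n_synthetic"])
        for (name, tech), res in resampled.items():
            fname = f"{name}__{tech}.csv"
            dumped = res.table.copy()
            dumped["origin"] = res.origin.to_numpy()
            dumped.to_csv(res_dir / fname, index=False)
            w.writerow([name, tech, fname, len(res.table),
                        int((res.origin == "synthetic").sum())])

    # 5. bench
    report_dir = out / "report"
    report_dir.mkdir(exist_ok=True)
    report = bench.run_benchmark(
        resampled, test_tables, classifiers=config.classifiers,
        folds=config.folds, seed=seeds["bench"],
        reduced=config.reduced_grids)
    report.to_csv(report_dir / "report.csv", index=False)
    summarise_report(report).to_csv(report_dir / "best_by_row.csv", index=False)
    with open(report_dir / "split_summary.json", "w") as fh:
        any_name = next(iter(datasets))
        tr, te = train_tables[any_name], test_tables[any_name]
        json.dump({
            "n_train": len(tr), "n_test": len(te),
            "train_degraded": int(tr["label"].sum()),
            "test_degraded": int(te["label"].sum()),
        }, fh, indent=2)
    return report


def load_report(run_dir: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(run_dir) / "report" / "report.csv")


def summarise_report(report: pd.DataFrame) -> pd.DataFrame:
    """Best classifier per (dataset, technique) row, Table-1 style."""
    best = report[report["best"]].copy()
    cols = ["dataset", "technique", "classifier", "sensitivity",
            "f_score", "auc_roc"]
    return best[cols].reset_index(drop=True)
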