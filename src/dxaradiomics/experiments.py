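"""Canned study-scale experiments on synthetic cohorts.

These reproduce, at desk scale, the qualitative findings the benchmark is
designed to surface: oversampling-family resampling outperforms random
undersampling on an imbalanced cohort, and the GLDM+GLRLM feature
combination holds its own against the single-family datasets.  Cohort
sizes are deliberately modest (the experiments regenerate images, extract
features and fit grids per seed) — see the methods note for the chosen
problem sizes.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import pandas as pd

from . import bench
from . import resampling as rs
from .features import extract_cohort, feature_names
from .synthetic import CohortSpec, generate_cohort

__all__ = ["resampling_comparison", "summarise_comparison"]

_DATASET_FAMILIES: dict[str, tuple[str, ...]] = {
    "GLDM-DS": ("GLDM",),
    "GLRLM-DS": ("GLRLM",),
    "GLDM-GLRLM-DS": ("GLDM", "GLRLM"),
}


def resampling_comparison(seeds: Iterable[int],
                          n_patients: int = 240,
                          degraded_fraction: float = 0.13,
                          image_height: int = 120,
                          image_width: int = 112,
                          texture_separation: float = 4.0,
                          datasets: Sequence[str] = tuple(_DATASET_FAMILIES),
                          classifiers: Sequence[str] = ("LR", "SVM"),
                          ) -> pd.DataFrame:
    """Paired resampling comparison over independent synthetic cohorts.

    For every seed: generate an imbalanced annotated cohort, extract the
    requested feature families from the ground-truth ROIs, split 70/30,
    apply all five resampling techniques to each training table and record
    the best held-out F-score over the classifier families (reduced
    grids).  Returns a tidy frame with columns seed/dataset/technique/
    f_score; rows are paired across techniques by construction.
    """
    needed = tuple(sorted({f for name in datasets
                           for f in _DATASET_FAMILIES[name]}))
    records = []
    for seed in seeds:
        spec = CohortSpec(n_patients=n_patients,
                          degraded_fraction=degraded_fraction,
                          image_height=image_height,
                          image_width=image_width,
                          texture_separation=texture_separation,
                          seed=seed)
        feats = extract_cohort(generate_cohort(spec), families=needed)
        split = bench.SplitSpec(seed=seed)
        for name in datasets:
            cols = feature_names(_DATASET_FAMILIES[name]) + ["label"]
            train, test = bench.stratified_split(feats[cols], split)
            resampled = rs.build_resampled_matrix({name: train}, seed=seed)
            for (_, tech), res in resampled.items():
                best_f = max(
                    bench.evaluate(
                        bench.grid_search_cv(res.table, clf, reduced=True,
                                             seed=seed).model,
                        test)["f_score"]
                    for clf in classifiers)
                records.append({"seed": seed, "dataset": name,
                                "technique": tech, "f_score": best_f})
    return pd.DataFrame.from_records(records)


def summarise_comparison(results: pd.DataFrame) -> dict[str, float]:
    """Headline numbers of a :func:`resampling_comparison` frame."""
    over = results[results.technique != "UNDERSAMPLING"]
    under = results[results.technique == "UNDERSAMPLING"]
    paired = (over.groupby("seed").f_score.mean()
              - under.groupby("seed").f_score.mean())
    per = results.groupby(["seed", "dataset"]).f_score.max().unstack()
    singles = [d for d in per.columns if d != "GLDM-GLRLM-DS"]
    out = {
        "oversampling_mean_f": float(over.f_score.mean()),
        "undersampling_mean_f": float(under.f_score.mean()),
        "paired_f_advantage": float(paired.mean()),
    }
    if "GLDM-GLRLM-DS" in per.columns and singles:
        out["combined_minus_best_single_f"] = float(
            (per["GLDM-GLRLM-DS"] - per[singles].max(axis=1)).mean())
    return out
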