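"""Full radiomic feature extraction and assembly of the nine datasets.

The complete signature is 93 features: 18 first-order, 24 GLCM, 16 GLRLM,
16 GLSZM, 14 GLDM and 5 NGTDM.  Shape features are deliberately excluded:
mask geometry reflects overall bone morphology rather than the trabecular
microarchitecture under study.

Nine benchmark datasets are assembled from a cohort's feature vectors: one
per family, the whole feature set (WFS, 93 columns), and two concatenations
that pair the historically strongest families (GLDM+GLRLM, 30 columns;
GLDM+GLRLM+GLSZM, 46 columns).
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import families as fam
from .firstorder import FIRSTORDER_NAMES, first_order_features
from .matrices import glcm, gldm, glrlm, glszm, ngtdm
from .quantise import quantise

__all__ = [
    "FAMILIES",
    "FAMILY_SIZES",
    "DATASET_DEFINITIONS",
    "feature_names",
    "extract_all",
    "extract_cohort",
    "assemble_datasets",
]

FAMILIES: tuple[str, ...] = ("FOIS", "GLCM", "GLRLM", "GLSZM", "GLDM", "NGTDM")

FAMILY_SIZES: dict[str, int] = {
    "FOIS": 18, "GLCM": 24, "GLRLM": 16, "GLSZM": 16, "GLDM": 14, "NGTDM": 5,
}

_FAMILY_NAMES: dict[str, tuple[str, ...]] = {
    "FOIS": FIRSTORDER_NAMES,
    "GLCM": fam.GLCM_NAMES,
    "GLRLM": fam.GLRLM_NAMES,
    "GLSZM": fam.GLSZM_NAMES,
    "GLDM": fam.GLDM_NAMES,
    "NGTDM": fam.NGTDM_NAMES,
}

# dataset name -> constituent families (order fixes the column order)
DATASET_DEFINITIONS: dict[str, tuple[str, ...]] = {
    "FOIS-DS": ("FOIS",),
    "GLCM-DS": ("GLCM",),
    "GLRLM-DS": ("GLRLM",),
    "GLSZM-DS": ("GLSZM",),
    "GLDM-DS": ("GLDM",),
    "NGTDM-DS": ("NGTDM",),
    "WFS": FAMILIES,
    "GLDM-GLRLM-DS": ("GLDM", "GLRLM"),
    "GLDM-GLRLM-GLSZM-DS": ("GLDM", "GLRLM", "GLSZM"),
}


def feature_names(families: Sequence[str] = FAMILIES) -> list[str]:
    """Stable, prefixed column names (``family_featureName``)."""
    names: list[str] = []
    for f in families:
        names.extend(f"{f}_{n}" for n in _FAMILY_NAMES[f])
    return names


def extract_all(image: np.ndarray, mask: np.ndarray,
                families: Sequence[str] = FAMILIES, n_levels: int = 32,
                alpha: int = 0, delta: int = 1) -> dict[str, float]:
    """Compute the requested feature families inside the masked ROI.

    Returns an ordered mapping ``family_featureName -> value``; with all
    six families this is exactly 93 entries.
    """
    unknown = set(families) - set(FAMILIES)
    if unknown:
        raise ValueError(f"unknown families: {sorted(unknown)}")
    out: dict[str, float] = {}
    need_matrix = set(families) - {"FOIS"}
    q = quantise(image, mask, n_levels) if need_matrix else None
    for f in families:
        if f == "FOIS":
            vals = first_order_features(image, mask, n_levels)
        elif f == "GLCM":
            vals = fam.glcm_features(glcm(q))
        elif f == "GLRLM":
            vals = fam.glrlm_features(glrlm(q), q.n_pixels)
        elif f == "GLSZM":
            vals = fam.glszm_features(glszm(q), q.n_pixels)
        elif f == "GLDM":
            vals = fam.gldm_features(gldm(q, alpha=alpha, delta=delta))
        else:  # NGTDM
            vals = fam.ngtdm_features(ngtdm(q, delta=delta))
        out.update({f"{f}_{k}": v for k, v in vals.items()})
    return out


def extract_cohort(images: Iterable, masks: Iterable[np.ndarray] | None = None,
                   families: Sequence[str] = FAMILIES,
                   n_levels: int = 32) -> pd.DataFrame:
    """Feature table for a cohort of annotated images.

    ``images`` may be AnnotatedImage objects (their truth masks are used
    when ``masks`` is None) or raw arrays paired with explicit masks.
    The result carries one row per sample plus a ``label`` column
    (1 = degraded) when labels are available.
    """
    rows, labels, ids = [], [], []
    if masks is None:
        pairs = ((im.pixels, im.truth_mask, im) for im in images)
    else:
        pairs = ((np.asarray(im), m, None) for im, m in zip(images, masks))
    for k, (pix, mask, meta) in enumerate(pairs):
        rows.append(extract_all(pix, mask, families, n_levels))
        if meta is not None:
            labels.append(1 if meta.label == "degraded" else 0)
            ids.append(meta.sample_id or f"s{k:05d}")
        else:
            ids.append(f"s{k:05d}")
    df = pd.DataFrame(rows, columns=feature_names(families), index=ids)
    if labels:
        df["label"] = labels
    return df


def assemble_datasets(features: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Build the nine benchmark datasets from a full 93-feature table.

    ``features`` must contain all 93 prefixed feature columns (and may
    carry a ``label`` column, which is propagated to every dataset).
    """
    missing = set(feature_names()) - set(features.columns)
    if missing:
        raise ValueError(f"feature table lacks columns: {sorted(missing)[:5]}...")
    out = {}
    for name, fams in DATASET_DEFINITIONS.items():
        cols = feature_names(fams)
        if "label" in features.columns:
            cols = cols + ["label"]
        out[name] = features[cols].copy()
    return out
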