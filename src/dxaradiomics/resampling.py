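"""Class-imbalance resampling for radiomic feature tables.

Five techniques: random undersampling, SMOTE, ADASYN and the two hybrid
cleaners SMOTETomek and SMOTEENN.  A feature table is a DataFrame with
numeric feature columns and a binary ``label`` column; the minority class
is whichever label has fewer rows (degraded bone, in this study).

Distances for every neighbour search are Euclidean on z-scored features
(statistics of the input table; radiomic features span orders of
magnitude).  Interpolation itself happens in raw feature space — the two
are equivalent because standardisation is affine.  Nearest-neighbour ties
break toward the lowest row index, which makes every operation
deterministic given its seed.

Cleaning scope: Tomek-link and ENN removal touch only majority-class rows;
synthetic minority samples are never deleted by the hybrid methods.  After
oversampling, synthetic feature values are clamped to the per-column range
of the original table so augmented samples stay within the observed
physiology.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

__all__ = [
    "TECHNIQUES",
    "ResamplingError",
    "SingleClassInput",
    "TooFewMinoritySamples",
    "ResamplingResult",
    "random_undersample",
    "smote",
    "adasyn",
    "tomek_links",
    "remove_majority_of_links",
    "enn_clean",
    "smote_tomek",
    "smote_enn",
    "clip_to_original_range",
    "resample",
    "build_resampled_matrix",
]

TECHNIQUES: tuple[str, ...] = (
    "UNDERSAMPLING", "SMOTE", "ADASYN", "SMOTETomek", "SMOTEENN",
)

ORIGINAL, SYNTHETIC = "original", "synthetic"


class ResamplingError(Exception):
    pass


class SingleClassInput(ResamplingError):
    """Both classes must be present to resample."""


class TooFewMinoritySamples(ResamplingError):
    """SMOTE/ADASYN need more minority samples than neighbours requested."""


@dataclass
class ResamplingResult:
    """A resampled feature table with per-row provenance.

    ``origin`` is aligned with ``table`` and flags each row as
    ``'original'`` or ``'synthetic'``.
    """

    table: pd.DataFrame
    technique: str
    origin: pd.Series
    seed: int

    @property
    def synthetic_rows(self) -> pd.DataFrame:
        return self.table.loc[self.origin.to_numpy() == SYNTHETIC]

    @property
    def original_rows(self) -> pd.DataFrame:
        return self.table.loc[self.origin.to_numpy() == ORIGINAL]


def _split_xy(t: pd.DataFrame):
    if "label" not in t.columns:
        raise ValueError("feature table must carry a 'label' column")
    y = t["label"].to_numpy()
    x = t.drop(columns="label")
    return x, y


def _class_split(y: np.ndarray):
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise SingleClassInput("resampling requires both classes")
    if classes.size > 2:
        raise ValueError("binary labels expected")
    order = np.argsort(counts, kind="stable")
    minority, majority = classes[order[0]], classes[order[1]]
    return minority, majority


def _standardise(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    return (x - mu) / sd


def _knn_indices(query: np.ndarray, pool: np.ndarray, k: int,
                 exclude_self_offset: int | None = None) -> np.ndarray:
    """Indices (into pool) of the k nearest pool points per query row.

    Stable argsort breaks distance ties toward the lowest pool index.
    When query rows are pool rows, ``exclude_self_offset`` gives the pool
    index of query row 0 so each point skips itself.
    """
    d = cdist(query, pool)
    if exclude_self_offset is not None:
        for qi in range(query.shape[0]):
            d[qi, exclude_self_offset + qi] = np.inf
    order = np.argsort(d, axis=1, kind="stable")
    return order[:, :k]


def _result(table: pd.DataFrame, origin: list[str], technique: str,
            seed: int) -> ResamplingResult:
    table = table.reset_index(drop=True)
    return ResamplingResult(
        table=table,
        technique=technique,
        origin=pd.Series(origin, index=table.index, name="origin"),
        seed=seed,
    )


def random_undersample(t: pd.DataFrame, seed: int = 0) -> ResamplingResult:
    """Downsample the majority class, without replacement, to the minority
    count; minority rows are untouched."""
    x, y = _split_xy(t)
    minority, majority = _class_split(y)
    rng = np.random.default_rng(seed)
    maj_pos = np.flatnonzero(y == majority)
    min_pos = np.flatnonzero(y == minority)
    keep_maj = np.sort(rng.choice(maj_pos, size=min_pos.size, replace=False))
    keep = np.sort(np.concatenate([min_pos, keep_maj]))
    out = t.iloc[keep]
    return _result(out, [ORIGINAL] * len(out), "UNDERSAMPLING", seed)


def _interpolate_minority(x_min: np.ndarray, bases: np.ndarray,
                          nbr_choice: np.ndarray, nbrs: np.ndarray,
                          u: np.ndarray) -> np.ndarray:
    picked = nbrs[bases, nbr_choice]
    a = x_min[bases]
    b = x_min[picked]
    return a + u[:, None] * (b - a)


def smote(t: pd.DataFrame, k: int = 5, seed: int = 0) -> ResamplingResult:
    """Synthetic minority oversampling: each new sample lies on the segment
    between a minority point and one of its k nearest minority neighbours."""
    x, y = _split_xy(t)
    minority, majority = _class_split(y)
    n_min = int((y == minority).sum())
    n_maj = int((y == majority).sum())
    if n_min <= k:
        raise TooFewMinoritySamples(
            f"{n_min} minority samples, need > k={k}")
    n_syn = n_maj - n_min
    xv = x.to_numpy(dtype=float)
    min_pos = np.flatnonzero(y == minority)
    x_min = xv[min_pos]
    z = _standardise(xv)
    nbrs = _knn_indices(z[min_pos], z[min_pos], k, exclude_self_offset=0)

    rng = np.random.default_rng(seed)
    bases = rng.integers(0, n_min, size=n_syn)
    nbr_choice = rng.integers(0, k, size=n_syn)
    u = rng.random(n_syn)
    syn = _interpolate_minority(x_min, bases, nbr_choice, nbrs, u)

    syn_df = pd.DataFrame(syn, columns=x.columns)
    syn_df["label"] = minority
    out = pd.concat([t, syn_df], ignore_index=True)
    origin = [ORIGINAL] * len(t) + [SYNTHETIC] * n_syn
    return _result(out, origin, "SMOTE", seed)


def adasyn(t: pd.DataFrame, k: int = 5, seed: int = 0) -> ResamplingResult:
    """Adaptive synthetic oversampling: generation quotas per minority
    sample are proportional to the majority fraction among its k nearest
    neighbours in the full table, so harder boundary regions receive more
    synthetic points.  When no minority sample has majority neighbours the
    density is degenerate and quotas fall back to uniform (SMOTE-like)."""
    x, y = _split_xy(t)
    minority, majority = _class_split(y)
    n_min = int((y == minority).sum())
    n_maj = int((y == majority).sum())
    if n_min <= k:
        raise TooFewMinoritySamples(
            f"{n_min} minority samples, need > k={k}")
    n_syn = n_maj - n_min
    xv = x.to_numpy(dtype=float)
    min_pos = np.flatnonzero(y == minority)
    x_min = xv[min_pos]
    z = _standardise(xv)

    # majority density around each minority sample (neighbours in the whole set)
    d = cdist(z[min_pos], z)
    for qi, p in enumerate(min_pos):
        d[qi, p] = np.inf
    order = np.argsort(d, axis=1, kind="stable")[:, :k]
    r = (y[order] == majority).mean(axis=1)
    if r.sum() == 0:
        quota_frac = np.full(n_min, 1.0 / n_min)
    else:
        quota_frac = r / r.sum()

    # integer quotas: floor + largest remainder, ties to lowest index
    raw = quota_frac * n_syn
    quotas = np.floor(raw).astype(int)
    short = n_syn - quotas.sum()
    if short > 0:
        rem_order = np.argsort(-(raw - quotas), kind="stable")
        quotas[rem_order[:short]] += 1

    nbrs = _knn_indices(z[min_pos], z[min_pos], k, exclude_self_offset=0)
    rng = np.random.default_rng(seed)
    bases = np.repeat(np.arange(n_min), quotas)
    nbr_choice = rng.integers(0, k, size=n_syn)
    u = rng.random(n_syn)
    syn = _interpolate_minority(x_min, bases, nbr_choice, nbrs, u)

    syn_df = pd.DataFrame(syn, columns=x.columns)
    syn_df["label"] = minority
    out = pd.concat([t, syn_df], ignore_index=True)
    origin = [ORIGINAL] * len(t) + [SYNTHETIC] * n_syn
    return _result(out, origin, "ADASYN", seed)


def tomek_links(t: pd.DataFrame) -> list[tuple[int, int]]:
    """Positional index pairs (a, b), a < b, of opposite-label mutual
    nearest neighbours."""
    x, y = _split_xy(t)
    z = _standardise(x.to_numpy(dtype=float))
    nn = _knn_indices(z, z, 1, exclude_self_offset=0)[:, 0]
    links = []
    for a in range(len(y)):
        b = int(nn[a])
        if a < b and nn[b] == a and y[a] != y[b]:
            links.append((a, b))
    return links


def remove_majority_of_links(t: pd.DataFrame,
                             majority_label=None) -> pd.DataFrame:
    """Drop the majority-class member of every Tomek link.

    ``majority_label`` pins the class regarded as majority — needed after
    oversampling, when counts are balanced and the table itself can no
    longer tell which class was originally in excess."""
    _, y = _split_xy(t)
    if majority_label is None:
        _, majority = _class_split(y)
    else:
        majority = majority_label
    drop = set()
    for a, b in tomek_links(t):
        if y[a] == majority:
            drop.add(a)
        if y[b] == majority:
            drop.add(b)
    keep = [i for i in range(len(t)) if i not in drop]
    return t.iloc[keep]


def enn_clean(t: pd.DataFrame, k: int = 3, majority_label=None) -> pd.DataFrame:
    """Edited nearest neighbours restricted to the majority class: a
    majority row is removed when the majority vote of its k nearest
    neighbours (any class, excluding itself) contradicts its label.
    ``majority_label`` pins the cleaned class (see
    :func:`remove_majority_of_links`)."""
    x, y = _split_xy(t)
    if majority_label is None:
        _, majority = _class_split(y)
    else:
        majority = majority_label
    z = _standardise(x.to_numpy(dtype=float))
    nbrs = _knn_indices(z, z, k, exclude_self_offset=0)
    votes = (y[nbrs] == majority).sum(axis=1)
    misclassified = votes < (k / 2.0)  # neighbour vote disagrees with label
    drop = (y == majority) & misclassified
    return t.iloc[~drop]


def _cleaned_result(base: ResamplingResult, cleaned: pd.DataFrame,
                    technique: str) -> ResamplingResult:
    keep = cleaned.index.to_numpy()
    origin = base.origin.iloc[keep].tolist()
    return _result(cleaned, origin, technique, base.seed)


def smote_tomek(t: pd.DataFrame, k: int = 5, seed: int = 0) -> ResamplingResult:
    """SMOTE followed by Tomek-link removal (original-majority members
    only)."""
    _, majority = _class_split(t["label"].to_numpy())
    s = smote(t, k=k, seed=seed)
    cleaned = remove_majority_of_links(s.table, majority_label=majority)
    return _cleaned_result(s, cleaned, "SMOTETomek")


def smote_enn(t: pd.DataFrame, k: int = 5, seed: int = 0,
              k_enn: int = 3) -> ResamplingResult:
    """SMOTE followed by ENN cleaning of the original majority class."""
    _, majority = _class_split(t["label"].to_numpy())
    s = smote(t, k=k, seed=seed)
    cleaned = enn_clean(s.table, k=k_enn, majority_label=majority)
    return _cleaned_result(s, cleaned, "SMOTEENN")


def clip_to_original_range(r: ResamplingResult,
                           original: pd.DataFrame) -> ResamplingResult:
    """Clamp every synthetic row's features to the columnwise [min, max] of
    the original table; original rows pass through untouched."""
    feat_cols = [c for c in r.table.columns if c != "label"]
    lo = original[feat_cols].min(axis=0)
    hi = original[feat_cols].max(axis=0)
    table = r.table.copy()
    syn = r.origin.to_numpy() == SYNTHETIC
    clipped = np.clip(table.loc[syn, feat_cols].to_numpy(dtype=float),
                      lo.to_numpy(dtype=float), hi.to_numpy(dtype=float))
    table.loc[syn, feat_cols] = clipped
    return ResamplingResult(table=table, technique=r.technique,
                            origin=r.origin.copy(), seed=r.seed)


def resample(t: pd.DataFrame, technique: str, seed: int = 0, k: int = 5,
             k_enn: int = 3, clip: bool = True) -> ResamplingResult:
    """Apply one named technique; oversampled outputs are range-clipped to
    the original table unless ``clip`` is False."""
    if technique == "UNDERSAMPLING":
        return random_undersample(t, seed=seed)
    if technique == "SMOTE":
        r = smote(t, k=k, seed=seed)
    elif technique == "ADASYN":
        r = adasyn(t, k=k, seed=seed)
    elif technique == "SMOTETomek":
        r = smote_tomek(t, k=k, seed=seed)
    elif technique == "SMOTEENN":
        r = smote_enn(t, k=k, seed=seed, k_enn=k_enn)
    else:
        raise ValueError(f"unknown technique {technique!r}")
    return clip_to_original_range(r, t) if clip else r


def build_resampled_matrix(train_tables: Mapping[str, pd.DataFrame],
                           seed: int = 0, k: int = 5, k_enn: int = 3,
                           techniques: Iterable[str] = TECHNIQUES,
                           ) -> dict[tuple[str, str], ResamplingResult]:
    """Cartesian product of feature datasets x techniques applied to the
    training partitions: 9 datasets and 5 techniques give the 45 balanced
    training sets of the benchmark."""
    out = {}
    for name, table in train_tables.items():
        for tech in techniques:
            out[(name, tech)] = resample(
                table, tech, seed=seed, k=k, k_enn=k_enn)
    return out
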