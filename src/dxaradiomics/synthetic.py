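"""Synthetic DXA-like cohort generation.

Clinical spine DXA datasets with scanner-software overlays are not publicly
available, so this module emulates the inputs the rest of the pipeline
consumes: grey-level lumbar-spine images carrying enCORE-style annotations
(black lateral contours, white horizontal dividers bounding L1 and L4),
together with ground-truth ROI masks and a binary bone-quality label
(healthy vs degraded trabecular microarchitecture, the TBS threshold
semantics).

Texture model
-------------
Tissue inside the spine contour is a stationary Gaussian random field:
white noise smoothed with a Gaussian kernel and rescaled to a fixed mean
and standard deviation.  Each patient draws an individual kernel width
around a class centre; healthy bone centres on the shorter correlation
length (fine trabecular texture, more fine-scale variance) while degraded
bone centres on a coarser, more homogeneous field.  ``texture_separation``
is the shift between the class centres in units of the between-patient
spread — an effect size, so classes genuinely overlap at realistic
settings and become indistinguishable at zero.  A bright cortical-style
rim lines the inside of each lateral contour, as the cortical shell does
in a real spine projection.  Grey levels are quantised to [1, 254]: value
0 is reserved for contour annotation pixels and 255 for the divider
segments, so annotation detection can never collide with tissue.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter

__all__ = [
    "CohortSpec",
    "AnnotatedImage",
    "LabelRule",
    "generate_cohort",
    "generate_annotated_image",
    "generate_feature_cohort",
    "write_cohort",
]

HEALTHY = "healthy"
DEGRADED = "degraded"

# annotation grey values (8-bit)
CONTOUR_VALUE = 0
DIVIDER_VALUE = 255
TISSUE_MIN, TISSUE_MAX = 1, 254
# cortical rim: the brightest tissue sits against the lateral contour,
# guaranteeing the contour detector's inward-brighter neighbourhood test
_RIM_WIDTH = 5
_RIM_MIN = 140.0
# trabecular texture model: smoothing-kernel width (px) of the healthy
# class centre and the between-patient spread of the kernel width
_SIGMA_HEALTHY = 1.0
_SIGMA_PATIENT_SD = 0.35


@dataclass(frozen=True)
class LabelRule:
    """TBS-equivalent thresholds: <=1.200 degraded, >=1.350 healthy."""

    degraded_threshold: float = 1.200
    healthy_threshold: float = 1.350

    def __post_init__(self) -> None:
        if not self.degraded_threshold < self.healthy_threshold:
            raise ValueError("degraded_threshold must be below healthy_threshold")


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic DXA cohort.

    Defaults mirror the clinical study conditions: ~300x280 px scans and a
    ~13% prevalence of degraded microarchitecture.
    """

    n_patients: int
    degraded_fraction: float = 0.13
    image_height: int = 300
    image_width: int = 280
    texture_separation: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if not 0.0 < self.degraded_fraction < 1.0:
            raise ValueError("degraded_fraction must lie in (0, 1)")
        if self.image_height <= 0 or self.image_width <= 0:
            raise ValueError("image dimensions must be positive")
        if self.texture_separation < 0:
            raise ValueError("texture_separation must be nonnegative")

    @property
    def n_degraded(self) -> int:
        n = int(round(self.n_patients * self.degraded_fraction))
        if n == 0 or n == self.n_patients:
            raise ValueError(
                "degraded_fraction yields a single-class cohort; "
                "adjust n_patients or degraded_fraction"
            )
        return n


@dataclass
class AnnotatedImage:
    """A grey-level image with scanner-style overlay and known ground truth.

    ``left_contour``/``right_contour`` are (n_rows, 2) arrays of (row, col)
    annotation pixels, one per spanned row, 8-connected top to bottom.
    ``divider_rows`` are the rows carrying white horizontal segments; the
    first bounds L1 from above and the last bounds L4 from below.
    """

    pixels: np.ndarray  # uint8, (H, W)
    left_contour: np.ndarray  # (n, 2) int
    right_contour: np.ndarray  # (n, 2) int
    divider_rows: np.ndarray  # sorted int row indices
    truth_mask: np.ndarray  # bool, (H, W)
    label: Literal["healthy", "degraded"]
    sample_id: str = ""

    @property
    def roi_rows(self) -> tuple[int, int]:
        """(top, bottom) rows of the L1-L4 enclosing region."""
        return int(self.divider_rows[0]), int(self.divider_rows[-1])


def _contour_columns(rows: np.ndarray, centre: float, amplitude: float,
                     wavelength: float, phase: float,
                     lo: int, hi: int) -> np.ndarray:
    """Gently curved contour: low-amplitude sinusoid around a vertical line.

    The slope bound amplitude * 2*pi / wavelength < 1 keeps consecutive rows
    8-connected after rounding.
    """
    cols = centre + amplitude * np.sin(2.0 * np.pi * rows / wavelength + phase)
    return np.clip(np.rint(cols).astype(int), lo, hi)


def _texture_field(shape: tuple[int, int], sigma: float, mean: float,
                   sd: float, rng: np.random.Generator) -> np.ndarray:
    noise = rng.standard_normal(shape)
    f = gaussian_filter(noise, sigma=sigma, mode="reflect")
    f = (f - f.mean()) / max(f.std(), 1e-12)
    return mean + sd * f


def generate_annotated_image(spec: CohortSpec, label: str,
                             rng: np.random.Generator,
                             sample_id: str = "") -> AnnotatedImage:
    """Generate one annotated image of the given class."""
    H, W = spec.image_height, spec.image_width
    # contour span: leave a small unannotated margin at top and bottom
    r0 = max(1, int(round(0.06 * H)))
    r1 = H - 1 - r0
    rows = np.arange(r0, r1 + 1)

    half = W // 2
    amp = 3.0 + 3.0 * rng.random()
    wavelength = max(H / 1.5, 40.0 * amp)  # keeps slope < 1 for connectivity
    lphase, rphase = rng.uniform(0, 2 * np.pi, size=2)
    lcentre = 0.33 * W + rng.uniform(-0.02, 0.02) * W
    rcentre = 0.67 * W + rng.uniform(-0.02, 0.02) * W
    lcols = _contour_columns(rows, lcentre, amp, wavelength, lphase,
                             lo=max(2, int(0.1 * W)), hi=half - 2)
    rcols = _contour_columns(rows, rcentre, amp, wavelength, rphase,
                             lo=half + 1, hi=W - 1 - max(2, int(0.1 * W)))

    # five dividers bound the four lumbar vertebrae L1..L4
    d0 = r0 + max(3, int(0.05 * H))
    d1 = r1 - max(3, int(0.05 * H))
    base = np.linspace(d0, d1, 5)
    gap = (d1 - d0) / 4.0
    jitter = rng.uniform(-0.15, 0.15, size=5) * gap
    jitter[0] = abs(jitter[0])
    jitter[-1] = -abs(jitter[-1])
    divider_rows = np.unique(np.rint(base + jitter).astype(int))

    # class-dependent Gaussian random field for the spine tissue: the
    # patient's correlation length is drawn around a class centre, and
    # texture_separation is the class shift in units of the
    # between-patient spread (an effect size, so class overlap is real)
    centre = _SIGMA_HEALTHY
    if label != HEALTHY:
        centre = centre + _SIGMA_PATIENT_SD * spec.texture_separation
    sigma = max(0.4, rng.normal(centre, _SIGMA_PATIENT_SD))
    tissue = _texture_field((H, W), sigma, mean=150.0, sd=35.0, rng=rng)
    # soft tissue background: bounded well below the cortical rim so the
    # contour detector's inward-brighter test holds on every row
    background = np.clip(_texture_field((H, W), 1.5, mean=60.0, sd=8.0, rng=rng),
                         TISSUE_MIN, _RIM_MIN - 20)

    img = background.copy()
    cols = np.arange(W)
    inside = np.zeros((H, W), dtype=bool)
    for r, lc, rc in zip(rows, lcols, rcols):
        inside[r, (cols > lc) & (cols < rc)] = True
    img[inside] = np.clip(tissue[inside], TISSUE_MIN, TISSUE_MAX)
    # bright cortical rim along the inner side of each lateral contour
    for r, lc, rc in zip(rows, lcols, rcols):
        li, ri = lc + 1, min(lc + 1 + _RIM_WIDTH, rc)
        img[r, li:ri] = np.maximum(img[r, li:ri], _RIM_MIN)
        li, ri = max(rc - _RIM_WIDTH, lc + 1), rc
        img[r, li:ri] = np.maximum(img[r, li:ri], _RIM_MIN)
    img = np.rint(img).astype(np.uint8)

    img[rows, lcols] = CONTOUR_VALUE
    img[rows, rcols] = CONTOUR_VALUE
    # white divider segments span strictly between the two contours
    row_to_idx = {int(r): i for i, r in enumerate(rows)}
    for dr in divider_rows:
        i = row_to_idx[int(dr)]
        img[dr, lcols[i] + 1:rcols[i]] = DIVIDER_VALUE

    top, bottom = int(divider_rows[0]), int(divider_rows[-1])
    truth = np.zeros((H, W), dtype=bool)
    for r in range(top, bottom + 1):
        i = row_to_idx[r]
        truth[r, lcols[i]:rcols[i] + 1] = True

    return AnnotatedImage(
        pixels=img,
        left_contour=np.column_stack([rows, lcols]),
        right_contour=np.column_stack([rows, rcols]),
        divider_rows=divider_rows,
        truth_mask=truth,
        label=label,
        sample_id=sample_id,
    )


def generate_cohort(spec: CohortSpec) -> list[AnnotatedImage]:
    """Generate the full annotated cohort.

    Exactly ``round(n_patients * degraded_fraction)`` images carry the
    degraded label.  The same spec (including seed) yields a bit-identical
    cohort.
    """
    n_deg = spec.n_degraded
    root = np.random.SeedSequence([spec.seed, spec.n_patients])
    order_rng = np.random.default_rng(root.spawn(1)[0])
    labels = np.array([DEGRADED] * n_deg + [HEALTHY] * (spec.n_patients - n_deg))
    order_rng.shuffle(labels)
    children = root.spawn(spec.n_patients + 1)[1:]
    cohort = []
    for i, (lab, child) in enumerate(zip(labels, children)):
        rng = np.random.default_rng(child)
        cohort.append(generate_annotated_image(
            spec, str(lab), rng, sample_id=f"p{i:05d}"))
    return cohort


def generate_feature_cohort(n: int, degraded_fraction: float, n_features: int,
                            class_shift: float, seed: int):
    """Two-cluster multivariate-Gaussian feature table, bypassing imaging.

    Both classes have isotropic unit within-class covariance; the class
    means are ``class_shift`` apart in Euclidean (i.e. within-class SD)
    units.  Returns a DataFrame with columns ``f0..f{p-1}`` and ``label``
    (1 = degraded minority, 0 = healthy).
    """
    import pandas as pd

    if n < 4:
        raise ValueError("n must be >= 4")
    if n_features < 1:
        raise ValueError("n_features must be >= 1")
    if class_shift < 0:
        raise ValueError("class_shift must be nonnegative")
    if not 0.0 < degraded_fraction < 1.0:
        raise ValueError("degraded_fraction must lie in (0, 1)")
    n_deg = int(round(n * degraded_fraction))
    if n_deg == 0 or n_deg == n:
        raise ValueError("degraded_fraction yields a single-class table")

    rng = np.random.default_rng(np.random.SeedSequence([seed, n, n_features]))
    shift = np.full(n_features, class_shift / np.sqrt(n_features))
    x = rng.standard_normal((n, n_features))
    y = np.zeros(n, dtype=int)
    idx = rng.permutation(n)[:n_deg]
    y[idx] = 1
    x[y == 1] += shift
    df = pd.DataFrame(x, columns=[f"f{j}" for j in range(n_features)])
    df["label"] = y
    return df


def write_cohort(cohort: list[AnnotatedImage], outdir: str | Path,
                 write_truth_masks: bool = True) -> Path:
    """Write images (8-bit grey PNG), truth masks (binary PNG) and a
    manifest CSV; returns the manifest path."""
    outdir = Path(outdir)
    (outdir / "images").mkdir(parents=True, exist_ok=True)
    if write_truth_masks:
        (outdir / "truth_masks").mkdir(parents=True, exist_ok=True)
    manifest = outdir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["sample_id", "image", "truth_mask", "label"])
        for im in cohort:
            name = f"{im.sample_id}.png"
            Image.fromarray(im.pixels, mode="L").save(outdir / "images" / name)
            mask_path = ""
            if write_truth_masks:
                mask_png = (im.truth_mask.astype(np.uint8) * 255)
                Image.fromarray(mask_png, mode="L").save(
                    outdir / "truth_masks" / name)
                mask_path = f"truth_masks/{name}"
            w.writerow([im.sample_id, f"images/{name}", mask_path, im.label])
    return manifest
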