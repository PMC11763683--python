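"""Scalar texture features derived from the grey-level matrices.

Feature definitions follow the standard reference radiomics formulary
(IBSI-aligned): 24 GLCM, 16 GLRLM, 16 GLSZM, 14 GLDM and 5 NGTDM features.
Directional families (GLCM, GLRLM) are computed per offset and averaged
over the four 2D angles.  Degenerate-case conventions: 0*log(0) = 0,
correlation of a constant ROI is 1, NGTDM coarseness is capped at 1e6 when
its denominator vanishes.
"""

from __future__ import annotations

import numpy as np

from .matrices import TextureMatrix

__all__ = [
    "GLCM_NAMES", "GLRLM_NAMES", "GLSZM_NAMES", "GLDM_NAMES", "NGTDM_NAMES",
    "glcm_features", "glrlm_features", "glszm_features", "gldm_features",
    "ngtdm_features",
]

_COARSENESS_CAP = 1e6

GLCM_NAMES: tuple[str, ...] = (
    "Autocorrelation", "JointAverage", "ClusterProminence", "ClusterShade",
    "ClusterTendency", "Contrast", "Correlation", "DifferenceAverage",
    "DifferenceEntropy", "DifferenceVariance", "JointEnergy", "JointEntropy",
    "Imc1", "Imc2", "Idm", "Idmn", "Id", "Idn", "InverseVariance",
    "MaximumProbability", "SumAverage", "SumEntropy", "SumSquares", "MCC",
)

GLRLM_NAMES: tuple[str, ...] = (
    "ShortRunEmphasis", "LongRunEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized", "RunPercentage",
    "GrayLevelVariance", "RunVariance", "RunEntropy",
    "LowGrayLevelRunEmphasis", "HighGrayLevelRunEmphasis",
    "ShortRunLowGrayLevelEmphasis", "ShortRunHighGrayLevelEmphasis",
    "LongRunLowGrayLevelEmphasis", "LongRunHighGrayLevelEmphasis",
)

GLSZM_NAMES: tuple[str, ...] = (
    "SmallAreaEmphasis", "LargeAreaEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized", "ZonePercentage",
    "GrayLevelVariance", "ZoneVariance", "ZoneEntropy",
    "LowGrayLevelZoneEmphasis", "HighGrayLevelZoneEmphasis",
    "SmallAreaLowGrayLevelEmphasis", "SmallAreaHighGrayLevelEmphasis",
    "LargeAreaLowGrayLevelEmphasis", "LargeAreaHighGrayLevelEmphasis",
)

GLDM_NAMES: tuple[str, ...] = (
    "SmallDependenceEmphasis", "LargeDependenceEmphasis",
    "GrayLevelNonUniformity", "DependenceNonUniformity",
    "DependenceNonUniformityNormalized", "GrayLevelVariance",
    "DependenceVariance", "DependenceEntropy", "LowGrayLevelEmphasis",
    "HighGrayLevelEmphasis", "SmallDependenceLowGrayLevelEmphasis",
    "SmallDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
)

NGTDM_NAMES: tuple[str, ...] = (
    "Coarseness", "Contrast", "Busyness", "Complexity", "Strength",
)


def _xlog2(p: np.ndarray) -> np.ndarray:
    """p * log2(p) with the 0*log(0) = 0 convention."""
    out = np.zeros_like(p, dtype=float)
    nz = p > 0
    out[nz] = p[nz] * np.log2(p[nz])
    return out


def _glcm_features_single(P: np.ndarray) -> dict[str, float]:
    ng = P.shape[0]
    total = P.sum()
    P = P / total if total > 0 else P
    i = np.arange(1, ng + 1, dtype=float)
    I, J = np.meshgrid(i, i, indexing="ij")

    px = P.sum(axis=1)
    py = P.sum(axis=0)
    ux = float((i * px).sum())
    uy = float((i * py).sum())
    sigx = float(np.sqrt(((i - ux) ** 2 * px).sum()))
    sigy = float(np.sqrt(((i - uy) ** 2 * py).sum()))

    # diagonal (|i-j|) and cross-diagonal (i+j) probability distributions
    kd = np.arange(0, ng, dtype=float)
    p_diff = np.zeros(ng)
    np.add.at(p_diff, np.abs(I - J).astype(int), P)
    ks = np.arange(2, 2 * ng + 1, dtype=float)
    p_sum = np.zeros(2 * ng - 1)
    np.add.at(p_sum, (I + J).astype(int) - 2, P)

    hxy = float(-_xlog2(P).sum())
    hx = float(-_xlog2(px).sum())
    hy = float(-_xlog2(py).sum())
    pxpy = np.outer(px, py)
    nz = (P > 0) & (pxpy > 0)
    hxy1 = float(-(P[nz] * np.log2(pxpy[nz])).sum())
    hxy2 = float(-_xlog2(pxpy).sum())

    if sigx * sigy > 0:
        correlation = ((I * J * P).sum() - ux * uy) / (sigx * sigy)
    else:
        correlation = 1.0

    max_h = max(hx, hy)
    imc1 = (hxy - hxy1) / max_h if max_h > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    da = float((kd * p_diff).sum())

    # maximal correlation coefficient: sqrt of the second-largest eigenvalue
    # of Q(i,j) = sum_k p(i,k) p(j,k) / (px(i) py(k)), over occupied levels
    occ = px > 0
    if occ.sum() < 2:
        mcc = 1.0
    else:
        Psub = P[np.ix_(occ, occ)]
        pxs = px[occ]
        pys = py[occ]
        Q = (Psub / pxs[:, None]) @ (Psub / pys[None, :]).T
        eig = np.sort(np.abs(np.linalg.eigvals(Q)))
        mcc = float(np.sqrt(max(0.0, eig[-2].real)))

    return {
        "Autocorrelation": float((I * J * P).sum()),
        "JointAverage": ux,
        "ClusterProminence": float(((I + J - ux - uy) ** 4 * P).sum()),
        "ClusterShade": float(((I + J - ux - uy) ** 3 * P).sum()),
        "ClusterTendency": float(((I + J - ux - uy) ** 2 * P).sum()),
        "Contrast": float(((I - J) ** 2 * P).sum()),
        "Correlation": float(correlation),
        "DifferenceAverage": da,
        "DifferenceEntropy": float(-_xlog2(p_diff).sum()),
        "DifferenceVariance": float(((kd - da) ** 2 * p_diff).sum()),
        "JointEnergy": float((P ** 2).sum()),
        "JointEntropy": hxy,
        "Imc1": float(imc1),
        "Imc2": imc2,
        "Idm": float((p_diff / (1.0 + kd ** 2)).sum()),
        "Idmn": float((p_diff / (1.0 + (kd / ng) ** 2)).sum()),
        "Id": float((p_diff / (1.0 + kd)).sum()),
        "Idn": float((p_diff / (1.0 + kd / ng)).sum()),
        "InverseVariance": float((p_diff[1:] / kd[1:] ** 2).sum()),
        "MaximumProbability": float(P.max()),
        "SumAverage": float((ks * p_sum).sum()),
        "SumEntropy": float(-_xlog2(p_sum).sum()),
        "SumSquares": float(((I - ux) ** 2 * P).sum()),
        "MCC": mcc,
    }


def _average_directions(per_direction: list[dict[str, float]],
                        names: tuple[str, ...]) -> dict[str, float]:
    return {k: float(np.mean([d[k] for d in per_direction])) for k in names}


def glcm_features(m: TextureMatrix) -> dict[str, float]:
    """The 24 co-occurrence features, averaged over the four angles."""
    if m.family != "GLCM":
        raise ValueError("expected a GLCM TextureMatrix")
    per_dir = [_glcm_features_single(m.values[k].astype(float))
               for k in range(m.values.shape[0])]
    return _average_directions(per_dir, GLCM_NAMES)


def _rl_features_single(P: np.ndarray, n_pixels: int,
                        zone_word: str) -> dict[str, float]:
    """Shared run-length / size-zone feature kernel.

    ``P[g-1, l-1]`` counts runs (zones) of level g and length (size) l.
    ``zone_word`` selects the GLRLM or GLSZM naming scheme.
    """
    ng, nl = P.shape
    ns = P.sum()
    g = np.arange(1, ng + 1, dtype=float)
    l = np.arange(1, nl + 1, dtype=float)
    G, L = np.meshgrid(g, l, indexing="ij")
    p = P / ns
    mu_g = float((G * p).sum())
    mu_l = float((L * p).sum())
    rg = P.sum(axis=1)  # per grey level
    rl = P.sum(axis=0)  # per length/size

    if zone_word == "run":
        names = GLRLM_NAMES
    else:
        names = GLSZM_NAMES
    vals = (
        float((P / L ** 2).sum() / ns),                     # short/small emphasis
        float((P * L ** 2).sum() / ns),                     # long/large emphasis
        float((rg ** 2).sum() / ns),                        # GLN
        float((rg ** 2).sum() / ns ** 2),                   # GLNN
        float((rl ** 2).sum() / ns),                        # RLN / SZN
        float((rl ** 2).sum() / ns ** 2),                   # RLNN / SZNN
        float(ns / n_pixels),                               # run/zone percentage
        float(((G - mu_g) ** 2 * p).sum()),                 # grey-level variance
        float(((L - mu_l) ** 2 * p).sum()),                 # run/zone variance
        float(-_xlog2(p).sum()),                            # entropy
        float((P / G ** 2).sum() / ns),                     # low grey-level emphasis
        float((P * G ** 2).sum() / ns),                     # high grey-level emphasis
        float((P / (G ** 2 * L ** 2)).sum() / ns),
        float((P * G ** 2 / L ** 2).sum() / ns),
        float((P * L ** 2 / G ** 2).sum() / ns),
        float((P * G ** 2 * L ** 2).sum() / ns),
    )
    return dict(zip(names, vals))


def glrlm_features(m: TextureMatrix, n_pixels: int) -> dict[str, float]:
    """The 16 run-length features, averaged over the four directions."""
    if m.family != "GLRLM":
        raise ValueError("expected a GLRLM TextureMatrix")
    per_dir = [_rl_features_single(m.values[k].astype(float), n_pixels, "run")
               for k in range(m.values.shape[0])]
    return _average_directions(per_dir, GLRLM_NAMES)


def glszm_features(m: TextureMatrix, n_pixels: int) -> dict[str, float]:
    """The 16 size-zone features (zones are directionless)."""
    if m.family != "GLSZM":
        raise ValueError("expected a GLSZM TextureMatrix")
    return _rl_features_single(m.values.astype(float), n_pixels, "zone")


def gldm_features(m: TextureMatrix) -> dict[str, float]:
    """The 14 dependence-matrix features."""
    if m.family != "GLDM":
        raise ValueError("expected a GLDM TextureMatrix")
    P = m.values.astype(float)
    ng, nd = P.shape
    nz = P.sum()
    g = np.arange(1, ng + 1, dtype=float)
    j = np.arange(1, nd + 1, dtype=float)
    G, Jm = np.meshgrid(g, j, indexing="ij")
    p = P / nz
    mu_g = float((G * p).sum())
    mu_j = float((Jm * p).sum())
    pg = P.sum(axis=1)
    pj = P.sum(axis=0)
    return {
        "SmallDependenceEmphasis": float((P / Jm ** 2).sum() / nz),
        "LargeDependenceEmphasis": float((P * Jm ** 2).sum() / nz),
        "GrayLevelNonUniformity": float((pg ** 2).sum() / nz),
        "DependenceNonUniformity": float((pj ** 2).sum() / nz),
        "DependenceNonUniformityNormalized": float((pj ** 2).sum() / nz ** 2),
        "GrayLevelVariance": float(((G - mu_g) ** 2 * p).sum()),
        "DependenceVariance": float(((Jm - mu_j) ** 2 * p).sum()),
        "DependenceEntropy": float(-_xlog2(p).sum()),
        "LowGrayLevelEmphasis": float((P / G ** 2).sum() / nz),
        "HighGrayLevelEmphasis": float((P * G ** 2).sum() / nz),
        "SmallDependenceLowGrayLevelEmphasis":
            float((P / (G ** 2 * Jm ** 2)).sum() / nz),
        "SmallDependenceHighGrayLevelEmphasis":
            float((P * G ** 2 / Jm ** 2).sum() / nz),
        "LargeDependenceLowGrayLevelEmphasis":
            float((P * Jm ** 2 / G ** 2).sum() / nz),
        "LargeDependenceHighGrayLevelEmphasis":
            float((P * G ** 2 * Jm ** 2).sum() / nz),
    }


def ngtdm_features(m: TextureMatrix) -> dict[str, float]:
    """Coarseness, contrast, busyness, complexity and strength."""
    if m.family != "NGTDM":
        raise ValueError("expected an NGTDM TextureMatrix")
    p_all = m.values[:, 0]
    s_all = m.values[:, 1]
    n_all = m.values[:, 2]
    occ = p_all > 0
    p = p_all[occ]
    s = s_all[occ]
    i = np.arange(1, m.values.shape[0] + 1, dtype=float)[occ]
    ngp = int(occ.sum())
    nvp = float(n_all.sum())

    denom_coarse = float((p * s).sum())
    coarseness = 1.0 / denom_coarse if denom_coarse > 0 else _COARSENESS_CAP
    coarseness = min(coarseness, _COARSENESS_CAP)

    if ngp > 1 and nvp > 0:
        ii, jj = np.meshgrid(i, i, indexing="ij")
        pi, pj = np.meshgrid(p, p, indexing="ij")
        contrast = (float((pi * pj * (ii - jj) ** 2).sum())
                    / (ngp * (ngp - 1))) * (float(s_all.sum()) / nvp)
        denom_busy = float(np.abs(ii * pi - jj * pj).sum())
        busyness = float((p * s).sum()) / denom_busy if denom_busy > 0 else 0.0
        si, sj = np.meshgrid(s, s, indexing="ij")
        complexity = float((np.abs(ii - jj)
                            * (pi * si + pj * sj) / (pi + pj)).sum()) / nvp
        s_sum = float(s_all.sum())
        strength = (float(((pi + pj) * (ii - jj) ** 2).sum()) / s_sum
                    if s_sum > 0 else 0.0)
    else:
        contrast = busyness = complexity = strength = 0.0

    return {
        "Coarseness": float(coarseness),
        "Contrast": float(contrast),
        "Busyness": float(busyness),
        "Complexity": float(complexity),
        "Strength": float(strength),
    }
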