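"""Feature formulas for the five texture-matrix families.

Counts come from :mod:`rotomics.features.matrices`; formulas follow the
standard (IBSI-aligned) definitions.  Family cardinalities are fixed:
GLCM 24, GLRLM 16, GLSZM 16, GLDM 14, NGTDM 5.

Degenerate-input policy (documented constants, never NaN): on a single gray
level, GLCM Correlation and MCC return 1.0 and Imc1/Imc2 return 0.0; NGTDM
Coarseness returns 1e6 when its denominator vanishes, Contrast/Busyness/
Strength return 0.0.
"""

from __future__ import annotations

import numpy as np

from .matrices import glcm_matrix, gldm_matrix, glrlm_matrix, glszm_matrix, ngtdm_table

__all__ = [
    "glcm_features", "glrlm_features", "glszm_features", "gldm_features",
    "ngtdm_features",
    "GLCM_NAMES", "GLRLM_NAMES", "GLSZM_NAMES", "GLDM_NAMES", "NGTDM_NAMES",
]

_EPS = np.finfo(np.float64).eps

GLCM_NAMES = (
    "Autocorrelation", "ClusterProminence", "ClusterShade", "ClusterTendency",
    "Contrast", "Correlation", "DifferenceAverage", "DifferenceEntropy",
    "DifferenceVariance", "Id", "Idm", "Idmn", "Idn", "Imc1", "Imc2",
    "InverseVariance", "JointAverage", "JointEnergy", "JointEntropy",
    "MaximumProbability", "MCC", "SumAverage", "SumEntropy", "SumSquares",
)

GLRLM_NAMES = (
    "GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance", "HighGrayLevelRunEmphasis", "LongRunEmphasis",
    "LongRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
    "LowGrayLevelRunEmphasis", "RunEntropy", "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized", "RunPercentage", "RunVariance",
    "ShortRunEmphasis", "ShortRunHighGrayLevelEmphasis",
    "ShortRunLowGrayLevelEmphasis",
)

GLSZM_NAMES = (
    "GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance", "HighGrayLevelZoneEmphasis", "LargeAreaEmphasis",
    "LargeAreaHighGrayLevelEmphasis", "LargeAreaLowGrayLevelEmphasis",
    "LowGrayLevelZoneEmphasis", "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized", "SmallAreaEmphasis",
    "SmallAreaHighGrayLevelEmphasis", "SmallAreaLowGrayLevelEmphasis",
    "ZoneEntropy", "ZonePercentage", "ZoneVariance",
)

GLDM_NAMES = (
    "DependenceEntropy", "DependenceNonUniformity",
    "DependenceNonUniformityNormalized", "DependenceVariance",
    "GrayLevelNonUniformity", "GrayLevelVariance", "HighGrayLevelEmphasis",
    "LargeDependenceEmphasis", "LargeDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis", "LowGrayLevelEmphasis",
    "SmallDependenceEmphasis", "SmallDependenceHighGrayLevelEmphasis",
    "SmallDependenceLowGrayLevelEmphasis",
)

NGTDM_NAMES = ("Busyness", "Coarseness", "Complexity", "Contrast", "Strength")


def glcm_features(levels: np.ndarray, mask: np.ndarray, distance: int = 1,
                  counts: np.ndarray | None = None) -> dict[str, float]:
    """24 co-occurrence descriptors, averaged over the 13 directions.

    All per-direction quantities are computed batched on the (13, Ng, Ng)
    probability stack; only MCC needs a short per-direction eigenvalue loop.
    """
    if counts is None:
        counts = glcm_matrix(levels, mask, distance)
    nd, ng, _ = counts.shape
    p = counts / counts.sum(axis=(1, 2), keepdims=True)
    i = np.arange(1, ng + 1, dtype=np.float64)
    ii = i[None, :, None]
    jj = i[None, None, :]
    px = p.sum(axis=2)  # (nd, ng)
    py = p.sum(axis=1)
    mu_x = (px * i).sum(axis=1)  # (nd,)
    mu_y = (py * i).sum(axis=1)
    sig_x = np.sqrt((px * (i[None, :] - mu_x[:, None]) ** 2).sum(axis=1))
    sig_y = np.sqrt((py * (i[None, :] - mu_y[:, None]) ** 2).sum(axis=1))
    # sum (k=2..2Ng) and difference (k=0..Ng-1) distributions, batched via
    # bincount on direction-offset flattened indices
    ks = np.arange(2, 2 * ng + 1, dtype=np.float64)
    kd = np.arange(0, ng, dtype=np.float64)
    sum_idx = (i[:, None] + i[None, :] - 2).astype(np.int64)
    diff_idx = np.abs(i[:, None] - i[None, :]).astype(np.int64)
    dir_off = np.arange(nd)[:, None, None]
    p_sum = np.bincount((sum_idx[None] + dir_off * (2 * ng - 1)).ravel(),
                        weights=p.ravel(), minlength=nd * (2 * ng - 1)
                        ).reshape(nd, 2 * ng - 1)
    p_diff = np.bincount((diff_idx[None] + dir_off * ng).ravel(),
                         weights=p.ravel(), minlength=nd * ng).reshape(nd, ng)
    diff_avg = (kd * p_diff).sum(axis=1)
    hx = -(px * np.log2(px + _EPS)).sum(axis=1)
    hy = -(py * np.log2(py + _EPS)).sum(axis=1)
    hxy = -(p * np.log2(p + _EPS)).sum(axis=(1, 2))
    pxpy = px[:, :, None] * py[:, None, :]
    log_pxpy = np.log2(pxpy + _EPS)
    hxy1 = -(p * log_pxpy).sum(axis=(1, 2))
    hxy2 = -(pxpy * log_pxpy).sum(axis=(1, 2))
    mcc = np.ones(nd)
    for k in range(nd):
        nz = px[k] > 0
        if nz.sum() > 1:
            psub = p[k][np.ix_(nz, nz)]
            q = (psub / px[k][nz][:, None]) @ (psub / py[k][nz][None, :]).T
            eig = np.sort(np.abs(np.linalg.eigvals(q)))[::-1]
            mcc[k] = np.sqrt(max(eig[1], 0.0))
    autoc = (p * ii * jj).sum(axis=(1, 2))
    ok = (sig_x > 0) & (sig_y > 0)
    corr = np.ones(nd)
    corr[ok] = (autoc[ok] - mu_x[ok] * mu_y[ok]) / (sig_x[ok] * sig_y[ok])
    hmax = np.maximum(hx, hy)
    imc1 = np.where(hmax > 0, (hxy - hxy1) / np.where(hmax > 0, hmax, 1.0), 0.0)
    imc2 = np.sqrt(np.clip(1.0 - np.exp(-2.0 * (hxy2 - hxy)), 0.0, None))
    csum = ii + jj - (mu_x + mu_y)[:, None, None]
    vals = {
        "Autocorrelation": autoc,
        "ClusterProminence": (p * csum**4).sum(axis=(1, 2)),
        "ClusterShade": (p * csum**3).sum(axis=(1, 2)),
        "ClusterTendency": (p * csum**2).sum(axis=(1, 2)),
        "Contrast": (p * (ii - jj) ** 2).sum(axis=(1, 2)),
        "Correlation": corr,
        "DifferenceAverage": diff_avg,
        "DifferenceEntropy": -(p_diff * np.log2(p_diff + _EPS)).sum(axis=1),
        "DifferenceVariance": (p_diff * (kd[None] - diff_avg[:, None]) ** 2).sum(axis=1),
        "Id": (p_diff / (1.0 + kd)).sum(axis=1),
        "Idm": (p_diff / (1.0 + kd**2)).sum(axis=1),
        "Idmn": (p_diff / (1.0 + kd**2 / ng**2)).sum(axis=1),
        "Idn": (p_diff / (1.0 + kd / ng)).sum(axis=1),
        "Imc1": imc1,
        "Imc2": imc2,
        "InverseVariance": (p_diff[:, 1:] / kd[1:] ** 2).sum(axis=1) if ng > 1
                           else np.zeros(nd),
        "JointAverage": mu_x,
        "JointEnergy": (p**2).sum(axis=(1, 2)),
        "JointEntropy": hxy,
        "MaximumProbability": p.max(axis=(1, 2)),
        "SumAverage": (ks * p_sum).sum(axis=1),
        "SumEntropy": -(p_sum * np.log2(p_sum + _EPS)).sum(axis=1),
        "SumSquares": (p * (ii - mu_x[:, None, None]) ** 2).sum(axis=(1, 2)),
        "MCC": mcc,
    }
    return {name: float(vals[name].mean()) for name in GLCM_NAMES}


def _rlm_szm_core(mat: np.ndarray, n_vox: int, prefix: dict[str, str]) -> dict[str, float]:
    """Shared formulas of the run-length / size-zone families.

    ``mat`` is (Ng, Smax) counts; ``prefix`` maps the generic keys to the
    family's feature names.
    """
    total = mat.sum()
    p = mat / total
    ng, smax = mat.shape
    i = np.arange(1, ng + 1, dtype=np.float64)[:, None]
    s = np.arange(1, smax + 1, dtype=np.float64)[None, :]
    pg = mat.sum(axis=1)  # per gray level
    ps = mat.sum(axis=0)  # per size
    mu_i = float((p * i).sum())
    mu_s = float((p * s).sum())
    sv = s[0]
    return {
        prefix["GLN"]: float((pg.astype(np.float64) ** 2).sum() / total),
        prefix["GLNN"]: float((pg.astype(np.float64) ** 2).sum() / total**2),
        prefix["GLV"]: float((p * (i - mu_i) ** 2).sum()),
        prefix["HGL"]: float((p * i**2).sum()),
        prefix["LGL"]: float((p / i**2).sum()),
        prefix["LARGE"]: float((p * s**2).sum()),
        prefix["LARGE_HGL"]: float((p * i**2 * s**2).sum()),
        prefix["LARGE_LGL"]: float((p * s**2 / i**2).sum()),
        prefix["SN"]: float((ps.astype(np.float64) ** 2).sum() / total),
        prefix["SNN"]: float((ps.astype(np.float64) ** 2).sum() / total**2),
        prefix["SMALL"]: float((p / s**2).sum()),
        prefix["SMALL_HGL"]: float((p * i**2 / s**2).sum()),
        prefix["SMALL_LGL"]: float((p / (i**2 * s**2)).sum()),
        prefix["ENTROPY"]: float(-(p * np.log2(p + _EPS)).sum()),
        prefix["PCT"]: float(total / n_vox),
        prefix["SV"]: float((p * (s - mu_s) ** 2).sum()),
    }


_GLRLM_KEYMAP = {
    "GLN": "GrayLevelNonUniformity", "GLNN": "GrayLevelNonUniformityNormalized",
    "GLV": "GrayLevelVariance", "HGL": "HighGrayLevelRunEmphasis",
    "LARGE": "LongRunEmphasis", "LARGE_HGL": "LongRunHighGrayLevelEmphasis",
    "LARGE_LGL": "LongRunLowGrayLevelEmphasis", "LGL": "LowGrayLevelRunEmphasis",
    "ENTROPY": "RunEntropy", "SN": "RunLengthNonUniformity",
    "SNN": "RunLengthNonUniformityNormalized", "PCT": "RunPercentage",
    "SV": "RunVariance", "SMALL": "ShortRunEmphasis",
    "SMALL_HGL": "ShortRunHighGrayLevelEmphasis",
    "SMALL_LGL": "ShortRunLowGrayLevelEmphasis",
}

_GLSZM_KEYMAP = {
    "GLN": "GrayLevelNonUniformity", "GLNN": "GrayLevelNonUniformityNormalized",
    "GLV": "GrayLevelVariance", "HGL": "HighGrayLevelZoneEmphasis",
    "LARGE": "LargeAreaEmphasis", "LARGE_HGL": "LargeAreaHighGrayLevelEmphasis",
    "LARGE_LGL": "LargeAreaLowGrayLevelEmphasis", "LGL": "LowGrayLevelZoneEmphasis",
    "SN": "SizeZoneNonUniformity", "SNN": "SizeZoneNonUniformityNormalized",
    "SMALL": "SmallAreaEmphasis", "SMALL_HGL": "SmallAreaHighGrayLevelEmphasis",
    "SMALL_LGL": "SmallAreaLowGrayLevelEmphasis", "ENTROPY": "ZoneEntropy",
    "PCT": "ZonePercentage", "SV": "ZoneVariance",
}


def glrlm_features(levels: np.ndarray, mask: np.ndarray,
                   counts: np.ndarray | None = None) -> dict[str, float]:
    """16 run-length descriptors, averaged over the 13 directions."""
    if counts is None:
        counts = glrlm_matrix(levels, mask)
    n_vox = int((np.asarray(mask) > 0).sum())
    acc = {name: 0.0 for name in GLRLM_NAMES}
    for k in range(counts.shape[0]):
        for key, val in _rlm_szm_core(counts[k], n_vox, _GLRLM_KEYMAP).items():
            acc[key] += val
    n = counts.shape[0]
    return {name: acc[name] / n for name in GLRLM_NAMES}


def glszm_features(levels: np.ndarray, mask: np.ndarray,
                   counts: np.ndarray | None = None) -> dict[str, float]:
    """16 size-zone descriptors (single zone matrix, no direction average)."""
    if counts is None:
        counts = glszm_matrix(levels, mask)
    n_vox = int((np.asarray(mask) > 0).sum())
    vals = _rlm_szm_core(counts, n_vox, _GLSZM_KEYMAP)
    return {name: vals[name] for name in GLSZM_NAMES}


def gldm_features(levels: np.ndarray, mask: np.ndarray, alpha: int = 0,
                  counts: np.ndarray | None = None) -> dict[str, float]:
    """14 dependence descriptors."""
    if counts is None:
        counts = gldm_matrix(levels, mask, alpha)
    total = counts.sum()
    p = counts / total
    ng, jmax = counts.shape
    i = np.arange(1, ng + 1, dtype=np.float64)[:, None]
    j = np.arange(1, jmax + 1, dtype=np.float64)[None, :]
    pg = counts.sum(axis=1).astype(np.float64)
    pj = counts.sum(axis=0).astype(np.float64)
    mu_i = float((p * i).sum())
    mu_j = float((p * j).sum())
    return {
        "DependenceEntropy": float(-(p * np.log2(p + _EPS)).sum()),
        "DependenceNonUniformity": float((pj**2).sum() / total),
        "DependenceNonUniformityNormalized": float((pj**2).sum() / total**2),
        "DependenceVariance": float((p * (j - mu_j) ** 2).sum()),
        "GrayLevelNonUniformity": float((pg**2).sum() / total),
        "GrayLevelVariance": float((p * (i - mu_i) ** 2).sum()),
        "HighGrayLevelEmphasis": float((p * i**2).sum()),
        "LargeDependenceEmphasis": float((p * j**2).sum()),
        "LargeDependenceHighGrayLevelEmphasis": float((p * i**2 * j**2).sum()),
        "LargeDependenceLowGrayLevelEmphasis": float((p * j**2 / i**2).sum()),
        "LowGrayLevelEmphasis": float((p / i**2).sum()),
        "SmallDependenceEmphasis": float((p / j**2).sum()),
        "SmallDependenceHighGrayLevelEmphasis": float((p * i**2 / j**2).sum()),
        "SmallDependenceLowGrayLevelEmphasis": float((p / (i**2 * j**2)).sum()),
    }


def ngtdm_features(levels: np.ndarray, mask: np.ndarray,
                   table: dict[str, np.ndarray] | None = None) -> dict[str, float]:
    """5 neighbourhood gray-tone-difference descriptors."""
    if table is None:
        table = ngtdm_table(levels, mask)
    n, p, s = table["n"], table["p"], table["s"]
    nvp = int(n.sum())
    present = p > 0
    ngp = int(present.sum())
    i = np.arange(1, len(p) + 1, dtype=np.float64)
    ip, pp, sp = i[present], p[present], s[present]
    ps_sum = float((pp * sp).sum())
    coarseness = 1.0 / ps_sum if ps_sum > 0 else 1e6
    if ngp > 1 and nvp > 0:
        dij2 = (ip[:, None] - ip[None, :]) ** 2
        contrast = float((pp[:, None] * pp[None, :] * dij2).sum()) \
            / (ngp * (ngp - 1)) * float(s.sum()) / nvp
        busy_den = float(np.abs(ip[:, None] * pp[:, None] - ip[None, :] * pp[None, :]).sum())
        busyness = ps_sum / busy_den if busy_den > 0 else 0.0
        absdiff = np.abs(ip[:, None] - ip[None, :])
        num = (pp[:, None] * sp[:, None] + pp[None, :] * sp[None, :])
        den = pp[:, None] + pp[None, :]
        complexity = float((absdiff * num / den).sum()) / nvp
        s_sum = float(s.sum())
        strength = float((den * dij2).sum()) / s_sum if s_sum > 0 else 0.0
    else:
        contrast, busyness, complexity, strength = 0.0, 0.0, 0.0, 0.0
    return {
        "Busyness": busyness,
        "Coarseness": coarseness,
        "Complexity": complexity,
        "Contrast": contrast,
        "Strength": strength,
    }
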