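"""Feature-level rotation-stability statistics.

For every feature: signed percentage differences (%d) of rotated vs original
values per patient, per-rotation-set IQRs with a Student-t confidence interval
on their mean, a pooled Spearman rank correlation of |%d| against the rotation
label, and the effect-size stratum of that correlation
(trivial |CC| < 0.1, weak < 0.3, moderate < 0.7, strong >= 0.7).
A feature is flagged ``significant_nontrivial`` iff p < alpha and |CC| >= 0.1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StabilityConfig",
    "percent_difference",
    "iqr_with_ci",
    "spearman_vs_rotation",
    "effect_stratum",
    "compute_stability",
    "aggregate_subgroups",
]

_MACHINE_EPS = np.finfo(np.float64).eps
#: absolute floor for the %d denominator guard.  sqrt(machine eps) rather than
#: machine eps itself: feature values at ~1e-13 are float-cancellation noise,
#: and dividing one noise value by another manufactures huge spurious %d.
EPS_FLOOR = float(np.sqrt(_MACHINE_EPS))


@dataclass
class StabilityConfig:
    alpha: float = 0.05
    cc_cutpoints: tuple[float, float, float] = (0.1, 0.3, 0.7)
    use_magnitude: bool = True  # correlate |%d| (not signed %d) with rotation
    eps_scale: float = 1e-6     # denominator guard scale vs cohort median |f0|
    bh_correct: bool = False    # optional Benjamini-Hochberg across features


def percent_difference(f_rot, f_0, eps: float = EPS_FLOOR):
    """Signed %d = 100*(f_rot - f_0)/max(|f_0|, eps); exactly 0 on equality."""
    f_rot = np.asarray(f_rot, dtype=np.float64)
    f_0 = np.asarray(f_0, dtype=np.float64)
    denom = np.maximum(np.abs(f_0), eps)
    out = 100.0 * (f_rot - f_0) / denom
    return out if out.shape else float(out)


def effect_stratum(cc: float, cutpoints=(0.1, 0.3, 0.7)) -> str:
    a = abs(cc)
    if a < cutpoints[0]:
        return "trivial"
    if a < cutpoints[1]:
        return "weak"
    if a < cutpoints[2]:
        return "moderate"
    return "strong"


def iqr_with_ci(values_by_label: dict[int, np.ndarray]):
    """Per-label IQR (Q3-Q1, linear-interpolation quantiles), their mean, and
    the 95% Student-t CI of the mean over labels."""
    labels = sorted(values_by_label)
    if len(labels) < 2:
        raise ValueError("need >= 2 rotation labels")
    iqrs = {}
    for label in labels:
        v = np.asarray(values_by_label[label], dtype=np.float64)
        if v.size < 4:
            raise ValueError(f"label {label}: need >= 4 values, got {v.size}")
        q1, q3 = np.percentile(v, [25, 75])
        iqrs[label] = float(q3 - q1)
    arr = np.array([iqrs[label] for label in labels])
    mean = float(arr.mean())
    n = arr.size
    sd = float(arr.std(ddof=1))
    half = stats.t.ppf(0.975, n - 1) * sd / np.sqrt(n)
    return iqrs, mean, (mean - float(half), mean + float(half))


def spearman_vs_rotation(pd_by_label: dict[int, np.ndarray],
                         config: StabilityConfig | None = None):
    """Pooled Spearman of %d (magnitude by default) against label degrees."""
    config = config or StabilityConfig()
    labels = sorted(pd_by_label)
    if len(labels) < 3:
        raise ValueError("need >= 3 distinct rotation labels")
    x, y = [], []
    for label in labels:
        v = np.asarray(pd_by_label[label], dtype=np.float64)
        x.append(np.full(v.size, label, dtype=np.float64))
        y.append(np.abs(v) if config.use_magnitude else v)
    x = np.concatenate(x)
    y = np.concatenate(y)
    if x.size < 10:
        raise ValueError("need >= 10 pooled points")
    if np.allclose(y, y[0]):
        warnings.warn("constant %d values: Spearman undefined, returning CC=0, p=1",
                      stacklevel=2)
        return 0.0, 1.0, "trivial"
    cc, p = stats.spearmanr(x, y)
    cc = float(cc)
    return cc, float(p), effect_stratum(cc, config.cc_cutpoints)


def _vector_spearman(x_rank: np.ndarray, y: np.ndarray):
    """Row-wise tie-corrected Spearman CC and two-sided t-approx p-values.

    ``x_rank``: (n,) precomputed ranks of the shared x; ``y``: (F, n).
    Matches scipy.stats.spearmanr (which uses the same t approximation).
    """
    n = y.shape[1]
    ry = stats.rankdata(y, axis=1)
    rx = x_rank - x_rank.mean()
    ryc = ry - ry.mean(axis=1, keepdims=True)
    denom = np.sqrt((rx**2).sum() * (ryc**2).sum(axis=1))
    ok = denom > 0
    cc = np.zeros(y.shape[0])
    cc[ok] = (ryc[ok] @ rx) / denom[ok]
    cc = np.clip(cc, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = cc * np.sqrt((n - 2) / np.maximum(1.0 - cc**2, _MACHINE_EPS))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    p = np.where(ok, np.clip(p, 0.0, 1.0), 1.0)
    return cc, p


def compute_stability(df: pd.DataFrame, config: StabilityConfig | None = None):
    """Full feature-level analysis from a long feature table.

    ``df`` columns: patient_id, rotation_label, channel, category, feature,
    value; label 0 must be present and is the %d reference.

    Returns ``(records, per_label_iqr)``: one row per feature with the pooled
    statistics, and a long table of per-(feature, label) IQRs (the line-plot
    data).
    """
    config = config or StabilityConfig()
    labels = sorted(df["rotation_label"].unique())
    if 0 not in labels:
        raise ValueError("rotation label 0 (reference) missing")
    rot_labels = [label for label in labels if label != 0]
    if len(rot_labels) < 2:
        raise ValueError("need >= 2 nonzero rotation labels")
    wide = df.pivot_table(index=["channel", "category", "feature"],
                          columns=["rotation_label", "patient_id"],
                          values="value", sort=True)
    if wide.isna().any().any():
        raise ValueError("feature table has missing (feature, label, patient) cells")
    patients = sorted({p for (_, p) in wide.columns})
    n_pat = len(patients)
    f0 = wide[0].to_numpy()  # (F, n_pat)
    eps = np.maximum(config.eps_scale * np.median(np.abs(f0), axis=1), EPS_FLOOR)
    pdiff = np.empty((wide.shape[0], len(rot_labels), n_pat))
    for li, label in enumerate(rot_labels):
        pdiff[:, li, :] = 100.0 * (wide[label].to_numpy() - f0) \
            / np.maximum(np.abs(f0), eps[:, None])
    q1, q3 = np.percentile(pdiff, [25, 75], axis=2)
    iqr = q3 - q1  # (F, L)
    n_lab = iqr.shape[1]
    mean_iqr = iqr.mean(axis=1)
    sd_iqr = iqr.std(axis=1, ddof=1)
    half = stats.t.ppf(0.975, n_lab - 1) * sd_iqr / np.sqrt(n_lab)
    x = np.repeat(np.asarray(rot_labels, dtype=np.float64), n_pat)
    y = pdiff.reshape(pdiff.shape[0], -1)
    if config.use_magnitude:
        y = np.abs(y)
    cc, p = _vector_spearman(stats.rankdata(x), y)
    if config.bh_correct:
        order = np.argsort(p)
        m = p.size
        adj = np.minimum.accumulate((p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
        p = np.empty_like(adj)
        p[order] = np.clip(adj, 0.0, 1.0)
    strata = [effect_stratum(c, config.cc_cutpoints) for c in cc]
    sig = (p < config.alpha) & (np.abs(cc) >= config.cc_cutpoints[0])
    idx = wide.index.to_frame(index=False)
    records = idx.assign(
        mean_iqr=mean_iqr, iqr_ci_lo=mean_iqr - half, iqr_ci_hi=mean_iqr + half,
        spearman_cc=cc, spearman_p=p, stratum=strata, significant_nontrivial=sig,
    )
    per_label = pd.DataFrame(
        iqr, index=wide.index, columns=pd.Index(rot_labels, name="rotation_label")
    ).stack().rename("iqr").reset_index()
    return records, per_label


def aggregate_subgroups(records: pd.DataFrame):
    """Fig-3-style tables: (a) mean IQR per (category, channel) cell,
    (b) % of features flagged significant per cell, plus per-channel totals."""
    heat_iqr = records.pivot_table(index="category", columns="channel",
                                   values="mean_iqr", aggfunc="mean")
    heat_pct = records.pivot_table(index="category", columns="channel",
                                   values="significant_nontrivial",
                                   aggfunc=lambda s: 100.0 * s.mean())
    per_channel = records.groupby("channel").agg(
        n_features=("feature", "size"),
        n_significant=("significant_nontrivial", "sum"),
        mean_iqr=("mean_iqr", "mean"),
    )
    per_channel["pct_significant"] = (
        100.0 * per_channel["n_significant"] / per_channel["n_features"]
    )
    return heat_iqr, heat_pct, per_channel
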