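"""Per-channel texture features (93 each) plus mask-only shape features (14).

The 93 texture features per channel break down as 18 first-order + 24 GLCM +
16 GLRLM + 16 GLSZM + 14 GLDM + 5 NGTDM; with the default 18-channel filter
bank this yields 1674 texture entries per patient (744 on wavelet channels,
930 on the rest) plus 14 shape entries computed once.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..filterbank import FilterChannel
from ..phantoms import VolumePair
from ..preprocess import discretize
from .firstorder import FIRSTORDER_NAMES, firstorder_features
from .matrices import (
    DIRECTIONS_13,
    OFFSETS_26,
    glcm_matrix,
    gldm_matrix,
    glrlm_matrix,
    glszm_matrix,
    ngtdm_table,
)
from .shape import SHAPE_NAMES, shape_features
from .texture import (
    GLCM_NAMES,
    GLDM_NAMES,
    GLRLM_NAMES,
    GLSZM_NAMES,
    NGTDM_NAMES,
    glcm_features,
    gldm_features,
    glrlm_features,
    glszm_features,
    ngtdm_features,
)

__all__ = [
    "FeatureConfig",
    "FeatureVector",
    "extract_channel_features",
    "extract_all",
    "feature_frame",
    "TEXTURE_FEATURE_COUNT",
    "CATEGORY_NAMES",
    "firstorder_features", "shape_features", "glcm_features", "glrlm_features",
    "glszm_features", "gldm_features", "ngtdm_features",
    "glcm_matrix", "glrlm_matrix", "glszm_matrix", "gldm_matrix", "ngtdm_table",
    "DIRECTIONS_13", "OFFSETS_26",
    "FIRSTORDER_NAMES", "GLCM_NAMES", "GLRLM_NAMES", "GLSZM_NAMES",
    "GLDM_NAMES", "NGTDM_NAMES", "SHAPE_NAMES",
]

CATEGORY_NAMES = ("firstorder", "glcm", "glrlm", "glszm", "gldm", "ngtdm")
TEXTURE_FEATURE_COUNT = (
    len(FIRSTORDER_NAMES) + len(GLCM_NAMES) + len(GLRLM_NAMES)
    + len(GLSZM_NAMES) + len(GLDM_NAMES) + len(NGTDM_NAMES)
)  # 93


@dataclass
class FeatureConfig:
    bin_width: float = 0.1
    gldm_alpha: int = 0
    glcm_distance: int = 1


@dataclass
class FeatureVector:
    """patient x rotation-set feature map keyed (channel, category, name)."""

    patient_id: str
    rotation_label: int = 0
    class_label: int | None = None
    entries: dict[tuple[str, str, str], float] = field(default_factory=dict)

    def n_texture(self) -> int:
        return sum(1 for (_, cat, _) in self.entries if cat != "shape")

    def n_wd(self, wd_channels: set[str]) -> int:
        return sum(1 for (ch, cat, _) in self.entries
                   if cat != "shape" and ch in wd_channels)

    def to_rows(self) -> list[dict]:
        return [
            {
                "patient_id": self.patient_id,
                "rotation_label": self.rotation_label,
                "class_label": self.class_label,
                "channel": ch,
                "category": cat,
                "feature": name,
                "value": val,
            }
            for (ch, cat, name), val in self.entries.items()
        ]


def _mask_bbox(mask: np.ndarray, pad: int = 1) -> tuple[slice, slice, slice]:
    out = []
    for ax in range(3):
        proj = np.any(mask, axis=tuple(a for a in range(3) if a != ax))
        idx = np.flatnonzero(proj)
        out.append(slice(max(int(idx[0]) - pad, 0),
                         min(int(idx[-1]) + 1 + pad, mask.shape[ax])))
    return tuple(out)


def extract_channel_features(image: np.ndarray, mask: np.ndarray,
                             config: FeatureConfig,
                             voxel_volume: float = 1.0) -> dict[tuple[str, str], float]:
    """The 93 texture features of one channel; keys are (category, name)."""
    mask = np.asarray(mask) > 0
    if not np.any(mask):
        raise ValueError("empty mask")
    bbox = _mask_bbox(mask)
    img = np.asarray(image, dtype=np.float64)[bbox]
    msk = mask[bbox]
    levels = discretize(img, msk, config.bin_width)
    out: dict[tuple[str, str], float] = {}
    for name, val in firstorder_features(img, msk, config.bin_width, voxel_volume).items():
        out[("firstorder", name)] = val
    for name, val in glcm_features(levels, msk, config.glcm_distance).items():
        out[("glcm", name)] = val
    for name, val in glrlm_features(levels, msk).items():
        out[("glrlm", name)] = val
    for name, val in glszm_features(levels, msk).items():
        out[("glszm", name)] = val
    for name, val in gldm_features(levels, msk, config.gldm_alpha).items():
        out[("gldm", name)] = val
    for name, val in ngtdm_features(levels, msk).items():
        out[("ngtdm", name)] = val
    bad = [k for k, v in out.items() if not np.isfinite(v)]
    if bad:
        raise ValueError(f"non-finite features produced: {bad}")
    return out


def extract_all(pair: VolumePair, channels: list[FilterChannel],
                config: FeatureConfig | None = None,
                rotation_label: int = 0) -> FeatureVector:
    """93 texture features per channel + 14 shape features for one lesion."""
    config = config or FeatureConfig()
    voxel_volume = float(np.prod(pair.spacing))
    vec = FeatureVector(patient_id=pair.patient_id, rotation_label=rotation_label,
                        class_label=pair.class_label)
    for channel in channels:
        try:
            feats = extract_channel_features(channel.image, pair.mask, config, voxel_volume)
        except Exception as exc:
            raise RuntimeError(f"feature extraction failed on channel "
                               f"{channel.name!r}: {exc}") from exc
        for (cat, name), val in feats.items():
            vec.entries[(channel.name, cat, name)] = val
    for name, val in shape_features(pair.mask, pair.spacing).items():
        vec.entries[("shape", "shape", name)] = val
    return vec


def feature_frame(vectors: list[FeatureVector]) -> pd.DataFrame:
    """Long-format table: patient_id, rotation_label, class_label, channel,
    category, feature, value."""
    rows: list[dict] = []
    for vec in vectors:
        rows.extend(vec.to_rows())
    return pd.DataFrame(rows)
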