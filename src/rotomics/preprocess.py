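"""Intensity normalization, mask cleanup, cropping, resampling, discretization.

The order used by the pipeline is: validate pair -> z-score normalize (Otsu
foreground) -> remove tiny mask islands -> (rotate) -> isotropic resample to
the cohort's modal spacing -> crop to the mask bounding box (+margin); fixed
bin-width discretization happens per filter channel at feature time.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .phantoms import VolumePair

__all__ = [
    "PreprocessConfig",
    "PairMismatchError",
    "zscore_normalize",
    "clean_mask",
    "check_pair",
    "crop_to_bbox",
    "modal_spacing",
    "resample_isotropic",
    "discretize",
    "preprocess_pair",
]

#: 26-connectivity structuring element used for island removal and zone search
STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class PreprocessConfig:
    min_island_voxels: int = 10
    resample_spacing_policy: str = "dataset-mode"  # or "explicit"
    explicit_spacing: float | None = None
    bin_width: float = 0.1  # intensity units *after* z-scoring
    crop_margin: int = 10  # voxels
    otsu_nbins: int = 256
    normalize: bool = True

    def __post_init__(self) -> None:
        if self.min_island_voxels < 1:
            raise ValueError("min_island_voxels must be >= 1")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be > 0")


class PairMismatchError(ValueError):
    """Image/segmentation pair fails validation; carries the patient id."""

    def __init__(self, patient_id: str, reason: str):
        self.patient_id = patient_id
        super().__init__(f"patient {patient_id}: {reason}")


def zscore_normalize(image: np.ndarray, nbins: int = 256) -> np.ndarray:
    """Z-score the volume using Otsu-thresholded foreground statistics.

    The Otsu threshold is computed on an ``nbins``-bin histogram of the whole
    volume; mean/SD are taken over voxels strictly above the threshold and the
    affine map is applied to every voxel.  Affine-equivariant: a*x+b (a>0)
    normalizes to the same output as x.
    """
    image = np.asarray(image, dtype=np.float64)
    if np.unique(image).size < 2:
        raise ValueError("image must have at least 2 distinct values for Otsu thresholding")
    thresh = threshold_otsu(image, nbins=nbins)
    fg = image > thresh
    mu = image[fg].mean()
    sd = image[fg].std()
    if sd == 0:
        raise ValueError("constant foreground: z-score normalization undefined")
    return (image - mu) / sd


def clean_mask(mask: np.ndarray, min_island_voxels: int = 10) -> np.ndarray:
    """Drop connected components (26-connectivity) with fewer than
    ``min_island_voxels`` voxels; a component of exactly the threshold stays."""
    mask = np.asarray(mask) > 0
    labels, n = ndimage.label(mask, structure=STRUCT_26)
    if n == 0:
        raise ValueError("no lesion after cleaning: mask is empty")
    sizes = np.bincount(labels.ravel())
    keep = np.flatnonzero(sizes >= min_island_voxels)
    keep = keep[keep > 0]
    if keep.size == 0:
        raise ValueError("no lesion after cleaning: all components below threshold")
    out = np.isin(labels, keep)
    return out.astype(np.uint8)


def check_pair(pair: VolumePair) -> VolumePair:
    """Exclusion check: image/mask shape mismatch or empty mask raises."""
    if pair.image.shape != pair.mask.shape:
        raise PairMismatchError(
            pair.patient_id,
            f"image shape {pair.image.shape} != mask shape {pair.mask.shape}",
        )
    if not np.any(pair.mask):
        raise PairMismatchError(pair.patient_id, "mask has no foreground voxels")
    return pair


def crop_to_bbox(pair: VolumePair, margin: int = 10) -> VolumePair:
    """Crop image+mask to the mask bounding box grown by ``margin`` voxels per
    side (clipped at the volume borders).  Foreground count is preserved."""
    mask = pair.mask > 0
    if not np.any(mask):
        raise ValueError("cannot crop: empty mask")
    slices = []
    for ax in range(3):
        proj = np.any(mask, axis=tuple(a for a in range(3) if a != ax))
        idx = np.flatnonzero(proj)
        lo = max(int(idx[0]) - margin, 0)
        hi = min(int(idx[-1]) + 1 + margin, mask.shape[ax])
        slices.append(slice(lo, hi))
    slices = tuple(slices)
    out = pair.copy()
    out.image = pair.image[slices].copy()
    out.mask = pair.mask[slices].copy()
    out.meta["crop_slices"] = tuple((s.start, s.stop) for s in slices)
    return out


def modal_spacing(cohort: list[VolumePair], decimals: int = 6) -> float:
    """Most frequent spacing value over all axes of all patients; ties break
    toward the smallest value."""
    if not cohort:
        raise ValueError("empty cohort")
    counter: Counter = Counter()
    for pair in cohort:
        for s in pair.spacing:
            counter[round(float(s), decimals)] += 1
    best = max(counter.items(), key=lambda kv: (kv[1], -kv[0]))
    return float(best[0])


def resample_isotropic(pair: VolumePair, target: float) -> VolumePair:
    """Resample to isotropic ``target`` mm spacing (trilinear image, nearest
    mask).  Voxel centers are node-aligned: output index j maps to input index
    j*target/spacing, so the physical extent is preserved within one voxel."""
    if target <= 0:
        raise ValueError("target spacing must be > 0")
    spacing = np.asarray(pair.spacing, dtype=float)
    in_shape = np.asarray(pair.image.shape)
    out_shape = np.floor((in_shape - 1) * spacing / target).astype(int) + 1
    out_shape = np.maximum(out_shape, 1)
    grids = np.meshgrid(
        *[np.arange(n, dtype=float) * target / s for n, s in zip(out_shape, spacing)],
        indexing="ij",
    )
    coords = np.stack(grids)
    out = pair.copy()
    out.image = ndimage.map_coordinates(pair.image, coords, order=1, mode="nearest")
    out.mask = ndimage.map_coordinates(pair.mask.astype(np.uint8), coords, order=0,
                                       mode="constant", cval=0)
    out.spacing = (float(target),) * 3
    if not np.any(out.mask):
        raise ValueError(f"mask vanished when resampling to {target} mm")
    return out


def discretize(image: np.ndarray, mask: np.ndarray, bin_width: float) -> np.ndarray:
    """Fixed-bin-width gray-level discretization.

    ``level(x) = floor((x - edge0)/w) + 1`` with ``edge0 = floor(min_in_mask/w)*w``
    so levels are stable under mask-preserving crops.  Returns an int array of
    the same shape; voxels outside the mask are 0.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    mask = np.asarray(mask) > 0
    if not np.any(mask):
        raise ValueError("empty mask")
    vals = np.asarray(image, dtype=np.float64)
    in_mask = vals[mask]
    vmin, vmax = float(in_mask.min()), float(in_mask.max())
    levels = np.zeros(vals.shape, dtype=np.int64)
    # numerically-constant regions get a single level: float-cancellation
    # noise (~1e-15 relative) must not straddle a bin edge and split levels
    if vmax - vmin <= max(1e-12 * bin_width, 1e-9 * max(abs(vmin), abs(vmax)), 1e-9):
        levels[mask] = 1
        return levels
    edge0 = np.floor(vmin / bin_width) * bin_width
    levels[mask] = np.floor((in_mask - edge0) / bin_width).astype(np.int64) + 1
    levels[mask] = np.maximum(levels[mask], 1)
    return levels


def preprocess_pair(pair: VolumePair, config: PreprocessConfig,
                    target_spacing: float | None = None,
                    crop: bool = True) -> VolumePair:
    """Standard single-patient path: validate, normalize, clean islands,
    optionally resample isotropically and crop."""
    check_pair(pair)
    out = pair.copy()
    if config.normalize:
        out.image = zscore_normalize(out.image, nbins=config.otsu_nbins)
    out.mask = clean_mask(out.mask, config.min_island_voxels)
    if target_spacing is None and config.resample_spacing_policy == "explicit":
        target_spacing = config.explicit_spacing
    if target_spacing is not None and not np.allclose(out.spacing, target_spacing):
        out = resample_isotropic(out, target_spacing)
    elif target_spacing is not None:
        out.spacing = (float(target_spacing),) * 3
    if crop:
        out = crop_to_bbox(out, config.crop_margin)
    check_pair(out)
    return out
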