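"""Rotation perturbation: per-patient sampled rigid rotations R5..R80.

For each rotation-set label ``i`` in {5, 10, ..., 80} a deviation angle is
drawn per patient as |N(i deg, 10 deg)| (negative draws are folded to a
magnitude, which biases the sample mean upward for small labels — notably R5;
the bias is a documented consequence of treating the angle as a deviation
magnitude) about an axis drawn uniformly on the sphere.  Rotation is applied
about the mask's center of mass by resampling on the unchanged grid
(trilinear image / nearest-neighbour mask).  The R0 set goes through the
identical resampling code path with the identity transform, so its features
share the interpolation bias of the rotated sets.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial.transform import Rotation as _R

from .phantoms import VolumePair

__all__ = [
    "ROTATION_LABELS",
    "RotationSet",
    "sample_rotations",
    "rotate_pair",
    "identity_resample",
    "build_rotated_cohort",
    "rotation_manifest",
]

#: the 17 rotation-set labels, degrees
ROTATION_LABELS: tuple[int, ...] = tuple(range(0, 85, 5))
ANGLE_SD_DEG = 10.0


@dataclass
class RotationSet:
    label_degrees: int
    theta_deg: float
    axis: tuple[float, float, float]
    matrix: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if self.label_degrees == 0:
            self.theta_deg = 0.0
            self.matrix = np.eye(3)
            return
        if self.theta_deg < 0:
            raise ValueError("theta must be a nonnegative deviation magnitude")
        if self.matrix is None:
            axis = np.asarray(self.axis, dtype=np.float64)
            axis = axis / np.linalg.norm(axis)
            self.matrix = _R.from_rotvec(axis * np.deg2rad(self.theta_deg)).as_matrix()
        err = np.linalg.norm(self.matrix.T @ self.matrix - np.eye(3))
        if err > 1e-10 or not np.isclose(np.linalg.det(self.matrix), 1.0, atol=1e-10):
            raise ValueError("rotation matrix is not special-orthogonal")


def _patient_rng(patient_id: str, seed: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(patient_id.encode())])
    )


def sample_rotations(patient_id: str, seed: int,
                     labels: tuple[int, ...] = ROTATION_LABELS[1:]) -> list[RotationSet]:
    """One RotationSet per nonzero label, deterministic in (patient_id, seed)."""
    rng = _patient_rng(patient_id, seed)
    sets = []
    for label in labels:
        if label == 0:
            sets.append(RotationSet(0, 0.0, (0.0, 0.0, 1.0)))
            continue
        theta = abs(rng.normal(label, ANGLE_SD_DEG))
        axis = rng.standard_normal(3)
        axis /= np.linalg.norm(axis)
        sets.append(RotationSet(int(label), float(theta), tuple(axis)))
    return sets


def _resample_through(pair: VolumePair, matrix: np.ndarray) -> VolumePair:
    """Resample image+mask through the rigid transform centered at the mask
    center of mass; the single code path used for both R0 and rotated sets."""
    spacing = np.asarray(pair.spacing, dtype=np.float64)
    com_idx = np.asarray(ndimage.center_of_mass(pair.mask))
    com_mm = com_idx * spacing
    # output index -> input index: A @ idx + b  (inverse mapping uses R^T)
    if np.array_equal(matrix, np.eye(3)):
        # keep lattice coordinates exactly integral so the identity resample
        # reproduces input values bit-for-bit
        a = np.eye(3)
        b = np.zeros(3)
    else:
        s = np.diag(spacing)
        s_inv = np.diag(1.0 / spacing)
        a = s_inv @ matrix.T @ s
        com_idx_v = com_mm / spacing
        b = com_idx_v - a @ com_idx_v
    out = pair.copy()
    out.image = ndimage.affine_transform(pair.image, a, offset=b, order=1, mode="nearest")
    out.mask = ndimage.affine_transform(pair.mask.astype(np.uint8), a, offset=b,
                                        order=0, mode="constant", cval=0)
    return out


def rotate_pair(pair: VolumePair, rot: RotationSet) -> VolumePair:
    """Apply one sampled rotation (or the R0 identity resample)."""
    out = _resample_through(pair, rot.matrix)
    if not np.any(out.mask):
        raise ValueError(f"patient {pair.patient_id}: mask vanished under rotation")
    border = np.zeros(out.mask.shape, dtype=bool)
    for ax in range(3):
        sl = [slice(None)] * 3
        sl[ax] = 0
        border[tuple(sl)] = True
        sl[ax] = -1
        border[tuple(sl)] = True
    if np.any(out.mask.astype(bool) & border):
        raise ValueError(
            f"patient {pair.patient_id}: rotated mask clipped by the volume border "
            f"(label {rot.label_degrees}, theta {rot.theta_deg:.1f} deg)"
        )
    n_in, n_out = int((pair.mask > 0).sum()), int((out.mask > 0).sum())
    if n_in >= 100 and abs(n_out - n_in) > 0.05 * n_in:
        warnings.warn(
            f"patient {pair.patient_id}: mask volume changed by "
            f"{100 * (n_out - n_in) / n_in:.1f}% under rotation", stacklevel=2)
    out.meta["rotation_label"] = rot.label_degrees
    out.meta["theta_deg"] = rot.theta_deg
    out.meta["axis"] = tuple(np.asarray(rot.axis, dtype=float))
    return out


def identity_resample(pair: VolumePair) -> VolumePair:
    """R0: the same resampling path with the identity transform (exact on
    lattice points, so constant images come back bit-identical)."""
    out = _resample_through(pair, np.eye(3))
    out.meta["rotation_label"] = 0
    out.meta["theta_deg"] = 0.0
    return out


def build_rotated_cohort(cohort: list[VolumePair], seed: int,
                         labels: tuple[int, ...] = ROTATION_LABELS,
                         ) -> dict[int, list[VolumePair]]:
    """label -> list of per-patient volumes; R0 via identity resample.

    Per-patient failures (mask clipped by the border) are logged as warnings
    and the patient is dropped from that label's group only.
    """
    nonzero = tuple(l for l in labels if l != 0)
    groups: dict[int, list[VolumePair]] = {label: [] for label in labels}
    for pair in cohort:
        if 0 in labels:
            r0 = identity_resample(pair)
            groups[0].append(r0)
        for rot in sample_rotations(pair.patient_id, seed, labels=nonzero):
            try:
                groups[rot.label_degrees].append(rotate_pair(pair, rot))
            except ValueError as exc:
                warnings.warn(f"dropping patient from R{rot.label_degrees}: {exc}",
                              stacklevel=2)
    return groups


def rotation_manifest(cohort: list[VolumePair], seed: int,
                      labels: tuple[int, ...] = ROTATION_LABELS) -> pd.DataFrame:
    """Replay manifest: patient_id, rotation_label, theta_deg, axis, seed."""
    rows = []
    nonzero = tuple(l for l in labels if l != 0)
    for pair in cohort:
        if 0 in labels:
            rows.append({"patient_id": pair.patient_id, "rotation_label": 0,
                         "theta_deg": 0.0, "axis_x": 0.0, "axis_y": 0.0,
                         "axis_z": 1.0, "seed": seed})
        for rot in sample_rotations(pair.patient_id, seed, labels=nonzero):
            rows.append({"patient_id": pair.patient_id,
                         "rotation_label": rot.label_degrees,
                         "theta_deg": rot.theta_deg, "axis_x": rot.axis[0],
                         "axis_y": rot.axis[1], "axis_z": rot.axis[2], "seed": seed})
    return pd.DataFrame(rows)
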