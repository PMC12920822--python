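"""Synthetic CT-like lesion phantoms with paired masks and class labels.

All phantoms here are *synthetic* stand-ins: ellipsoidal lesions on a flat
background, optionally carrying an orientation-bearing texture (an oriented
sinusoidal grating or oriented filtered noise) so that downstream analyses
have both directional and non-directional signal to work with.  Nothing in
this module attempts realistic CT physics.

Volumes are written/read as NRRD (minimal built-in codec) or NIfTI-1
(via nibabel); a cohort is described by a plain CSV manifest.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "PhantomSpec",
    "VolumePair",
    "make_phantom",
    "make_cohort",
    "write_volume",
    "read_volume",
    "write_cohort",
    "read_cohort",
    "CLASS_DEFAULTS",
]

TextureKind = Literal[
    "isotropic-noise", "oriented-grating", "oriented-filtered-noise", "radial-blob"
]


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one synthetic lesion volume.

    Identical specs (including ``seed``) generate bit-identical volumes.
    """

    grid_shape: tuple[int, int, int] = (48, 48, 32)
    spacing: tuple[float, float, float] = (1.0, 1.0, 3.0)
    lesion_radii: tuple[float, float, float] = (10.0, 10.0, 10.0)  # mm semi-axes
    texture_kind: TextureKind = "oriented-grating"
    texture_orientation: tuple[float, float, float] = (1.0, 0.0, 0.0)
    texture_wavelength: float = 6.0  # mm
    texture_amplitude: float = 100.0
    noise_sd: float = 10.0
    background_level: float = -800.0
    lesion_level: float = 40.0
    class_label: int = 0
    seed: int = 0

    def validate(self) -> None:
        shape = np.asarray(self.grid_shape)
        spacing = np.asarray(self.spacing, dtype=float)
        radii = np.asarray(self.lesion_radii, dtype=float)
        if shape.shape != (3,) or np.any(shape < 8):
            raise ValueError(f"grid_shape must be 3 axes all >= 8, got {self.grid_shape}")
        if np.any(spacing <= 0):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if np.any(radii <= 0):
            raise ValueError(f"lesion_radii must be positive, got {self.lesion_radii}")
        # lesion must fit with a >=2-voxel margin per axis
        half_extent = (shape - 1) * spacing / 2.0
        for ax in range(3):
            if radii[ax] > half_extent[ax] - 2 * spacing[ax]:
                raise ValueError(
                    f"lesion semi-axis {radii[ax]} mm does not fit grid along axis {ax} "
                    f"(half extent {half_extent[ax]} mm, 2-voxel margin required)"
                )


@dataclass
class VolumePair:
    """One patient-lesion: 3D image + binary mask + voxel spacing (mm)."""

    image: np.ndarray
    mask: np.ndarray
    spacing: tuple[float, float, float]
    patient_id: str = "anon"
    class_label: int | None = None
    meta: dict = field(default_factory=dict)

    def copy(self) -> "VolumePair":
        return VolumePair(
            image=self.image.copy(),
            mask=self.mask.copy(),
            spacing=tuple(self.spacing),
            patient_id=self.patient_id,
            class_label=self.class_label,
            meta=dict(self.meta),
        )


def _mm_grid(shape: Sequence[int], spacing: Sequence[float]) -> list[np.ndarray]:
    """Open mm-coordinate grids centered on the volume center."""
    axes = [
        (np.arange(n, dtype=float) - (n - 1) / 2.0) * s for n, s in zip(shape, spacing)
    ]
    return np.meshgrid(*axes, indexing="ij", sparse=True)


def _texture_field(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    xx, yy, zz = _mm_grid(spec.grid_shape, spec.spacing)
    u = np.asarray(spec.texture_orientation, dtype=float)
    nrm = np.linalg.norm(u)
    if nrm == 0:
        raise ValueError("texture_orientation must be a nonzero vector")
    u = u / nrm
    if spec.texture_kind == "oriented-grating":
        phase = 2.0 * np.pi * (xx * u[0] + yy * u[1] + zz * u[2]) / spec.texture_wavelength
        return spec.texture_amplitude * np.sin(phase)
    if spec.texture_kind == "radial-blob":
        # rotationally symmetric smooth bump (negative-control phantom):
        # amplitude * exp(-r^2 / (2*wavelength^2)) about the volume center
        r2 = xx**2 + yy**2 + zz**2
        return spec.texture_amplitude * np.exp(-0.5 * r2 / spec.texture_wavelength**2)
    # filtered-noise textures: white noise smoothed by a (possibly anisotropic)
    # Gaussian, rescaled so the field SD equals texture_amplitude
    noise = rng.standard_normal(spec.grid_shape)
    spacing = np.asarray(spec.spacing, dtype=float)
    if spec.texture_kind == "isotropic-noise":
        sigma_vox = (spec.texture_wavelength / 4.0) / spacing
        field_ = ndimage.gaussian_filter(noise, sigma=sigma_vox, mode="wrap")
    elif spec.texture_kind == "oriented-filtered-noise":
        # smooth strongly along the orientation, weakly across it: approximate
        # by a separable blur with per-axis sigmas proportional to |u|
        sig_mm = spec.texture_wavelength * (0.25 + 1.5 * np.abs(u))
        field_ = ndimage.gaussian_filter(noise, sigma=sig_mm / spacing, mode="wrap")
    else:
        raise ValueError(f"unknown texture_kind {spec.texture_kind!r}")
    sd = field_.std()
    if sd > 0:
        field_ = field_ * (spec.texture_amplitude / sd)
    return field_


def make_phantom(spec: PhantomSpec) -> VolumePair:
    """Rasterize one phantom lesion.

    Lesion voxels get ``lesion_level + texture + N(0, noise_sd)``, background
    voxels ``background_level + N(0, noise_sd)``; the mask is the ellipsoid
    indicator evaluated at voxel centers (mm coordinates).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    xx, yy, zz = _mm_grid(spec.grid_shape, spec.spacing)
    r = np.asarray(spec.lesion_radii, dtype=float)
    mask = ((xx / r[0]) ** 2 + (yy / r[1]) ** 2 + (zz / r[2]) ** 2) <= 1.0
    image = np.full(spec.grid_shape, float(spec.background_level))
    image[mask] = float(spec.lesion_level)
    if spec.texture_amplitude != 0:
        texture = _texture_field(spec, rng)
        image[mask] += texture[mask]
    if spec.noise_sd > 0:
        # mildly correlated noise (like reconstructed CT, whose noise power
        # is not Nyquist-peaked): white noise would be half-destroyed by any
        # interpolating resample, biasing every intensity statistic at once
        noise = ndimage.gaussian_filter(rng.standard_normal(spec.grid_shape), 0.6)
        image = image + noise * (spec.noise_sd / noise.std())
    return VolumePair(
        image=image.astype(np.float64),
        mask=mask.astype(np.uint8),
        spacing=tuple(float(s) for s in spec.spacing),
        class_label=spec.class_label,
        meta={"spec_seed": spec.seed, "texture_kind": spec.texture_kind},
    )


# Per-class texture parameter defaults: class 0 = coarse oriented grating,
# class 1 = fine oriented grating, class 2 = isotropic filtered noise.
# Wavelengths/amplitudes differ between classes so classes are partially
# separable from texture features alone.  Wavelengths stay >= ~6 voxels so
# trilinear resampling under rotation attenuates the texture only mildly
# (near-Nyquist gratings would destabilize every feature family at once).
CLASS_DEFAULTS: dict[int, dict] = {
    0: {"texture_kind": "oriented-grating", "texture_wavelength": 9.0, "texture_amplitude": 100.0},
    1: {"texture_kind": "oriented-grating", "texture_wavelength": 6.0, "texture_amplitude": 100.0},
    2: {"texture_kind": "isotropic-noise", "texture_wavelength": 7.5, "texture_amplitude": 100.0},
}


def _uniform_sphere(rng: np.random.Generator) -> tuple[float, float, float]:
    v = rng.standard_normal(3)
    v /= np.linalg.norm(v)
    return tuple(float(x) for x in v)


def _inject_island(pair: VolumePair, rng: np.random.Generator, max_voxels: int = 9) -> None:
    """Add one small spurious connected component far from the lesion."""
    mask = pair.mask
    free = np.argwhere(mask == 0)
    # pick a corner-ish seed voxel with a 1-voxel margin from borders
    shape = np.asarray(mask.shape)
    candidates = free[np.all((free >= 1) & (free < shape - 1), axis=1)]
    seed_vox = candidates[rng.integers(len(candidates))]
    n_vox = int(rng.integers(2, max_voxels + 1))
    cur = [tuple(seed_vox)]
    placed = set(cur)
    while len(placed) < n_vox:
        base = cur[rng.integers(len(cur))]
        step = rng.integers(-1, 2, size=3)
        cand = tuple(np.clip(np.asarray(base) + step, 1, shape - 2))
        if mask[cand] == 0:
            placed.add(cand)
            cur.append(cand)
    for vox in placed:
        mask[vox] = 1
    pair.meta["injected_island_voxels"] = len(placed)


def make_cohort(
    n_patients: int,
    class_probs: Sequence[float] = (1 / 3, 1 / 3, 1 / 3),
    seed: int = 0,
    *,
    base_spec: PhantomSpec | None = None,
    island_fraction: float = 0.0,
    class_overrides: dict[int, dict] | None = None,
    orientation_spread_deg: float | None = None,
) -> list[VolumePair]:
    """Generate a labeled cohort of phantom lesions.

    Each lesion draws its texture orientation uniformly on the sphere
    (default) and its texture parameters from the per-class defaults
    (``CLASS_DEFAULTS``) with per-patient jitter.  ``island_fraction`` of the
    masks receive one spurious <10-voxel island to exercise island removal
    downstream.

    ``orientation_spread_deg``, when set, concentrates texture orientations
    around the +x axis with the given angular spread instead of drawing them
    uniformly — emulating scans of consistently positioned patients, where
    baseline (unrotated) texture orientation is shared across the cohort.
    """
    if n_patients < 15:
        raise ValueError(f"n_patients must be >= 15, got {n_patients}")
    probs = np.asarray(class_probs, dtype=float)
    if probs.shape != (3,) or abs(probs.sum() - 1.0) > 1e-9 or np.any(probs < 0):
        raise ValueError(f"class_probs must be 3 nonnegative values summing to 1, got {class_probs}")
    if np.any(probs == 0):
        warnings.warn("degenerate class_probs: at least one class has probability 0", stacklevel=2)
    base = base_spec or PhantomSpec()
    rng = np.random.default_rng(seed)
    labels = rng.choice(3, size=n_patients, p=probs)
    overrides = {k: dict(v) for k, v in CLASS_DEFAULTS.items()}
    if class_overrides:
        for k, v in class_overrides.items():
            overrides.setdefault(k, {}).update(v)
    cohort: list[VolumePair] = []
    base_radii = np.asarray(base.lesion_radii, dtype=float)
    for idx in range(n_patients):
        label = int(labels[idx])
        params = dict(overrides[label])
        # per-patient texture jitter: classes overlap rather than separate
        # perfectly, so classifiers face a realistic margin
        params["texture_amplitude"] = params["texture_amplitude"] * rng.uniform(0.7, 1.3)
        params["texture_wavelength"] = params["texture_wavelength"] * rng.uniform(0.8, 1.2)
        radii = tuple(base_radii * rng.uniform(0.85, 1.0, size=3))
        if orientation_spread_deg is None:
            orientation = _uniform_sphere(rng)
        else:
            v = np.array([1.0, 0.0, 0.0]) \
                + np.tan(np.deg2rad(orientation_spread_deg)) * rng.standard_normal(3)
            orientation = tuple(v / np.linalg.norm(v))
        spec = replace(
            base,
            lesion_radii=radii,
            texture_orientation=orientation,
            class_label=label,
            seed=int(rng.integers(2**31)),
            **params,
        )
        pair = make_phantom(spec)
        pair.patient_id = f"P{idx:04d}"
        pair.meta["texture_wavelength"] = spec.texture_wavelength
        pair.meta["texture_amplitude"] = spec.texture_amplitude
        pair.meta["texture_orientation"] = spec.texture_orientation
        if island_fraction > 0 and rng.random() < island_fraction:
            _inject_island(pair, rng)
        cohort.append(pair)
    return cohort


# ---------------------------------------------------------------------------
# Volume I/O: minimal NRRD codec + NIfTI via nibabel
# ---------------------------------------------------------------------------

_NRRD_TYPES = {
    "float64": "double", "float32": "float",
    "uint8": "uint8", "int16": "short", "int32": "int", "int64": "long long",
}
_NRRD_TYPES_INV = {
    "double": np.float64, "float": np.float32, "uint8": np.uint8,
    "short": np.int16, "int": np.int32, "long long": np.int64,
    "unsigned char": np.uint8,
}


def _write_nrrd(path: Path, array: np.ndarray, spacing: Sequence[float]) -> None:
    dtype_name = _NRRD_TYPES.get(array.dtype.name)
    if dtype_name is None:
        array = array.astype(np.float64)
        dtype_name = "double"
    header = [
        "NRRD0004",
        "# produced by rotomics",
        f"type: {dtype_name}",
        "dimension: 3",
        f"sizes: {array.shape[0]} {array.shape[1]} {array.shape[2]}",
        f"spacings: {spacing[0]:.9g} {spacing[1]:.9g} {spacing[2]:.9g}",
        "encoding: ascii",
    ]
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n\n")
        # C-order flatten; one value per line keeps the file diffable
        np.savetxt(fh, array.reshape(-1, 1), fmt="%.17g")


def _read_nrrd(path: Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    with open(path, "rb") as fh:
        magic = fh.readline().decode().strip()
        if not magic.startswith("NRRD"):
            raise ValueError(f"{path}: not an NRRD file")
        fields: dict[str, str] = {}
        while True:
            line = fh.readline().decode()
            if line.strip() == "":
                break
            if line.startswith("#"):
                continue
            key, _, value = line.partition(":")
            fields[key.strip().lower()] = value.strip()
        sizes = tuple(int(s) for s in fields["sizes"].split())
        dtype = _NRRD_TYPES_INV[fields["type"]]
        if "spacings" in fields:
            spacing = tuple(float(s) for s in fields["spacings"].split())
        elif "space directions" in fields:
            vecs = [v for v in fields["space directions"].split(") (")]
            spacing = tuple(
                float(np.linalg.norm([float(x) for x in v.strip("() ").split(",")]))
                for v in vecs
            )
        else:
            raise ValueError(f"{path}: NRRD header carries no voxel spacing metadata")
        encoding = fields.get("encoding", "raw")
        if encoding == "ascii":
            data = np.loadtxt(fh).astype(dtype)
        elif encoding == "raw":
            data = np.frombuffer(fh.read(), dtype=np.dtype(dtype).newbyteorder("<"))
        else:
            raise ValueError(f"{path}: unsupported NRRD encoding {encoding!r}")
    return data.reshape(sizes), spacing  # C-order


def write_volume(pair: VolumePair, image_path: str | Path, mask_path: str | Path,
                 format: str = "nrrd") -> None:
    """Write image and mask as two sibling files (``nrrd`` or ``nifti``)."""
    image_path, mask_path = Path(image_path), Path(mask_path)
    fmt = format.lower()
    if fmt == "nrrd":
        _write_nrrd(image_path, pair.image, pair.spacing)
        _write_nrrd(mask_path, pair.mask.astype(np.uint8), pair.spacing)
    elif fmt in ("nifti", "nii"):
        import nibabel as nib

        affine = np.diag(list(pair.spacing) + [1.0])
        for arr, path in ((pair.image, image_path), (pair.mask.astype(np.uint8), mask_path)):
            img = nib.Nifti1Image(arr, affine)
            img.header.set_zooms(pair.spacing)
            nib.save(img, str(path))
    else:
        raise ValueError(f"unknown volume format {format!r} (use 'nrrd' or 'nifti')")


def _read_one(path: Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    name = path.name.lower()
    if name.endswith(".nrrd"):
        return _read_nrrd(path)
    if name.endswith(".nii") or name.endswith(".nii.gz"):
        import nibabel as nib

        img = nib.load(str(path))
        hdr = img.header
        if int(hdr["sform_code"]) == 0 and int(hdr["qform_code"]) == 0:
            raise ValueError(f"{path}: NIfTI header carries no spacing metadata "
                             "(sform and qform both unset)")
        return np.asarray(img.dataobj), tuple(float(z) for z in hdr.get_zooms()[:3])
    raise ValueError(f"unknown volume format for {path}")


def read_volume(image_path: str | Path, mask_path: str | Path,
                patient_id: str = "anon", class_label: int | None = None) -> VolumePair:
    image, sp_i = _read_one(Path(image_path))
    mask, sp_m = _read_one(Path(mask_path))
    if not np.allclose(sp_i, sp_m, atol=1e-6):
        raise ValueError(f"image/mask spacing disagree: {sp_i} vs {sp_m}")
    return VolumePair(image=np.asarray(image, dtype=np.float64),
                      mask=(np.asarray(mask) > 0).astype(np.uint8),
                      spacing=sp_i, patient_id=patient_id, class_label=class_label)


def write_cohort(cohort: list[VolumePair], outdir: str | Path, format: str = "nrrd") -> Path:
    """Write a cohort plus its CSV manifest; returns the manifest path."""
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ext = "nrrd" if format.lower() == "nrrd" else "nii"
    rows = []
    for pair in cohort:
        img = outdir / f"{pair.patient_id}_image.{ext}"
        msk = outdir / f"{pair.patient_id}_mask.{ext}"
        write_volume(pair, img, msk, format=format)
        rows.append({"patient_id": pair.patient_id, "image_path": img.name,
                     "mask_path": msk.name, "class_label": pair.class_label})
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_cohort(manifest_path: str | Path) -> list[VolumePair]:
    import pandas as pd

    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    root = manifest_path.parent
    cohort = []
    for row in df.itertuples(index=False):
        label = None if pd.isna(row.class_label) else int(row.class_label)
        cohort.append(read_volume(root / row.image_path, root / row.mask_path,
                                  patient_id=str(row.patient_id), class_label=label))
    return cohort


def stable_patient_seed(global_seed: int, patient_id: str) -> np.random.SeedSequence:
    """Per-patient seed derived from (global seed, patient_id) so cohorts can
    grow without reshuffling existing patients."""
    return np.random.SeedSequence([int(global_seed), zlib.crc32(patient_id.encode())])
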