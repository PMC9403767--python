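"""Synthetic contrast-enhanced CT liver phantoms.

The phantom emulates the structure of portal-venous CECT data used for liver
lesion segmentation: an ellipsoidal "liver" of roughly uniform parenchymal
enhancement inside an air-valued background, containing hypo-dense ellipsoidal
lesions (colorectal metastases and ablation zones are both hypo-enhancing),
optionally with a thin hyper-enhancing rim.  Gaussian noise stands in for CT
quantum noise.  Masks are exact (noise-free) and everything is deterministic
given ``PhantomSpec.rng_seed``.

Default tissue values are plausible portal-venous numbers chosen for
testability: parenchyma 100 HU, lesion core 60 HU (-40 offset), rim +30 HU,
noise 15 HU.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from .volumes import BinaryMask, CTVolume

BACKGROUND_HU = -1000.0


@dataclasses.dataclass(frozen=True)
class Lesion:
    center_mm: tuple[float, float, float]   # physical (z, y, x), relative to origin 0
    diameter_mm: float                      # sphere-equivalent diameter
    hu_offset: float = -40.0                # added to parenchyma inside the core (< 0)
    rim_width_mm: float = 0.0               # 0 disables the enhancing rim
    rim_hu_offset: float = 30.0

    def __post_init__(self):
        if self.hu_offset >= 0:
            raise ValueError("lesion core hu_offset must be negative (hypo-enhancing)")
        if self.diameter_mm <= 0:
            raise ValueError("lesion diameter must be > 0")


@dataclasses.dataclass
class PhantomSpec:
    volume_shape: tuple[int, int, int] = (40, 128, 128)
    spacing: tuple[float, float, float] = (2.5, 0.75, 0.75)
    liver_center_mm: tuple[float, float, float] | None = None   # default: volume centre
    liver_semiaxes_mm: tuple[float, float, float] = (40.0, 40.0, 40.0)
    parenchyma_hu: float = 100.0
    lesions: tuple[Lesion, ...] = ()
    noise_sd: float = 15.0
    rng_seed: int = 0

    def physical_size_mm(self) -> np.ndarray:
        return np.array(self.volume_shape) * np.array(self.spacing)


def _voxel_centers_mm(shape, spacing):
    axes = [(np.arange(n) + 0.5) * s for n, s in zip(shape, spacing)]
    return np.meshgrid(*axes, indexing="ij")


def _ellipsoid_mask(grids, center, semiaxes) -> np.ndarray:
    q = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semiaxes))
    return q <= 1.0


def generate_phantom(spec: PhantomSpec) -> tuple[CTVolume, BinaryMask, BinaryMask]:
    """Rasterize a phantom: returns (image, liver mask, disease mask).

    A voxel belongs to a shape when its centre lies inside it.  Lesions must
    lie entirely inside the liver and be pairwise disjoint (rims included).
    """
    shape, spacing = spec.volume_shape, spec.spacing
    grids = _voxel_centers_mm(shape, spacing)
    center = (spec.liver_center_mm if spec.liver_center_mm is not None
              else tuple(spec.physical_size_mm() / 2.0))
    liver = _ellipsoid_mask(grids, center, spec.liver_semiaxes_mm)
    if not liver.any():
        raise ValueError("liver ellipsoid does not intersect the volume")

    image = np.full(shape, BACKGROUND_HU, dtype=np.float32)
    image[liver] = spec.parenchyma_hu
    disease = np.zeros(shape, dtype=bool)

    for i, les in enumerate(spec.lesions):
        r = les.diameter_mm / 2.0
        core = _ellipsoid_mask(grids, les.center_mm, (r, r, r))
        outer_r = r + les.rim_width_mm
        outer = _ellipsoid_mask(grids, les.center_mm, (outer_r,) * 3)
        if not core.any():
            raise ValueError(f"lesion {i} rasterizes to zero voxels at this spacing")
        if np.any(outer & ~liver):
            raise ValueError(f"lesion {i} is not entirely inside the liver")
        if np.any(outer & disease):
            raise ValueError(f"lesion {i} overlaps a previous lesion")
        rim = outer & ~core
        image[core] = spec.parenchyma_hu + les.hu_offset
        if rim.any():
            image[rim] = spec.parenchyma_hu + les.rim_hu_offset
        disease |= core

    rng = np.random.default_rng(spec.rng_seed)
    if spec.noise_sd > 0:
        image = image + rng.normal(0.0, spec.noise_sd, size=shape).astype(np.float32)

    pid = f"phantom-{spec.rng_seed}"
    vol = CTVolume(image.astype(np.float32), spacing, patient_id=pid)
    liver_m = BinaryMask(liver.astype(np.uint8), spacing, patient_id=pid, kind="liver")
    disease_m = BinaryMask(disease.astype(np.uint8), spacing, patient_id=pid, kind="disease")
    return vol, liver_m, disease_m


def random_phantom_spec(rng_seed: int, n_lesions: int = 3,
                        diameter_range_mm: tuple[float, float] = (12.0, 28.0),
                        shape: tuple[int, int, int] = (40, 128, 128),
                        spacing: tuple[float, float, float] = (2.5, 0.75, 0.75),
                        rim: bool = True, max_tries: int = 200) -> PhantomSpec:
    """Draw a phantom spec with ``n_lesions`` random non-overlapping lesions.

    The liver ellipsoid is shrunk to fit the volume; lesion centres are
    sampled inside the inner parallel ellipsoid (semi-axes reduced by the
    lesion's reach), which guarantees the whole lesion, rim included, stays
    intra-hepatic.
    """
    rng = np.random.default_rng(rng_seed)
    base = PhantomSpec(volume_shape=shape, spacing=spacing, rng_seed=rng_seed)
    half = base.physical_size_mm() / 2.0
    semi = np.minimum(np.array(base.liver_semiaxes_mm), 0.95 * half)
    base = dataclasses.replace(base, liver_semiaxes_mm=tuple(semi))
    center = np.array(half)
    lesions: list[Lesion] = []
    tries = 0
    while len(lesions) < n_lesions and tries < max_tries:
        tries += 1
        d = float(rng.uniform(*diameter_range_mm))
        rim_w = 2.0 if rim else 0.0
        reach = d / 2.0 + rim_w + 1.0   # 1 mm rasterization safety margin
        inner = semi - reach
        if np.any(inner <= 1.0):
            continue
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        rad = rng.uniform(0, 1) ** (1 / 3)
        pos = center + u * rad * inner
        cand = Lesion(tuple(pos), d, rim_width_mm=rim_w)
        if all(np.linalg.norm(np.array(cand.center_mm) - np.array(l.center_mm))
               > (cand.diameter_mm + l.diameter_mm) / 2 + 2 * rim_w + 2.0 for l in lesions):
            lesions.append(cand)
    if len(lesions) < n_lesions:
        raise RuntimeError(f"could not place {n_lesions} disjoint lesions "
                           f"(diameters {diameter_range_mm} in a "
                           f"{tuple(np.round(semi, 1))} mm liver)")
    return dataclasses.replace(base, lesions=tuple(lesions))


def synth_probability_map(disease: BinaryMask, blur_sigma_mm: float = 2.0,
                          noise_sd: float = 0.05, rng_seed: int = 0):
    """A stand-in model output: smoothed disease indicator plus clipped noise.

    Emulates the output of a trained network — a confident interior with a
    narrow uncertain band at the lesion border — so the seeded-growth
    post-processing and the evaluation metrics can be exercised without
    training a model.  The indicator is Gaussian-smoothed at ``blur_sigma_mm``
    and then gamma-sharpened (exponent 1.5): this mimics the sharp
    interior/exterior contrast of a softmax output and keeps the
    mid-probability iso-surfaces close to the true boundary (a plain blur
    pushes them uniformly outside it; a stronger gamma over-contracts small,
    strongly curved lesions).
    """
    from .postprocess import ProbabilityMap  # local import to avoid a cycle

    if blur_sigma_mm < 0 or noise_sd < 0:
        raise ValueError("blur_sigma_mm and noise_sd must be >= 0")
    ind = disease.voxels.astype(np.float32)
    if blur_sigma_mm > 0:
        sigma_vox = [blur_sigma_mm / s for s in disease.spacing]
        prob = ndimage.gaussian_filter(ind, sigma=sigma_vox) ** 1.5
    else:
        prob = ind
    if noise_sd > 0:
        rng = np.random.default_rng(rng_seed)
        prob = prob + rng.normal(0.0, noise_sd, size=prob.shape).astype(np.float32)
    prob = np.clip(prob, 0.0, 1.0)
    return ProbabilityMap(prob.astype(np.float32), disease.spacing, disease.origin,
                          disease.patient_id)
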