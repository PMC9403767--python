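"""Class-balanced training-slab extraction and flip/mirror augmentation.

Whole-liver training under-represents small lesions badly: most of the liver is
normal tissue, so a network can score well by predicting "normal" everywhere.
Instead, one fixed-size slab (default 32 x 120 x 120 voxels) is extracted per
connected disease site, centred on the site's centroid, so every training
sample contains both disease and normal liver.  All disease voxels falling
inside a window are labelled, not only the seeding site.
"""

from __future__ import annotations

import dataclasses
import logging
import math

import numpy as np
from scipy import ndimage

from .volumes import BinaryMask, CTVolume

log = logging.getLogger(__name__)

DEFAULT_SLAB_SHAPE = (32, 120, 120)


@dataclasses.dataclass
class ComponentSet:
    """Connected components of a binary mask with physical measurements."""

    labels: np.ndarray            # int array, 0 = background, 1..count = components
    count: int
    centroids_mm: np.ndarray      # (count, 3) physical coordinates
    volumes_cc: np.ndarray        # (count,) physical volumes
    spacing: tuple[float, float, float]

    def component_mask(self, component_id: int) -> np.ndarray:
        return self.labels == component_id


@dataclasses.dataclass
class Slab:
    """A fixed-size training sample: normalized image, liver mask and disease label."""

    image: np.ndarray
    liver: np.ndarray
    label: np.ndarray
    source_patient: str = ""
    site_index: int = 0
    origin_voxel: tuple[int, int, int] = (0, 0, 0)  # window start in the source volume

    def __post_init__(self):
        if not (self.image.shape == self.liver.shape == self.label.shape):
            raise ValueError("slab arrays must share one shape")
        if np.any(self.label.astype(bool) & ~self.liver.astype(bool)):
            raise ValueError("slab label must be a subset of the liver mask")


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 26:
        return ndimage.generate_binary_structure(3, 3)
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    raise ValueError(f"connectivity must be 6 or 26, got {connectivity}")


def label_components(mask: BinaryMask, connectivity: int = 26) -> ComponentSet:
    """Label connected components; centroids/volumes in physical units.

    Each disconnected disease site is treated as an independent case, so the
    default 26-connectivity merges diagonal touches into one site.
    """
    labels, count = ndimage.label(mask.voxels, structure=_structure(connectivity))
    spacing = np.array(mask.spacing)
    if count:
        idx = np.arange(1, count + 1)
        cent_vox = np.array(ndimage.center_of_mass(np.ones_like(labels), labels, idx))
        centroids = (cent_vox + 0.5) * spacing + np.array(mask.origin)
        counts = np.bincount(labels.ravel(), minlength=count + 1)[1:]
        volumes = counts * mask.voxel_volume_mm3 / 1000.0
    else:
        centroids = np.zeros((0, 3))
        volumes = np.zeros(0)
    return ComponentSet(labels=labels, count=int(count), centroids_mm=centroids,
                        volumes_cc=volumes, spacing=mask.spacing)


def _window_starts(center: int, extent_lo: int, extent_hi: int, win: int, n: int) -> list[int]:
    """Start indices of `n` windows of size `win` covering [extent_lo, extent_hi].

    Consecutive starts are <= win apart, so the union of windows covers the
    whole extent with minimal overlap.
    """
    if n == 1:
        return [center - win // 2]
    span = extent_hi - extent_lo + 1
    return [int(round(s)) for s in np.linspace(extent_lo, extent_lo + span - win, n)]


def extract_slabs(image: CTVolume, liver: BinaryMask, disease: BinaryMask,
                  slab_shape: tuple[int, int, int] = DEFAULT_SLAB_SHAPE,
                  connectivity: int = 26) -> list[Slab]:
    """One slab per connected disease site (tiled when a site exceeds the window).

    Windows are centred on the site centroid (voxel coordinates, rounded) and
    shifted inward at volume boundaries; zero padding is used only when the
    whole volume is smaller than the window along an axis.  The slab label
    contains every disease voxel inside the window regardless of which site
    seeded it.
    """
    if not (image.same_grid(liver) and image.same_grid(disease)):
        raise ValueError("image, liver and disease must share one grid")
    comps = label_components(disease, connectivity=connectivity)
    if comps.count == 0:
        log.warning("disease mask for %s is empty; no slabs extracted", image.patient_id)
        return []

    vol_shape = np.array(image.shape)
    win = np.array(slab_shape)
    slabs: list[Slab] = []
    objects = ndimage.find_objects(comps.labels)
    for cid in range(1, comps.count + 1):
        sl = objects[cid - 1]
        lo = np.array([s.start for s in sl])
        hi = np.array([s.stop - 1 for s in sl])
        extent = hi - lo + 1
        n_tiles = np.maximum(1, np.ceil(extent / win)).astype(int)
        comp_vox = np.argwhere(comps.labels == cid)
        centroid = np.round(comp_vox.mean(axis=0)).astype(int)
        starts_per_axis = [
            _window_starts(centroid[a], lo[a], hi[a], win[a], n_tiles[a])
            for a in range(3)
        ]
        for s0 in starts_per_axis[0]:
            for s1 in starts_per_axis[1]:
                for s2 in starts_per_axis[2]:
                    start = np.array([s0, s1, s2])
                    # keep the seeding site inside a single window where it fits
                    single = n_tiles == 1
                    start[single] = np.clip(start[single], (hi + 1 - win)[single], lo[single])
                    # clamp inward so the window stays inside the volume
                    start = np.clip(start, 0, np.maximum(0, vol_shape - win))
                    slabs.append(_cut_window(image, liver, disease, start, win, cid))
    return slabs


def _cut_window(image: CTVolume, liver: BinaryMask, disease: BinaryMask,
                start: np.ndarray, win: np.ndarray, site_index: int) -> Slab:
    vol_shape = np.array(image.shape)
    stop = np.minimum(start + win, vol_shape)
    sl = tuple(slice(int(a), int(b)) for a, b in zip(start, stop))

    def pad(arr, fill=0.0):
        out = np.full(tuple(win), fill, dtype=arr.dtype)
        region = tuple(slice(0, int(b - a)) for a, b in zip(start, stop))
        out[region] = arr[sl]
        return out

    return Slab(
        image=pad(image.voxels.astype(np.float32)),
        liver=pad(liver.voxels),
        label=pad(disease.voxels),
        source_patient=image.patient_id,
        site_index=site_index,
        origin_voxel=tuple(int(a) for a in start),
    )


AXIS_NAMES = {"slice": 0, "row": 1, "column": 2}


def flip_mirror_augment(slab: Slab, axes: set[str] | tuple[str, ...]) -> Slab:
    """Reflect a slab along the named axes; image, liver and label flip together."""
    idx = []
    for name in axes:
        if name not in AXIS_NAMES:
            raise ValueError(f"unknown axis {name!r}; choose from {sorted(AXIS_NAMES)}")
        idx.append(AXIS_NAMES[name])
    if not idx:
        return dataclasses.replace(slab)
    return dataclasses.replace(
        slab,
        image=np.flip(slab.image, axis=idx).copy(),
        liver=np.flip(slab.liver, axis=idx).copy(),
        label=np.flip(slab.label, axis=idx).copy(),
    )


def random_flip(slab: Slab, rng: np.random.Generator, p: float = 0.5) -> Slab:
    """On-the-fly augmentation: each axis is flipped independently with probability p."""
    axes = {name for name in AXIS_NAMES if rng.random() < p}
    return flip_mirror_augment(slab, axes)


def save_slabs(slabs: list[Slab], path) -> None:
    """Write slabs to a compressed .npz archive with a JSON-compatible manifest."""
    arrays = {}
    manifest = []
    for i, s in enumerate(slabs):
        arrays[f"image_{i}"] = s.image.astype(np.float32)
        arrays[f"liver_{i}"] = s.liver.astype(np.uint8)
        arrays[f"label_{i}"] = s.label.astype(np.uint8)
        manifest.append({"source_patient": s.source_patient, "site_index": s.site_index,
                         "origin_voxel": list(s.origin_voxel)})
    import json
    np.savez_compressed(path, manifest=json.dumps(manifest), **arrays)


def load_slabs(path) -> list[Slab]:
    import json
    with np.load(path, allow_pickle=False) as data:
        manifest = json.loads(str(data["manifest"]))
        return [
            Slab(image=data[f"image_{i}"], liver=data[f"liver_{i}"], label=data[f"label_{i}"],
                 source_patient=m["source_patient"], site_index=m["site_index"],
                 origin_voxel=tuple(m["origin_voxel"]))
            for i, m in enumerate(manifest)
        ]
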