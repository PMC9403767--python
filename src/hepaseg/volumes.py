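"""Volume data model, NIfTI I/O, resampling and patient-specific intensity normalization.

Arrays are stored in ``(slice, row, column)`` = ``(z, y, x)`` order; ``spacing``
and ``origin`` follow the same axis order, in millimetres.  The slice axis
carries the CT slice thickness, the row/column axes the in-plane pixel size.

Intensity normalization is patient specific: the mode of the in-liver
Hounsfield-unit histogram is taken as the parenchyma centre and the full width
at half maximum (FWHM) of that peak supplies the scale, ``sigma = FWHM /
(2*sqrt(2*ln 2))``.  This is robust against the long HU tails created by
vessels, lesions and calcifications that would dominate a plain mean/std.
Voxels outside the liver mask are set to exactly 0, so the network never sees
extra-hepatic anatomy.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from pathlib import Path
from typing import Literal

import nibabel as nib
import numpy as np
from scipy import ndimage

from .errors import AlignmentError, DegenerateHistogramError, FormatError

log = logging.getLogger(__name__)

FWHM_TO_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))

MaskKind = Literal["liver", "disease", "ablation", "prediction"]


@dataclasses.dataclass
class CTVolume:
    """A 3D CT image in Hounsfield units with physical grid metadata."""

    voxels: np.ndarray          # (slice, row, column), float
    spacing: tuple[float, float, float]  # mm per voxel, same axis order
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    patient_id: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise FormatError(f"expected a 3D volume, got shape {self.voxels.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing components must be > 0, got {self.spacing}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("volume contains non-finite voxel values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def grid(self) -> tuple:
        return (self.shape, self.spacing, self.origin)

    def same_grid(self, other: "CTVolume | BinaryMask") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=1e-6)
            and np.allclose(self.origin, other.origin, atol=1e-3)
        )


@dataclasses.dataclass
class BinaryMask:
    """A {0,1} label volume (liver, disease, ablation zone or prediction)."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    patient_id: str = ""
    kind: MaskKind = "liver"

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels)
        if vox.ndim != 3:
            raise FormatError(f"expected a 3D mask, got shape {vox.shape}")
        uniq = np.unique(vox)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError(f"mask values must be exactly 0/1, found {uniq[:5]}")
        self.voxels = vox.astype(np.uint8)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing components must be > 0, got {self.spacing}")

    shape = CTVolume.shape
    voxel_volume_mm3 = CTVolume.voxel_volume_mm3
    grid = CTVolume.grid
    same_grid = CTVolume.same_grid

    def count(self) -> int:
        return int(self.voxels.sum())

    def volume_cc(self) -> float:
        return self.count() * self.voxel_volume_mm3 / 1000.0


@dataclasses.dataclass(frozen=True)
class NormalizationStats:
    """Histogram-peak centre and FWHM-derived scale of the in-liver HU values."""

    center: float
    sigma: float
    fwhm: float

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "NormalizationStats":
        return cls(**json.loads(Path(path).read_text()))


# --------------------------------------------------------------------------- I/O

def _to_zyx(img: nib.Nifti1Image) -> tuple[np.ndarray, tuple, tuple]:
    img = nib.as_closest_canonical(img)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"expected a 3D NIfTI image, got {data.ndim}D")
    zooms = img.header.get_zooms()[:3]
    origin = img.affine[:3, 3]
    # canonical nibabel order is (x, y, z); transpose to (z, y, x)
    return data.T, tuple(float(z) for z in zooms[::-1]), tuple(float(o) for o in origin[::-1])


def read_volume(path: str | Path, patient_id: str | None = None) -> CTVolume:
    """Read a NIfTI-1/2 file into a :class:`CTVolume` ordered (slice, row, column)."""
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # unreadable / not NIfTI
        raise FormatError(f"cannot read NIfTI file {path}: {exc}") from exc
    data, spacing, origin = _to_zyx(img)
    return CTVolume(
        voxels=np.ascontiguousarray(data, dtype=np.float32),
        spacing=spacing,
        origin=origin,
        patient_id=patient_id or path.name.split(".")[0],
    )


def read_mask(path: str | Path, kind: MaskKind, patient_id: str | None = None,
              liver: BinaryMask | None = None) -> BinaryMask:
    """Read a binary mask; disease/ablation masks are clipped to ``liver`` when given.

    Out-of-liver label voxels are untrainable (the model input is zero there),
    so they are intersected away with a warning rather than kept.
    """
    vol = read_volume(path, patient_id)
    vox = (vol.voxels > 0.5).astype(np.uint8)
    if liver is not None and kind in ("disease", "ablation"):
        outside = int((vox & (1 - liver.voxels)).sum())
        if outside:
            log.warning("%s: %d %s voxels outside the liver mask were clipped",
                        path, outside, kind)
            vox &= liver.voxels
    return BinaryMask(vox, vol.spacing, vol.origin, vol.patient_id, kind)


def write_volume(volume, path: str | Path) -> None:
    """Write a CTVolume / BinaryMask / probability map to NIfTI.

    Integer masks round-trip bit-for-bit; float volumes to float32 precision.
    """
    path = Path(path)
    if not path.parent.exists():
        raise IOError(f"parent directory does not exist: {path.parent}")
    vox = np.asarray(volume.voxels)
    dtype = np.uint8 if vox.dtype.kind in "uib" else np.float32
    data = vox.T.astype(dtype)  # back to (x, y, z)
    affine = np.diag(list(volume.spacing[::-1]) + [1.0])
    affine[:3, 3] = volume.origin[::-1]
    nib.save(nib.Nifti1Image(data, affine), str(path))


# --------------------------------------------------------------------- resampling

def resample_to_spacing(volume, target_spacing, mode: Literal["linear", "nearest"] = "linear"):
    """Resample onto a new voxel spacing.

    Output size per axis is ``round(n * s_in / s_target)`` (min 1).  Images use
    linear interpolation; binary masks are interpolated linearly and
    re-binarized at 0.5, so mask boundaries move with the image content
    instead of staying on a voxel lattice.
    """
    target_spacing = tuple(float(s) for s in target_spacing)
    if any(s <= 0 for s in target_spacing):
        raise ValueError(f"target spacing must be > 0, got {target_spacing}")
    is_mask = isinstance(volume, BinaryMask)
    vox = volume.voxels.astype(np.float32)
    in_shape = np.array(vox.shape)
    out_shape = np.maximum(1, np.round(in_shape * np.array(volume.spacing) / np.array(target_spacing))).astype(int)
    if tuple(out_shape) == tuple(in_shape) and np.allclose(volume.spacing, target_spacing):
        out = vox.copy()
    else:
        zoom = out_shape / in_shape
        order = 0 if mode == "nearest" else 1
        out = ndimage.zoom(vox, zoom, order=order, mode="nearest", grid_mode=True)
        out = out[: out_shape[0], : out_shape[1], : out_shape[2]]
    if is_mask:
        thresholded = (out >= 0.5).astype(np.uint8) if mode == "linear" else out.astype(np.uint8)
        return BinaryMask(thresholded, target_spacing, volume.origin, volume.patient_id, volume.kind)
    return CTVolume(out, target_spacing, volume.origin, volume.patient_id)


# ------------------------------------------------------------------ normalization

def fwhm_stats(volume: CTVolume, liver: BinaryMask, bin_width: float = 1.0) -> NormalizationStats:
    """Estimate (centre, sigma) of the in-liver HU distribution from its histogram peak.

    The histogram of in-liver values is built at ``bin_width`` HU; the FWHM is
    the distance between the linearly interpolated half-maximum crossings
    nearest the highest bin (ties resolved toward the lowest HU), and the
    centre is the midpoint of those crossings.  The crossings sit on the steep
    flanks of the peak, so their midpoint localizes the parenchyma centre far
    more stably than the (noisy) mode bin itself.
    ``sigma = FWHM / (2*sqrt(2*ln 2))`` assumes a locally Gaussian peak, which
    holds well for liver parenchyma.
    """
    if not volume.same_grid(liver):
        raise AlignmentError("volume and liver mask are on different grids")
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    values = volume.voxels[liver.voxels > 0]
    if values.size == 0:
        raise ValueError("liver mask is empty")
    lo, hi = float(values.min()), float(values.max())
    n_bins = max(1, int(math.ceil((hi - lo) / bin_width)))
    counts, edges = np.histogram(values, bins=n_bins, range=(lo, lo + n_bins * bin_width))
    centers = 0.5 * (edges[:-1] + edges[1:])
    peak = int(np.argmax(counts))  # first (lowest-HU) maximal bin
    half = counts[peak] / 2.0

    def _crossing(direction: int) -> float | None:
        i = peak
        while 0 <= i + direction < len(counts):
            j = i + direction
            if counts[j] < half:
                # linear interpolation between bin centres i and j
                frac = (counts[i] - half) / (counts[i] - counts[j])
                return float(centers[i] + frac * (centers[j] - centers[i]))
            i = j
        return None

    left, right = _crossing(-1), _crossing(+1)
    if left is None or right is None:
        raise DegenerateHistogramError(
            "in-liver histogram never falls below half maximum on both sides "
            "(constant or near-constant intensities?)")
    fwhm = right - left
    sigma = fwhm / FWHM_TO_SIGMA
    if sigma <= 0:
        raise DegenerateHistogramError(f"non-positive FWHM estimate ({fwhm})")
    return NormalizationStats(center=float((left + right) / 2.0), sigma=float(sigma),
                              fwhm=float(fwhm))


def normalize_in_mask(volume: CTVolume, liver: BinaryMask, stats: NormalizationStats) -> CTVolume:
    """Standardize in-liver intensities to (HU - centre)/sigma; zero outside the liver."""
    if stats.sigma <= 0:
        raise ValueError("stats.sigma must be > 0")
    if not volume.same_grid(liver):
        raise AlignmentError("volume and liver mask are on different grids")
    inside = liver.voxels > 0
    out = np.zeros_like(volume.voxels, dtype=np.float32)
    out[inside] = (volume.voxels[inside] - stats.center) / stats.sigma
    return CTVolume(out, volume.spacing, volume.origin, volume.patient_id)
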