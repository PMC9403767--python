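"""Lesion-level and patient-level segmentation metrics at original resolution.

Metrics follow the conventions used for liver-lesion model evaluation:

* **DSC** — Dice similarity coefficient ``2|A∩B| / (|A|+|B|)``, reported per
  disease site, per patient, and *globally* (all patients' masks pooled into
  one pair, the LiTS-challenge convention).
* **Median surface distance (MSD)** — the median of the pooled symmetric
  nearest-surface distances between the two mask boundaries, in mm.
* **Detection sensitivity** — a ground-truth site counts as detected when at
  least 45% of its voxels are covered by the predicted segmentation
  (boundary inclusive).
* **False positives** — predicted-minus-truth voxels, split into *erroneous*
  volume (predicted components with zero ground-truth overlap) and
  *over-segmentation* volume (the remaining false-positive voxels, i.e. spill
  around detected lesions).  Erroneous + over-segmentation = total
  false-positive volume by construction.

All metrics are computed at the original image resolution; predictions made on
a resampled grid must be mapped back (nearest-neighbour) first.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .errors import AlignmentError
from .slabs import ComponentSet, label_components
from .volumes import BinaryMask, CTVolume, resample_to_spacing

SENSITIVITY_OVERLAP = 0.45
DEFAULT_DIAMETER_BINS = (15.0,)   # <15 mm / >=15 mm


# ------------------------------------------------------------------ overlap

def _check_grid(a, b):
    if not a.same_grid(b):
        raise AlignmentError("masks are on different grids")


def dice(a: BinaryMask, b: BinaryMask) -> float:
    """Dice similarity coefficient; two empty masks score 1.0 by convention."""
    _check_grid(a, b)
    av, bv = a.voxels.astype(bool), b.voxels.astype(bool)
    denom = int(av.sum()) + int(bv.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((av & bv).sum()) / denom


def global_dice(pairs: list[tuple[BinaryMask, BinaryMask]]) -> float:
    """Pooled DSC over a cohort: 2*sum(|A_i ∩ B_i|) / sum(|A_i| + |B_i|)."""
    if not pairs:
        raise ValueError("need at least one mask pair")
    inter = denom = 0
    for a, b in pairs:
        _check_grid(a, b)
        av, bv = a.voxels.astype(bool), b.voxels.astype(bool)
        inter += int((av & bv).sum())
        denom += int(av.sum()) + int(bv.sum())
    return 1.0 if denom == 0 else 2.0 * inter / denom


# ----------------------------------------------------------- surface distance

def _surface_points_mm(mask: np.ndarray, spacing) -> np.ndarray:
    """Centres (mm) of mask voxels with at least one face-adjacent background voxel."""
    m = mask.astype(bool)
    eroded = ndimage.binary_erosion(m, structure=ndimage.generate_binary_structure(3, 1),
                                    border_value=0)
    surf = m & ~eroded
    return (np.argwhere(surf) + 0.5) * np.asarray(spacing)


def median_surface_distance(a: BinaryMask, b: BinaryMask,
                            spacing=None) -> float:
    """Median of the pooled symmetric nearest-surface distances, in mm.

    Undefined for an empty mask: raises ValueError (callers report it as
    missing rather than zero).
    """
    spacing = spacing if spacing is not None else a.spacing
    if a.count() == 0 or b.count() == 0:
        raise ValueError("median surface distance is undefined for an empty mask")
    pa = _surface_points_mm(a.voxels, spacing)
    pb = _surface_points_mm(b.voxels, spacing)
    d_ab = cKDTree(pb).query(pa)[0]
    d_ba = cKDTree(pa).query(pb)[0]
    return float(np.median(np.concatenate([d_ab, d_ba])))


# ------------------------------------------------------------ site matching

def match_sites(gt: ComponentSet, pred: ComponentSet) -> list[tuple[int, int | None]]:
    """Match every GT component to the predicted component with the nearest centroid.

    A predicted component may serve several GT sites; with no predictions all
    GT sites are unmatched.
    """
    out: list[tuple[int, int | None]] = []
    for gid in range(1, gt.count + 1):
        if pred.count == 0:
            out.append((gid, None))
            continue
        d = np.linalg.norm(pred.centroids_mm - gt.centroids_mm[gid - 1], axis=1)
        out.append((gid, int(np.argmin(d)) + 1))
    return out


def site_sensitivity(gt_component: np.ndarray, pred_union: np.ndarray) -> tuple[float, bool]:
    """Covered fraction of one GT site against the union of ALL predicted voxels."""
    gt = np.asarray(gt_component, bool)
    n = int(gt.sum())
    if n == 0:
        raise ValueError("ground-truth component is empty")
    frac = int((gt & np.asarray(pred_union, bool)).sum()) / n
    return frac, frac >= SENSITIVITY_OVERLAP


# ----------------------------------------------------------- false positives

def false_positive_metrics(gt: BinaryMask, pred: BinaryMask,
                           connectivity: int = 26) -> tuple[int, float, float, float]:
    """(discoveries, fp_cc, erroneous_cc, oversegmentation_cc).

    *Discoveries* counts predicted components with zero GT overlap; their
    voxels form the erroneous volume.  The remaining false-positive voxels
    (spill from components that do touch GT) are over-segmentation.
    """
    _check_grid(gt, pred)
    gtv = gt.voxels.astype(bool)
    fp = pred.voxels.astype(bool) & ~gtv
    vox_cc = gt.voxel_volume_mm3 / 1000.0
    comps = label_components(pred, connectivity=connectivity)
    discoveries = 0
    erroneous_vox = 0
    for cid in range(1, comps.count + 1):
        cmask = comps.labels == cid
        if not np.any(cmask & gtv):
            discoveries += 1
            erroneous_vox += int(cmask.sum())
    fp_vox = int(fp.sum())
    return (discoveries, fp_vox * vox_cc, erroneous_vox * vox_cc,
            (fp_vox - erroneous_vox) * vox_cc)


# -------------------------------------------------------------- geometry

def equivalent_diameter(component_volume_cc: float) -> float:
    """Sphere-equivalent diameter (mm) of a component volume given in cc."""
    if component_volume_cc <= 0:
        raise ValueError("component volume must be > 0")
    v_mm3 = component_volume_cc * 1000.0
    return (6.0 * v_mm3 / math.pi) ** (1.0 / 3.0)


# ---------------------------------------------------------------- reporting

@dataclasses.dataclass
class SiteResult:
    gt_component_id: int
    matched_pred_component_id: int | None
    centroid_distance_mm: float | None
    dsc: float
    median_surface_distance_mm: float | None
    gt_overlap_fraction: float
    detected: bool
    equivalent_diameter_mm: float


@dataclasses.dataclass
class PatientResult:
    patient_id: str
    dsc: float
    median_surface_distance_mm: float | None
    false_positive_discoveries: int
    false_positive_volume_cc: float
    erroneous_fp_volume_cc: float
    oversegmentation_fp_volume_cc: float
    site_results: list[SiteResult]


@dataclasses.dataclass
class CohortResult:
    patients: list[PatientResult]
    global_dsc: float
    site_table: pd.DataFrame        # one row per GT site
    size_summary: pd.DataFrame      # stratified by diameter bin

    def patient_table(self) -> pd.DataFrame:
        return pd.DataFrame([
            {
                "patient_id": p.patient_id,
                "Dice similarity coefficient": p.dsc,
                "Median surface distance (mm)": p.median_surface_distance_mm,
                "False-positive discoveries (per patient)": p.false_positive_discoveries,
                "False-positive volume (cc)": p.false_positive_volume_cc,
                "Erroneous false-positive volume (cc)": p.erroneous_fp_volume_cc,
                "Over-segmentation false-positive volume (cc)": p.oversegmentation_fp_volume_cc,
            }
            for p in self.patients
        ])


def _mask_from(comp_labels: np.ndarray, cid: int, like: BinaryMask) -> BinaryMask:
    return BinaryMask((comp_labels == cid).astype(np.uint8), like.spacing, like.origin,
                      like.patient_id, like.kind)


def evaluate_patient(gt: BinaryMask, pred: BinaryMask, connectivity: int = 26) -> PatientResult:
    """All patient-level and site-level metrics for one (GT, prediction) pair."""
    _check_grid(gt, pred)
    gt_comps = label_components(gt, connectivity=connectivity)
    pred_comps = label_components(pred, connectivity=connectivity)
    matches = match_sites(gt_comps, pred_comps)
    pred_union = pred.voxels.astype(bool)

    sites = []
    for gid, pid in matches:
        gmask = gt_comps.labels == gid
        frac, det = site_sensitivity(gmask, pred_union)
        diam = equivalent_diameter(float(gt_comps.volumes_cc[gid - 1]))
        if pid is None:
            sites.append(SiteResult(gid, None, None, 0.0, None, frac, det, diam))
            continue
        g = _mask_from(gt_comps.labels, gid, gt)
        p = _mask_from(pred_comps.labels, pid, pred)
        site_dsc = dice(g, p)
        msd = (median_surface_distance(g, p) if g.count() and p.count() else None)
        cdist = float(np.linalg.norm(gt_comps.centroids_mm[gid - 1]
                                     - pred_comps.centroids_mm[pid - 1]))
        sites.append(SiteResult(gid, pid, cdist, site_dsc, msd, frac, det, diam))

    disc, fp_cc, err_cc, over_cc = false_positive_metrics(gt, pred, connectivity)
    try:
        patient_msd = median_surface_distance(gt, pred)
    except ValueError:
        patient_msd = None
    return PatientResult(
        patient_id=gt.patient_id, dsc=dice(gt, pred), median_surface_distance_mm=patient_msd,
        false_positive_discoveries=disc, false_positive_volume_cc=fp_cc,
        erroneous_fp_volume_cc=err_cc, oversegmentation_fp_volume_cc=over_cc,
        site_results=sites)


def _bin_label(diam: float, edges) -> str:
    prev = None
    for e in edges:
        if diam < e:
            return f"<{e:g} mm" if prev is None else f"{prev:g}-{e:g} mm"
        prev = e
    return f">={prev:g} mm"


def evaluate_cohort(cases: list[tuple[BinaryMask, BinaryMask, CTVolume | None]],
                    diameter_bins=DEFAULT_DIAMETER_BINS,
                    connectivity: int = 26) -> CohortResult:
    """Evaluate a cohort of (gt, prediction, original-grid volume or None) cases.

    When an original-grid volume is supplied and the prediction lives on a
    different grid (e.g. the 1 x 0.75 x 0.75 mm training grid), the prediction
    is resampled back with nearest-neighbour interpolation before any metric
    is computed.
    """
    patients = []
    pairs = []
    for gt, pred, original in cases:
        if original is not None and not pred.same_grid(original):
            pred = resample_to_spacing(pred, original.spacing, mode="nearest")
            if pred.shape != original.shape:
                raise AlignmentError(
                    f"prediction resampled to {pred.shape} but original grid is {original.shape}")
            pred = dataclasses.replace(pred, origin=original.origin)
        patients.append(evaluate_patient(gt, pred, connectivity))
        pairs.append((gt, pred))

    rows = []
    for p in patients:
        for s in p.site_results:
            rows.append({
                "patient_id": p.patient_id, "gt_component_id": s.gt_component_id,
                "diameter_mm": s.equivalent_diameter_mm,
                "bin": _bin_label(s.equivalent_diameter_mm, diameter_bins),
                "dsc": s.dsc, "msd_mm": s.median_surface_distance_mm,
                "gt_overlap_fraction": s.gt_overlap_fraction, "detected": s.detected,
            })
    site_table = pd.DataFrame(rows)
    if len(site_table):
        grouped = site_table.groupby("bin", sort=False)
        size_summary = grouped.agg(
            n_sites=("dsc", "size"),
            mean_dsc=("dsc", "mean"), min_dsc=("dsc", "min"), max_dsc=("dsc", "max"),
            median_msd_mm=("msd_mm", "median"), min_msd_mm=("msd_mm", "min"),
            max_msd_mm=("msd_mm", "max"),
            sensitivity=("detected", "mean"),
        ).reset_index()
    else:
        size_summary = pd.DataFrame()
    return CohortResult(patients=patients, global_dsc=global_dice(pairs),
                        site_table=site_table, size_summary=size_summary)
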