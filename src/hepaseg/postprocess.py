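"""Seed-and-threshold growth on probability maps, and (seed, threshold) tuning.

A trained network outputs a per-voxel disease probability in [0, 1].  The most
inferior/superior slices of a lesion typically score lower than its centre, so
plain thresholding either clips lesion poles (high threshold) or floods noise
(low threshold).  Seeded growth does both jobs: voxels above a high *seed*
value mark confident lesion cores, which are then grown outward through the
connected region above a lower *threshold*.  Components above threshold that
contain no seed voxel are discarded.

The defaults (seed 0.67, threshold 0.30) are the grid-search optimum found on
the validation data of the original study; `tune_seed_threshold` re-derives
such an optimum for any cohort.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import ndimage

from .volumes import BinaryMask, CTVolume

DEFAULT_SEED = 0.67
DEFAULT_THRESHOLD = 0.30


@dataclasses.dataclass
class ProbabilityMap:
    """Per-voxel disease probability on the same grid as its CT volume."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    patient_id: str = ""
    model: str = ""

    def __post_init__(self):
        vox = np.asarray(self.voxels, dtype=np.float32)
        if vox.ndim != 3:
            raise ValueError(f"expected a 3D probability map, got shape {vox.shape}")
        if vox.min() < 0 or vox.max() > 1:
            raise ValueError("probabilities must lie in [0, 1]")
        self.voxels = vox
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    shape = CTVolume.shape
    voxel_volume_mm3 = CTVolume.voxel_volume_mm3
    grid = CTVolume.grid
    same_grid = CTVolume.same_grid


@dataclasses.dataclass(frozen=True)
class GrowParams:
    seed: float = DEFAULT_SEED
    threshold: float = DEFAULT_THRESHOLD
    connectivity: int = 26

    def __post_init__(self):
        if not (0 < self.threshold <= self.seed <= 1):
            raise ValueError(
                f"require 0 < threshold <= seed <= 1, got seed={self.seed}, "
                f"threshold={self.threshold}")
        if self.connectivity not in (6, 26):
            raise ValueError("connectivity must be 6 or 26")


def _structure(connectivity: int) -> np.ndarray:
    return ndimage.generate_binary_structure(3, 3 if connectivity == 26 else 1)


def seed_threshold_grow(prob: ProbabilityMap, params: GrowParams = GrowParams()) -> BinaryMask:
    """Grow seed voxels (prob >= seed) through the connected region prob >= threshold."""
    above_thr = prob.voxels >= params.threshold
    out = np.zeros(prob.shape, dtype=np.uint8)
    if above_thr.any():
        labels, n = ndimage.label(above_thr, structure=_structure(params.connectivity))
        if n:
            seeded = np.unique(labels[prob.voxels >= params.seed])
            seeded = seeded[seeded > 0]
            if seeded.size:
                out = np.isin(labels, seeded).astype(np.uint8)
    return BinaryMask(out, prob.spacing, prob.origin, prob.patient_id, kind="prediction")


def default_seed_grid() -> np.ndarray:
    return np.round(np.arange(0.25, 0.95 + 1e-9, 0.01), 2)


def default_threshold_grid() -> np.ndarray:
    return np.round(np.arange(0.20, 0.80 + 1e-9, 0.01), 2)


def tune_seed_threshold(probs: list[ProbabilityMap], refs: list[BinaryMask],
                        seed_grid=None, threshold_grid=None,
                        objective: str = "mean_patient_dsc",
                        connectivity: int = 26) -> tuple[GrowParams, pd.DataFrame]:
    """Exhaustive grid search over (seed, threshold) pairs with seed >= threshold.

    Returns the best parameters (ties resolved toward the smallest seed, then
    the smallest threshold) and the full score table.  The objective is the
    mean patient-wise Dice by default; ``global_dsc`` pools all voxels.
    """
    if len(probs) != len(refs):
        raise ValueError("probs and refs must be paired lists of equal length")
    if not probs:
        raise ValueError("need at least one (probability map, reference) pair")
    if objective not in ("mean_patient_dsc", "global_dsc"):
        raise ValueError(f"unknown objective {objective!r}")
    seed_grid = default_seed_grid() if seed_grid is None else np.asarray(seed_grid, float)
    threshold_grid = (default_threshold_grid() if threshold_grid is None
                      else np.asarray(threshold_grid, float))
    if seed_grid.size == 0 or threshold_grid.size == 0:
        raise ValueError("grids must be non-empty")

    rows = []
    best = (-np.inf, np.inf, np.inf)  # (score, seed, threshold) with tie-breaks
    best_params = None
    # labelling at each threshold is shared across every seed value
    for thr in sorted(threshold_grid):
        seeds = np.array(sorted(s for s in seed_grid if s >= thr))
        if seeds.size == 0:
            continue
        per_case = []  # (labels, per-component max prob, ref) per case
        for p, r in zip(probs, refs):
            labels, n = ndimage.label(p.voxels >= thr, structure=_structure(connectivity))
            comp_max = ndimage.maximum(p.voxels, labels, np.arange(1, n + 1)) if n else np.zeros(0)
            per_case.append((labels, np.asarray(comp_max), r))
        for s in seeds:
            inters = sizes_a = sizes_b = 0
            dscs = []
            for (labels, comp_max, r) in per_case:
                keep = np.flatnonzero(comp_max >= s) + 1
                pred = np.isin(labels, keep) if keep.size else np.zeros_like(labels, bool)
                gt = r.voxels.astype(bool)
                inter = int((pred & gt).sum())
                na, nb = int(pred.sum()), int(gt.sum())
                inters += inter; sizes_a += na; sizes_b += nb
                dscs.append(1.0 if na + nb == 0 else 2.0 * inter / (na + nb))
            score = (float(np.mean(dscs)) if objective == "mean_patient_dsc"
                     else (1.0 if sizes_a + sizes_b == 0 else 2.0 * inters / (sizes_a + sizes_b)))
            rows.append({"seed": float(s), "threshold": float(thr), objective: score})
            key = (score, -float(s), -float(thr))
            if key > best:
                best = key
                best_params = GrowParams(float(s), float(thr), connectivity)
    table = pd.DataFrame(rows).sort_values(["seed", "threshold"]).reset_index(drop=True)
    return best_params, table
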