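"""Contour and region evaluation for LV segmentation.

The per-slice measures are the dice metric DM = 2|A_s ∩ A_g| / (|A_s| +
|A_g|) between the segmented and ground-truth areas, and the average
perpendicular distance (APD) between the two boundary contours in mm.
A slice is "good" when its APD is strictly below 5 mm.  Per case, the
percentage of good contours (PGC) is taken over all slices, while mean
DM and APD are computed over the good slices only; a slice where the
method found no structure counts against PGC but is excluded from the
DM/APD means.

APD here is the symmetric convention: the mean over vertices of one
contour of the distance to the nearest *segment* of the other polyline,
averaged over both directions, computed in physical mm (anisotropic
pixel spacing supported).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import LinearRing, Point
from skimage import measure

GOOD_APD_MM = 5.0


@dataclass
class Contour:
    """Closed boundary polyline in pixel coordinates with physical spacing.

    ``points`` is an (M, 2) array of (x, y) = (col, row) vertices; the
    polyline is implicitly closed (last vertex connects to the first).
    ``spacing`` is mm/pixel: a scalar, or (sx, sy) for anisotropic grids.
    """

    points: np.ndarray
    spacing: float | tuple[float, float] = 1.0

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2 or len(self.points) < 3:
            raise ValueError("a contour needs at least 3 (x, y) points")
        sx, sy = self.spacing_xy
        if sx <= 0 or sy <= 0:
            raise ValueError("pixel spacing must be positive")

    @property
    def spacing_xy(self) -> tuple[float, float]:
        if np.isscalar(self.spacing):
            return float(self.spacing), float(self.spacing)
        sx, sy = self.spacing
        return float(sx), float(sy)

    def points_mm(self) -> np.ndarray:
        sx, sy = self.spacing_xy
        return self.points * np.array([sx, sy])


@dataclass
class SliceEval:
    """Evaluation record of one slice; apd/dm are None for empty predictions."""

    apd_mm: float | None
    dm: float | None
    good: bool


@dataclass
class CaseMetrics:
    pgc_percent: float
    mean_dm_of_good: float | None
    mean_apd_of_good: float | None
    n_slices: int
    n_good: int
    slice_evals: list[SliceEval]


@dataclass
class SummaryStats:
    """Cohort mean and sample SD of PGC / DM / APD across cases."""

    pgc_mean: float
    pgc_sd: float
    dm_mean: float
    dm_sd: float
    apd_mean: float
    apd_sd: float
    n_cases: int


def dice(mask_s: np.ndarray, mask_g: np.ndarray) -> float:
    """Dice metric 2|A_s ∩ A_g| / (|A_s| + |A_g|) of two same-shape binary masks."""
    mask_s = np.asarray(mask_s).astype(bool)
    mask_g = np.asarray(mask_g).astype(bool)
    if mask_s.shape != mask_g.shape:
        raise ValueError(f"mask shapes differ: {mask_s.shape} vs {mask_g.shape}")
    total = int(mask_s.sum()) + int(mask_g.sum())
    if total == 0:
        raise ValueError("dice is undefined when both masks are empty")
    return 2.0 * int((mask_s & mask_g).sum()) / total


def mask_to_contour(mask: np.ndarray, spacing: float | tuple[float, float] = 1.0) -> Contour:
    """Sub-pixel closed boundary of a single-component binary mask.

    Uses the 0.5 iso-contour of the binary image (marching squares), so
    the polyline sits half a pixel outside the foreground pixel centers.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("cannot extract a contour from an empty mask")
    n_comp = int(measure.label(mask, connectivity=1).max())
    if n_comp != 1:
        raise ValueError(f"mask has {n_comp} connected components, expected exactly 1")
    contours = measure.find_contours(mask.astype(float), 0.5)
    # the outer boundary is the longest iso-line (holes would be shorter)
    rc = max(contours, key=len)
    points_xy = rc[:, ::-1]  # (row, col) -> (x, y)
    return Contour(points=points_xy, spacing=spacing)


def _directed_mean_distance(pts_mm: np.ndarray, ring: LinearRing) -> float:
    return float(np.mean([ring.distance(Point(p)) for p in pts_mm]))


def apd(contour_a: Contour, contour_b: Contour) -> float:
    """Symmetric average perpendicular distance between two contours, in mm."""
    if contour_a.spacing_xy != contour_b.spacing_xy:
        raise ValueError(
            f"pixel spacing mismatch: {contour_a.spacing_xy} vs {contour_b.spacing_xy}"
        )
    a_mm = contour_a.points_mm()
    b_mm = contour_b.points_mm()
    ring_a = LinearRing(a_mm)
    ring_b = LinearRing(b_mm)
    return 0.5 * (_directed_mean_distance(a_mm, ring_b)
                  + _directed_mean_distance(b_mm, ring_a))


def classify_good(apd_mm: float) -> bool:
    """A contour is good iff its APD is strictly less than 5 mm."""
    if apd_mm < 0:
        raise ValueError("APD cannot be negative")
    return apd_mm < GOOD_APD_MM


def evaluate_slice(pred_mask: np.ndarray, gt_mask: np.ndarray,
                   spacing: float | tuple[float, float]) -> SliceEval:
    pred_mask = np.asarray(pred_mask).astype(bool)
    gt_mask = np.asarray(gt_mask).astype(bool)
    if not gt_mask.any():
        raise ValueError("ground-truth mask is empty")
    if not pred_mask.any():
        return SliceEval(apd_mm=None, dm=None, good=False)
    dm = dice(pred_mask, gt_mask)
    c_pred = mask_to_contour(pred_mask, spacing)
    c_gt = mask_to_contour(gt_mask, spacing)
    a = apd(c_pred, c_gt)
    return SliceEval(apd_mm=a, dm=dm, good=classify_good(a))


def evaluate_case(pred_masks, gt_masks,
                  spacing: float | tuple[float, float]) -> CaseMetrics:
    """Per-case PGC over all slices; DM/APD means over the good slices only."""
    if len(pred_masks) != len(gt_masks):
        raise ValueError(
            f"{len(pred_masks)} predictions vs {len(gt_masks)} ground-truth slices"
        )
    if len(pred_masks) == 0:
        raise ValueError("cannot evaluate an empty case")
    evals = [evaluate_slice(p, g, spacing) for p, g in zip(pred_masks, gt_masks)]
    n = len(evals)
    good = [e for e in evals if e.good]
    return CaseMetrics(
        pgc_percent=100.0 * len(good) / n,
        mean_dm_of_good=float(np.mean([e.dm for e in good])) if good else None,
        mean_apd_of_good=float(np.mean([e.apd_mm for e in good])) if good else None,
        n_slices=n,
        n_good=len(good),
        slice_evals=evals,
    )


def _mean_sd(values) -> tuple[float, float]:
    arr = np.asarray([v for v in values if v is not None], dtype=float)
    if arr.size == 0:
        return float("nan"), float("nan")
    if arr.size == 1:
        return float(arr[0]), 0.0
    return float(arr.mean()), float(arr.std(ddof=1))


def summarize(cases: list[CaseMetrics]) -> SummaryStats:
    """Cohort mean / sample SD rows (ddof=1; a single case reports SD 0)."""
    if not cases:
        raise ValueError("summarize needs at least one case")
    pgc_m, pgc_s = _mean_sd([c.pgc_percent for c in cases])
    dm_m, dm_s = _mean_sd([c.mean_dm_of_good for c in cases])
    apd_m, apd_s = _mean_sd([c.mean_apd_of_good for c in cases])
    return SummaryStats(pgc_m, pgc_s, dm_m, dm_s, apd_m, apd_s, len(cases))
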