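"""LV localization and fixed-size ROI cropping.

The left ventricle is the most strongly moving structure in a cine
stack, so the locator computes the per-pixel temporal standard
deviation across frames, clusters those values with k-means (default
k=3), binarizes the highest-mean cluster, and returns the centroid of
the connected component nearest the frame center.  If clustering
yields no component, an Otsu threshold on the variation map is used as
fallback.  Cropping then takes a size x size window centred on that
point, shifted (never padded) to stay inside the frame, recording the
offset so predictions can be mapped back to full-frame coordinates.

All coordinates are 0-based (row, col); offsets refer to the window's
top-left corner.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure
from skimage.filters import threshold_otsu
from sklearn.cluster import KMeans


class DegenerateInputError(ValueError):
    """Raised when the input carries no usable localization signal."""


@dataclass
class RoiResult:
    roi: np.ndarray
    offset: tuple[int, int]           # (row, col) of top-left in source frame
    center_estimate: tuple[float, float]

    @property
    def size(self) -> int:
        return self.roi.shape[0]


def temporal_variation_map(cine_stack) -> np.ndarray:
    """Per-pixel standard deviation across the frames of a cine stack."""
    frames = np.stack([np.asarray(f, dtype=float) for f in cine_stack])
    if frames.shape[0] < 2:
        raise ValueError("need at least 2 frames to measure temporal variation")
    return frames.std(axis=0)


def locate_lv_center(cine_stack, k: int = 3) -> tuple[float, float]:
    """Estimate the LV blood-pool centroid (row, col) from a cine stack."""
    if k < 2:
        raise ValueError("k-means needs k >= 2")
    var_map = temporal_variation_map(cine_stack)
    if float(var_map.max()) == 0.0:
        raise DegenerateInputError(
            "cine stack has no temporal variation (identical frames); "
            "the moving-structure cue cannot localize the LV"
        )
    km = KMeans(n_clusters=k, n_init=4, random_state=0)
    labels = km.fit_predict(var_map.reshape(-1, 1)).reshape(var_map.shape)
    top = int(np.argmax(km.cluster_centers_.ravel()))
    binary = labels == top
    comp = measure.label(binary, connectivity=1)
    if comp.max() == 0:
        # threshold-adjustment fallback
        binary = var_map > threshold_otsu(var_map)
        comp = measure.label(binary, connectivity=1)
        if comp.max() == 0:
            raise DegenerateInputError("no moving component found in the cine stack")
    frame_center = (np.array(var_map.shape) - 1) / 2.0
    best, best_d = None, np.inf
    for region in measure.regionprops(comp):
        d = float(np.hypot(*(np.array(region.centroid) - frame_center)))
        if d < best_d:
            best, best_d = region.centroid, d
    return float(best[0]), float(best[1])


def crop_roi(image: np.ndarray, center, size: int = 128) -> RoiResult:
    """Crop a size x size window centred on ``center``, clamped into the frame."""
    image = np.asarray(image)
    h, w = image.shape[:2]
    if size > min(h, w):
        raise ValueError(
            f"ROI size {size} exceeds image dimensions {h}x{w}; resize or pad "
            f"the input explicitly before cropping"
        )
    r0 = int(round(center[0])) - size // 2
    c0 = int(round(center[1])) - size // 2
    r0 = min(max(r0, 0), h - size)
    c0 = min(max(c0, 0), w - size)
    roi = image[r0:r0 + size, c0:c0 + size]
    return RoiResult(roi=roi.copy(), offset=(r0, c0),
                     center_estimate=(float(center[0]), float(center[1])))


def paste_back(patch: np.ndarray, offset: tuple[int, int], frame_shape) -> np.ndarray:
    """Place an ROI-sized array back into a zero full frame at ``offset``."""
    out = np.zeros(frame_shape, dtype=patch.dtype)
    r0, c0 = offset
    out[r0:r0 + patch.shape[0], c0:c0 + patch.shape[1]] = patch
    return out
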