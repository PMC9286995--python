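"""Ten-fold training-set augmentation.

Each ROI/mask training pair is expanded to ten: the original, seven
clockwise rotations (45°..315° in 45° steps) and horizontal/vertical
flips of the original.  Rotations by multiples of 90° and flips are
exact pixel permutations; the 45° family uses bilinear interpolation
for images and nearest-neighbour for masks (so masks stay binary),
with out-of-frame corners filled by the median of the image corners
(images) or 0 (masks).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

ROTATION_ANGLES = (45, 90, 135, 180, 225, 270, 315)
AUGMENT_TAGS = ("original", "rot45", "rot90", "rot135", "rot180",
                "rot225", "rot270", "rot315", "hflip", "vflip")


@dataclass
class AugmentedPair:
    tag: str
    image: np.ndarray
    mask: np.ndarray


def _check_pair(image: np.ndarray, mask: np.ndarray) -> None:
    if image.shape != mask.shape:
        raise ValueError(f"image {image.shape} and mask {mask.shape} shapes differ")
    vals = np.unique(mask)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError(f"mask must be binary (0/1), found values {vals[:5]}")


def rotate_pair(image: np.ndarray, mask: np.ndarray,
                angle_deg: int) -> tuple[np.ndarray, np.ndarray]:
    """Rotate an image/mask pair clockwise about the image center."""
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask).astype(np.uint8)
    _check_pair(image, mask)
    if image.shape[0] != image.shape[1]:
        raise ValueError(
            f"rotation requires square inputs, got {image.shape}; 45° rotation "
            f"of non-square grids is ill-defined here"
        )
    if angle_deg not in ROTATION_ANGLES:
        raise ValueError(f"angle must be one of {ROTATION_ANGLES}, got {angle_deg}")
    if angle_deg % 90 == 0:
        k = -(angle_deg // 90)  # negative k = clockwise in (row, col) display
        return np.rot90(image, k=k), np.rot90(mask, k=k)
    bg = float(np.median([image[0, 0], image[0, -1], image[-1, 0], image[-1, -1]]))
    rot_img = ndimage.rotate(image, -angle_deg, reshape=False, order=1,
                             mode="constant", cval=bg)
    rot_mask = ndimage.rotate(mask, -angle_deg, reshape=False, order=0,
                              mode="constant", cval=0)
    return rot_img, rot_mask.astype(np.uint8)


def augment_tenfold(image: np.ndarray, mask: np.ndarray) -> list[AugmentedPair]:
    """Original + 7 rotations + horizontal flip + vertical flip = 10 pairs."""
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask).astype(np.uint8)
    _check_pair(image, mask)
    out = [AugmentedPair("original", image.copy(), mask.copy())]
    for angle in ROTATION_ANGLES:
        ri, rm = rotate_pair(image, mask, angle)
        out.append(AugmentedPair(f"rot{angle}", ri, rm))
    out.append(AugmentedPair("hflip", np.fliplr(image).copy(), np.fliplr(mask).copy()))
    out.append(AugmentedPair("vflip", np.flipud(image).copy(), np.flipud(mask).copy()))
    assert len(out) == len(AUGMENT_TAGS)
    return out
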