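"""Synthetic short-axis cine cardiac MR phantom.

Each case is a stack of 6–12 short-axis slices at end-diastole (ED) and
end-systole (ES): a bright, roughly circular blood pool (the LV cavity)
inside a darker myocardial ring on a dim textured background.  The endo
radius shrinks multiplicatively at ES and tapers from base to apex;
additive Gaussian noise is applied to the image only, so the ground
truth endo/epi masks and contours are exact.

Rasterization rule: a pixel belongs to a disc iff its center lies
strictly inside the (possibly sinusoidally perturbed) radius — a fixed,
half-open convention, because mask pixel counts feed the volume and
dice oracles downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

DEFAULT_PIXEL_SPACING_MM = 1.367
DEFAULT_SLICE_THICKNESS_MM = 8.0


@dataclass
class PhantomConfig:
    """Geometry, intensity and noise settings of the simulated acquisition.

    Defaults mimic a short-axis cine protocol: 256x256 frames at
    1.367 mm/pixel, 8 mm slices, 6–12 slices per case, and an ES
    endocardial radius of 0.65x the ED radius (per-slice area ratio
    0.65^2, i.e. a physiological ejection fraction near 58%).
    """

    image_size: int = 256
    pixel_spacing_mm: float = DEFAULT_PIXEL_SPACING_MM
    slice_thickness_mm: float = DEFAULT_SLICE_THICKNESS_MM
    n_slices: int | None = None  # None: per-case uniform draw from n_slices_range
    n_slices_range: tuple[int, int] = (6, 12)
    endo_radius_px: tuple[float, float] = (14.0, 22.0)
    wall_thickness_px: tuple[float, float] = (5.0, 9.0)
    es_scale: float = 0.65
    intensity_pool: float = 400.0
    intensity_myo: float = 180.0
    intensity_bg: float = 60.0
    noise_sd: float = 12.0
    center_jitter_px: float = 10.0
    apex_taper: float = 0.93
    wobble_amp_px: float = 0.0  # sinusoidal boundary perturbation amplitude
    wobble_lobes: int = 5
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.es_scale <= 1.0):
            raise ValueError(f"es_scale must be in (0, 1], got {self.es_scale}")
        if self.intensity_pool <= self.intensity_myo:
            raise ValueError("blood pool must be brighter than myocardium")
        if self.endo_radius_px[1] + self.wall_thickness_px[1] >= self.image_size / 2:
            raise ValueError("endo radius + wall thickness must fit within half the frame")
        for name in ("image_size", "pixel_spacing_mm", "slice_thickness_mm", "noise_sd"):
            if getattr(self, name) < 0 or (name != "noise_sd" and getattr(self, name) <= 0):
                raise ValueError(f"{name} must be positive")
        lo, hi = self.n_slices_range
        if not (1 <= lo <= hi):
            raise ValueError("invalid n_slices_range")


@dataclass
class SliceRecord:
    """One simulated slice with its exact ground truth and provenance."""

    image: np.ndarray
    endo_mask: np.ndarray
    epi_mask: np.ndarray
    phase: str  # "ED" | "ES"
    slice_index: int
    center: tuple[float, float]  # (row, col)
    endo_radius_px: float
    epi_radius_px: float


@dataclass
class PhantomCase:
    """A full cine case: ED and ES stacks ordered base -> apex."""

    case_id: str
    config: PhantomConfig
    slices: list[SliceRecord] = field(default_factory=list)

    def phase_slices(self, phase: str) -> list[SliceRecord]:
        return [s for s in self.slices if s.phase == phase]


def _disc_mask(size: int, center: tuple[float, float], radius: float,
               wobble_amp: float = 0.0, wobble_lobes: int = 5,
               wobble_phase: float = 0.0) -> np.ndarray:
    rows, cols = np.mgrid[0:size, 0:size]
    dy = rows - center[0]
    dx = cols - center[1]
    dist = np.hypot(dy, dx)
    if wobble_amp > 0:
        theta = np.arctan2(dy, dx)
        r_eff = radius + wobble_amp * np.sin(wobble_lobes * theta + wobble_phase)
    else:
        r_eff = radius
    return dist < r_eff


def generate_slice(
    config: PhantomConfig,
    center: tuple[float, float],
    endo_radius_px: float,
    wall_px: float,
    phase: str,
    rng: np.random.Generator,
    slice_index: int = 0,
    wobble_phase: float = 0.0,
) -> SliceRecord:
    """Render one slice: background + myocardial annulus + blood pool + noise.

    ``endo_radius_px`` is the ED radius; at ES it is multiplied by
    ``config.es_scale``.  Masks are computed on the noiseless geometry.
    """
    if phase not in ("ED", "ES"):
        raise ValueError(f"phase must be 'ED' or 'ES', got {phase!r}")
    endo_r = endo_radius_px * (config.es_scale if phase == "ES" else 1.0)
    epi_r = endo_r + wall_px
    size = config.image_size
    max_r = epi_r + config.wobble_amp_px
    if (center[0] - max_r < 0 or center[0] + max_r > size - 1
            or center[1] - max_r < 0 or center[1] + max_r > size - 1):
        raise ValueError(
            f"epicardial radius {epi_r:.1f}px at center {center} exceeds the "
            f"{size}x{size} frame"
        )
    endo_mask = _disc_mask(size, center, endo_r, config.wobble_amp_px,
                           config.wobble_lobes, wobble_phase)
    epi_mask = _disc_mask(size, center, epi_r, config.wobble_amp_px,
                          config.wobble_lobes, wobble_phase)
    image = np.full((size, size), config.intensity_bg, dtype=np.float64)
    image[epi_mask] = config.intensity_myo
    image[endo_mask] = config.intensity_pool
    if config.noise_sd > 0:
        image = image + rng.normal(0.0, config.noise_sd, size=image.shape)
    return SliceRecord(
        image=image,
        endo_mask=endo_mask,
        epi_mask=epi_mask,
        phase=phase,
        slice_index=slice_index,
        center=(float(center[0]), float(center[1])),
        endo_radius_px=float(endo_r),
        epi_radius_px=float(epi_r),
    )


def generate_case(config: PhantomConfig, seed: int, case_id: str = "case") -> PhantomCase:
    """Generate a full case deterministically from ``seed``.

    The base endocardial radius, wall thickness, center jitter and slice
    count are drawn once per case; the radius then shrinks by
    ``apex_taper`` per slice toward the apex.  Slices whose tapered
    radius would fall below 1 px are dropped with a warning.
    """
    rng = np.random.default_rng(seed)
    n = config.n_slices
    if n is None:
        lo, hi = config.n_slices_range
        n = int(rng.integers(lo, hi + 1))
    base_r = float(rng.uniform(*config.endo_radius_px))
    wall = float(rng.uniform(*config.wall_thickness_px))
    mid = (config.image_size - 1) / 2.0
    jitter = rng.uniform(-config.center_jitter_px, config.center_jitter_px, size=2)
    center = (mid + float(jitter[0]), mid + float(jitter[1]))
    wobble_phase = float(rng.uniform(0, 2 * np.pi))

    case = PhantomCase(case_id=case_id, config=config)
    kept = 0
    for k in range(n):
        radius = base_r * config.apex_taper**k
        if radius * config.es_scale < 1.0:
            warnings.warn(
                f"{case_id}: apex taper drove slice {k} endo radius below 1 px; "
                f"truncating case at {kept} slices"
            )
            break
        kept += 1
        for phase in ("ED", "ES"):
            case.slices.append(
                generate_slice(config, center, radius, wall, phase, rng,
                               slice_index=k, wobble_phase=wobble_phase)
            )
    return case


# ---------------------------------------------------------------------------
# dataset I/O: 16-bit PNG (or NIfTI volumes), manifest table, contour lists


def _to_uint16(image: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(image), 0, 65535).astype(np.uint16)


def write_mask_png(mask: np.ndarray, path) -> None:
    iio.imwrite(str(path), mask.astype(np.uint16))


def read_mask_png(path) -> np.ndarray:
    return np.asarray(iio.imread(str(path))) > 0


def write_image_png(image: np.ndarray, path) -> None:
    iio.imwrite(str(path), _to_uint16(image))


def read_image_png(path) -> np.ndarray:
    return np.asarray(iio.imread(str(path))).astype(np.float64)


def write_contour_txt(points_xy: np.ndarray, path) -> None:
    """MICCAI-style contour list: one 'x y' float pair per line."""
    np.savetxt(str(path), np.asarray(points_xy, dtype=float), fmt="%.3f")


def read_contour_txt(path) -> np.ndarray:
    pts = np.loadtxt(str(path), dtype=float)
    return pts.reshape(-1, 2)


def generate_dataset(
    config: PhantomConfig,
    n_cases: int,
    seed: int,
    out_dir,
    overwrite: bool = False,
    fmt: str = "png",
) -> pd.DataFrame:
    """Write ``n_cases`` phantom cases plus a manifest to ``out_dir``.

    The manifest (manifest.csv) has one row per slice per phase with the
    file paths, acquisition metadata (pixel spacing, slice thickness)
    and the true center/radii as provenance columns.
    """
    from .metrics import mask_to_contour  # local import to avoid a cycle

    out_dir = Path(out_dir)
    manifest_path = out_dir / "manifest.csv"
    if manifest_path.exists() and not overwrite:
        raise FileExistsError(
            f"{manifest_path} already exists; pass overwrite=True to replace it"
        )
    out_dir.mkdir(parents=True, exist_ok=True)
    if fmt not in ("png", "nifti"):
        raise ValueError("fmt must be 'png' or 'nifti'")

    master = np.random.default_rng(seed)
    case_seeds = master.integers(0, 2**31 - 1, size=n_cases)
    rows = []
    for i, cseed in enumerate(case_seeds):
        case_id = f"case{i:03d}"
        case = generate_case(config, int(cseed), case_id=case_id)
        cdir = out_dir / case_id
        cdir.mkdir(exist_ok=True)
        if fmt == "nifti":
            _write_case_nifti(case, cdir, config)
        for rec in case.slices:
            stem = f"{rec.phase}_{rec.slice_index:02d}"
            row = {
                "case": case_id,
                "slice": rec.slice_index,
                "phase": rec.phase,
                "pixel_spacing_mm": config.pixel_spacing_mm,
                "slice_thickness_mm": config.slice_thickness_mm,
                "true_center_row": rec.center[0],
                "true_center_col": rec.center[1],
                "true_endo_radius_px": rec.endo_radius_px,
                "true_epi_radius_px": rec.epi_radius_px,
            }
            if fmt == "png":
                img_p = cdir / f"{stem}.png"
                endo_p = cdir / f"{stem}_endo_mask.png"
                epi_p = cdir / f"{stem}_epi_mask.png"
                write_image_png(rec.image, img_p)
                write_mask_png(rec.endo_mask, endo_p)
                write_mask_png(rec.epi_mask, epi_p)
                row.update(
                    image=str(img_p.relative_to(out_dir)),
                    endo_mask=str(endo_p.relative_to(out_dir)),
                    epi_mask=str(epi_p.relative_to(out_dir)),
                )
            for structure, mask in (("endo", rec.endo_mask), ("epi", rec.epi_mask)):
                cont = mask_to_contour(mask, spacing=config.pixel_spacing_mm)
                cont_p = cdir / f"{stem}_{structure}_contour.txt"
                write_contour_txt(cont.points, cont_p)
                row[f"{structure}_contour"] = str(cont_p.relative_to(out_dir))
            rows.append(row)
    manifest = pd.DataFrame(rows)
    manifest.to_csv(manifest_path, index=False)
    return manifest


def _write_case_nifti(case: PhantomCase, cdir: Path, config: PhantomConfig) -> None:
    import nibabel as nib

    for phase in ("ED", "ES"):
        recs = case.phase_slices(phase)
        for name, arr in (
            ("image", np.stack([r.image for r in recs], axis=-1)),
            ("endo_mask", np.stack([r.endo_mask for r in recs], axis=-1).astype(np.uint8)),
            ("epi_mask", np.stack([r.epi_mask for r in recs], axis=-1).astype(np.uint8)),
        ):
            affine = np.diag([config.pixel_spacing_mm, config.pixel_spacing_mm,
                              config.slice_thickness_mm, 1.0])
            nib.save(nib.Nifti1Image(np.asarray(arr, dtype=np.float32), affine),
                     str(cdir / f"{phase}_{name}.nii"))


def load_slice(out_dir, row: pd.Series) -> SliceRecord:
    """Rehydrate one manifest row (PNG datasets)."""
    out_dir = Path(out_dir)
    return SliceRecord(
        image=read_image_png(out_dir / row["image"]),
        endo_mask=read_mask_png(out_dir / row["endo_mask"]),
        epi_mask=read_mask_png(out_dir / row["epi_mask"]),
        phase=row["phase"],
        slice_index=int(row["slice"]),
        center=(float(row["true_center_row"]), float(row["true_center_col"])),
        endo_radius_px=float(row["true_endo_radius_px"]),
        epi_radius_px=float(row["true_epi_radius_px"]),
    )
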