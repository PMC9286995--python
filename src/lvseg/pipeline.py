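"""End-to-end phantom workflow: simulate -> crop -> augment -> train ->
predict -> evaluate -> clinical.

Every run directory contains the exact configuration that produced it
(config.yaml), per-stage manifests as delimited text, and stages are
skipped when their outputs already exist unless forced, so a run is
reproducible and idempotent.  One global seed deterministically derives
per-stage seeds.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clinical as clin
from . import metrics as met
from .augment import augment_tenfold
from .model import ArchConfig, build_model, load_checkpoint, predict, save_checkpoint
from .phantom import (
    PhantomConfig,
    generate_dataset,
    read_image_png,
    read_mask_png,
    write_contour_txt,
    write_image_png,
    write_mask_png,
)
from .roi import crop_roi, locate_lv_center, paste_back
from .train import TrainConfig, train

log = logging.getLogger("lvseg")

STAGES = ("simulate", "crop", "augment", "train", "predict", "evaluate", "clinical")


@dataclass
class RunConfig:
    """Merged configuration of a full pipeline run."""

    out_dir: str = "runs/phantom"
    seed: int = 0
    n_train_cases: int = 4
    n_val_cases: int = 1
    n_test_cases: int = 2
    roi_size: int = 128
    roi_k: int = 3
    gap_mm: float = 0.0
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    arch: ArchConfig = field(default_factory=ArchConfig)
    train: TrainConfig = field(default_factory=TrainConfig)

    def __post_init__(self):
        if self.arch.input_size != self.roi_size:
            raise ValueError(
                f"arch.input_size ({self.arch.input_size}) must equal roi_size "
                f"({self.roi_size})"
            )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key, sub in (("phantom", PhantomConfig), ("arch", ArchConfig),
                         ("train", TrainConfig)):
            if key in d and isinstance(d[key], dict):
                sub_d = dict(d[key])
                if key == "phantom":
                    for tup in ("n_slices_range", "endo_radius_px", "wall_thickness_px"):
                        if tup in sub_d and isinstance(sub_d[tup], list):
                            sub_d[tup] = tuple(sub_d[tup])
                d[key] = sub(**sub_d)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)


def stage_seed(seed: int, stage: str, index: int = 0) -> int:
    """Deterministic per-stage seed below 2^31 derived from the global seed."""
    ss = np.random.SeedSequence([seed, STAGES.index(stage), index])
    return int(ss.generate_state(1)[0] % (2**31))


def _done(marker: Path) -> bool:
    return marker.exists()


# ---------------------------------------------------------------------------
# stages


def stage_simulate(cfg: RunConfig, run_dir: Path, force: bool) -> None:
    for split, n in (("train", cfg.n_train_cases), ("val", cfg.n_val_cases),
                     ("test", cfg.n_test_cases)):
        d = run_dir / "data" / split
        if _done(d / "manifest.csv") and not force:
            log.info("simulate[%s]: cached", split)
            continue
        generate_dataset(cfg.phantom, n, stage_seed(cfg.seed, "simulate",
                                                    ("train", "val", "test").index(split)),
                         d, overwrite=True)


def stage_crop(cfg: RunConfig, run_dir: Path, force: bool) -> None:
    for split in ("train", "val", "test"):
        src = run_dir / "data" / split
        dst = run_dir / "roi" / split
        if _done(dst / "manifest.csv") and not force:
            log.info("crop[%s]: cached", split)
            continue
        dst.mkdir(parents=True, exist_ok=True)
        manifest = pd.read_csv(src / "manifest.csv")
        rows = []
        for case_id, grp in manifest.groupby("case", sort=True):
            stack = [read_image_png(src / p) for p in grp["image"]]
            center = locate_lv_center(stack, k=cfg.roi_k)
            (dst / case_id).mkdir(exist_ok=True)
            for _, row in grp.iterrows():
                img = read_image_png(src / row["image"])
                res = crop_roi(img, center, size=cfg.roi_size)
                stem = f"{row['phase']}_{row['slice']:02d}"
                out_row = row.to_dict()
                out_row.update(offset_row=res.offset[0], offset_col=res.offset[1],
                               center_row=center[0], center_col=center[1])
                p_img = dst / case_id / f"{stem}.png"
                write_image_png(res.roi, p_img)
                out_row["roi_image"] = str(p_img.relative_to(dst))
                for structure in ("endo", "epi"):
                    m = read_mask_png(src / row[f"{structure}_mask"])
                    mroi = m[res.offset[0]:res.offset[0] + cfg.roi_size,
                             res.offset[1]:res.offset[1] + cfg.roi_size]
                    p_m = dst / case_id / f"{stem}_{structure}_mask.png"
                    write_mask_png(mroi, p_m)
                    out_row[f"roi_{structure}_mask"] = str(p_m.relative_to(dst))
                rows.append(out_row)
        pd.DataFrame(rows).to_csv(dst / "manifest.csv", index=False)


def stage_augment(cfg: RunConfig, run_dir: Path, force: bool) -> None:
    src = run_dir / "roi" / "train"
    dst = run_dir / "augmented"
    if _done(dst / "manifest.csv") and not force:
        log.info("augment: cached")
        return
    dst.mkdir(parents=True, exist_ok=True)
    manifest = pd.read_csv(src / "manifest.csv")
    rows = []
    for _, row in manifest.iterrows():
        img = read_image_png(src / row["roi_image"])
        endo = read_mask_png(src / row["roi_endo_mask"]).astype(np.uint8)
        epi = read_mask_png(src / row["roi_epi_mask"]).astype(np.uint8)
        # the same operator must transform image and both masks
        aug_endo = augment_tenfold(img, endo)
        aug_epi = augment_tenfold(img, epi)
        case_dir = dst / row["case"]
        case_dir.mkdir(exist_ok=True)
        for pe, pp in zip(aug_endo, aug_epi):
            stem = f"{row['phase']}_{row['slice']:02d}_{pe.tag}"
            p_img = case_dir / f"{stem}.png"
            p_endo = case_dir / f"{stem}_endo_mask.png"
            p_epi = case_dir / f"{stem}_epi_mask.png"
            write_image_png(pe.image, p_img)
            write_mask_png(pe.mask.astype(bool), p_endo)
            write_mask_png(pp.mask.astype(bool), p_epi)
            rows.append({
                "case": row["case"], "slice": row["slice"], "phase": row["phase"],
                "tag": pe.tag,
                "roi_image": str(p_img.relative_to(dst)),
                "roi_endo_mask": str(p_endo.relative_to(dst)),
                "roi_epi_mask": str(p_epi.relative_to(dst)),
            })
    pd.DataFrame(rows).to_csv(dst / "manifest.csv", index=False)


def _load_pairs(base: Path, manifest: pd.DataFrame, target: str):
    return [
        (read_image_png(base / r["roi_image"]),
         read_mask_png(base / r[f"roi_{target}_mask"]))
        for _, r in manifest.iterrows()
    ]


def stage_train(cfg: RunConfig, run_dir: Path, force: bool) -> None:
    aug = run_dir / "augmented"
    val = run_dir / "roi" / "val"
    mdir = run_dir / "models"
    mdir.mkdir(parents=True, exist_ok=True)
    train_manifest = pd.read_csv(aug / "manifest.csv")
    val_manifest = pd.read_csv(val / "manifest.csv")
    for target in ("endo", "epi"):
        ckpt = mdir / f"model_{target}.npz"
        if _done(ckpt) and not force:
            log.info("train[%s]: cached", target)
            continue
        tcfg = dataclasses.replace(cfg.train, target=target,
                                   seed=stage_seed(cfg.seed, "train",
                                                   ("endo", "epi").index(target)))
        acfg = dataclasses.replace(cfg.arch, seed=tcfg.seed)
        model = build_model(acfg)
        t0 = time.time()
        model, history = train(model, _load_pairs(aug, train_manifest, target),
                               _load_pairs(val, val_manifest, target), tcfg)
        log.info("train[%s]: %d epochs in %.1fs, best val dice %.4f", target,
                 tcfg.n_epochs, time.time() - t0,
                 max(r.val_dice for r in history.records))
        save_checkpoint(model, ckpt)
        history.to_frame().to_csv(mdir / f"history_{target}.csv", index=False)


def stage_predict(cfg: RunConfig, run_dir: Path, force: bool) -> None:
    src = run_dir / "roi" / "test"
    dst = run_dir / "predictions"
    if _done(dst / "manifest.csv") and not force:
        log.info("predict: cached")
        return
    dst.mkdir(parents=True, exist_ok=True)
    manifest = pd.read_csv(src / "manifest.csv")
    models = {t: load_checkpoint(run_dir / "models" / f"model_{t}.npz")
              for t in ("endo", "epi")}
    frame_shape = (cfg.phantom.image_size, cfg.phantom.image_size)
    rows = []
    for _, row in manifest.iterrows():
        img = read_image_png(src / row["roi_image"])
        case_dir = dst / row["case"]
        case_dir.mkdir(exist_ok=True)
        out_row = {"case": row["case"], "slice": row["slice"], "phase": row["phase"],
                   "pixel_spacing_mm": row["pixel_spacing_mm"],
                   "slice_thickness_mm": row["slice_thickness_mm"]}
        stem = f"{row['phase']}_{row['slice']:02d}"
        for target, model in models.items():
            _, mask = predict(model, img)
            full = paste_back(mask, (int(row["offset_row"]), int(row["offset_col"])),
                              frame_shape)
            p_m = case_dir / f"{stem}_{target}_pred.png"
            write_mask_png(full, p_m)
            out_row[f"pred_{target}_mask"] = str(p_m.relative_to(dst))
            if full.any():
                cont = met.mask_to_contour(full, spacing=row["pixel_spacing_mm"])
                p_c = case_dir / f"{stem}_{target}_pred_contour.txt"
                write_contour_txt(cont.points, p_c)
                out_row[f"pred_{target}_contour"] = str(p_c.relative_to(dst))
        rows.append(out_row)
    pd.DataFrame(rows).to_csv(dst / "manifest.csv", index=False)


def stage_evaluate(cfg: RunConfig, run_dir: Path, force: bool) -> pd.DataFrame:
    report_path = run_dir / "report.csv"
    if _done(report_path) and not force:
        log.info("evaluate: cached")
        return pd.read_csv(report_path)
    pred = pd.read_csv(run_dir / "predictions" / "manifest.csv")
    gt = pd.read_csv(run_dir / "data" / "test" / "manifest.csv")
    merged = pred.merge(gt, on=["case", "slice", "phase"], suffixes=("", "_gt"))
    rows = []
    for structure in ("endo", "epi"):
        case_metrics = []
        for case_id, grp in merged.groupby("case", sort=True):
            grp = grp.sort_values(["phase", "slice"])
            preds = [read_mask_png(run_dir / "predictions" / p)
                     for p in grp[f"pred_{structure}_mask"]]
            gts = [read_mask_png(run_dir / "data" / "test" / p)
                   for p in grp[f"{structure}_mask"]]
            cm = met.evaluate_case(preds, gts, float(grp["pixel_spacing_mm"].iloc[0]))
            case_metrics.append(cm)
            rows.append({"structure": structure, "case": case_id,
                         "pgc_percent": round(cm.pgc_percent, 4),
                         "mean_dm": None if cm.mean_dm_of_good is None
                         else round(cm.mean_dm_of_good, 6),
                         "mean_apd_mm": None if cm.mean_apd_of_good is None
                         else round(cm.mean_apd_of_good, 6),
                         "n_slices": cm.n_slices, "n_good": cm.n_good})
        summary = met.summarize(case_metrics)
        rows.append({"structure": structure, "case": "MEAN",
                     "pgc_percent": round(summary.pgc_mean, 4),
                     "mean_dm": round(summary.dm_mean, 6),
                     "mean_apd_mm": round(summary.apd_mean, 6),
                     "n_slices": "", "n_good": ""})
        rows.append({"structure": structure, "case": "STD",
                     "pgc_percent": round(summary.pgc_sd, 4),
                     "mean_dm": round(summary.dm_sd, 6),
                     "mean_apd_mm": round(summary.apd_sd, 6),
                     "n_slices": "", "n_good": ""})
    report = pd.DataFrame(rows)
    report.to_csv(report_path, index=False)
    return report


def stage_clinical(cfg: RunConfig, run_dir: Path, force: bool) -> pd.DataFrame:
    out_path = run_dir / "clinical.csv"
    if _done(out_path) and not force:
        log.info("clinical: cached")
        return pd.read_csv(out_path)
    pred = pd.read_csv(run_dir / "predictions" / "manifest.csv")
    gt = pd.read_csv(run_dir / "data" / "test" / "manifest.csv")
    merged = pred.merge(gt, on=["case", "slice", "phase"], suffixes=("", "_gt"))
    rows = []
    autos, manuals = {"lvm": [], "ef": []}, {"lvm": [], "ef": []}
    for case_id, grp in merged.groupby("case", sort=True):
        spacing = float(grp["pixel_spacing_mm"].iloc[0])
        thickness = float(grp["slice_thickness_mm"].iloc[0])

        def stacks(prefix, root):
            ed = grp[grp["phase"] == "ED"].sort_values("slice")
            es = grp[grp["phase"] == "ES"].sort_values("slice")
            return (
                [read_mask_png(root / p) for p in ed[f"{prefix}endo_mask"]],
                [read_mask_png(root / p) for p in es[f"{prefix}endo_mask"]],
                [read_mask_png(root / p) for p in ed[f"{prefix}epi_mask"]],
            )

        manual = clin.clinical_indices(*stacks("", run_dir / "data" / "test"),
                                       spacing, thickness, cfg.gap_mm)
        # an undertrained model can emit non-physiological volumes
        # (epi < endo, or an empty ED stack); flag instead of aborting
        try:
            auto = clin.clinical_indices(*stacks("pred_", run_dir / "predictions"),
                                         spacing, thickness, cfg.gap_mm)
            auto_lvm, auto_ef = auto.lvm_g, auto.ef_percent
            physiological = True
        except ValueError:
            auto = None
            auto_lvm = auto_ef = float("nan")
            physiological = False
        rows.append({"case": case_id,
                     "lvm_auto_g": round(auto_lvm, 3),
                     "lvm_manual_g": round(manual.lvm_g, 3),
                     "ef_auto_percent": round(auto_ef, 3),
                     "ef_manual_percent": round(manual.ef_percent, 3),
                     "v_end_ed_auto_ml": round(auto.v_end_ed_ml, 3) if auto else float("nan"),
                     "v_end_ed_manual_ml": round(manual.v_end_ed_ml, 3),
                     "physiological": physiological})
        if physiological:
            autos["lvm"].append(auto_lvm)
            manuals["lvm"].append(manual.lvm_g)
            autos["ef"].append(auto_ef)
            manuals["ef"].append(manual.ef_percent)
    table = pd.DataFrame(rows)
    table.to_csv(out_path, index=False)
    if len(autos["lvm"]) >= 3:
        agr = {name: vars(clin.agreement(autos[name], manuals[name]))
               for name in ("lvm", "ef")}
        with open(run_dir / "agreement.yaml", "w") as fh:
            yaml.safe_dump(agr, fh)
    return table


# ---------------------------------------------------------------------------


def run_pipeline(cfg: RunConfig, force: bool = False) -> Path:
    """Execute all stages in order; halts with the stage name on failure."""
    run_dir = Path(cfg.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(run_dir / "config.yaml")
    stage_fns = {
        "simulate": stage_simulate, "crop": stage_crop, "augment": stage_augment,
        "train": stage_train, "predict": stage_predict,
        "evaluate": stage_evaluate, "clinical": stage_clinical,
    }
    for name in STAGES:
        t0 = time.time()
        try:
            stage_fns[name](cfg, run_dir, force)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        log.info("stage %s finished in %.1fs", name, time.time() - t0)
    return run_dir
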