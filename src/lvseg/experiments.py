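"""Self-contained desk-scale benchmark experiments on the phantom.

These functions wire the phantom, ROI, augmentation, training and
evaluation stages into small, fully seeded experiments: a learning
capability benchmark (can a tiny improved network segment held-out
phantom slices?) and a per-epoch timing comparison between the
depthwise-separable network and its standard-convolution twin.

Study conditions are fixed here rather than passed around: 96 px
phantom frames whose 64 px ROI plays the role of the 128 px ROI used on
real acquisitions, a 3-level improved network with 8 base channels, 128
ten-fold-augmented training slices, 32 held-out validation slices and a
linear learning-rate decay over the run.
"""

from __future__ import annotations

import dataclasses
import time

import numpy as np

from .augment import augment_tenfold
from .metrics import evaluate_case, summarize
from .model import ArchConfig, build_model, predict
from .phantom import PhantomConfig, generate_case
from .roi import crop_roi, locate_lv_center
from .train import TrainConfig, train, validation_dice

BENCH_PHANTOM = PhantomConfig(
    image_size=96,
    endo_radius_px=(10.0, 16.0),
    wall_thickness_px=(4.0, 7.0),
    center_jitter_px=6.0,
    wobble_amp_px=1.0,
)

BENCH_ARCH = ArchConfig(input_size=64, n_levels=3, base_channels=8)

ROI_SIZE = 64

# the timing benchmark runs channel-heavy (below): a proportionally scaled
# phantom whose 32 px ROI still contains the full epicardium
TIMING_PHANTOM = PhantomConfig(
    image_size=64,
    endo_radius_px=(5.0, 8.0),
    wall_thickness_px=(2.0, 3.5),
    center_jitter_px=3.0,
    wobble_amp_px=0.5,
)

TIMING_ARCH = ArchConfig(input_size=32, n_levels=3, base_channels=64)


def _case_roi_pairs(seed: int, target: str = "endo",
                    phantom: PhantomConfig = BENCH_PHANTOM,
                    roi_size: int = ROI_SIZE):
    """ROI/mask pairs of one seeded case, localized from its own cine stack."""
    case = generate_case(phantom, seed)
    center = locate_lv_center([s.image for s in case.slices])
    pairs = []
    for s in case.slices:
        res = crop_roi(s.image, center, roi_size)
        r0, c0 = res.offset
        mask = getattr(s, f"{target}_mask")[r0:r0 + roi_size, c0:c0 + roi_size]
        pairs.append((res.roi, mask.astype(np.uint8)))
    return pairs


def build_benchmark_sets(seed: int, n_train: int = 128, n_val: int = 32,
                         n_test_cases: int = 2, target: str = "endo",
                         phantom: PhantomConfig = BENCH_PHANTOM,
                         roi_size: int = ROI_SIZE):
    """Augmented training slices, held-out validation slices, test cases."""
    rng = np.random.default_rng(seed)
    train_seeds, val_seeds, test_seeds = (
        [int(v) for v in rng.integers(0, 2**31 - 1, size=k)] for k in (4, 4, n_test_cases)
    )
    base = []
    for s in train_seeds:
        base += _case_roi_pairs(s, target, phantom, roi_size)
    base = base[: max(1, -(-n_train // 10))]  # ceil: ten-fold then truncate
    train_set = []
    for img, m in base:
        train_set += [(p.image, p.mask) for p in augment_tenfold(img, m)]
    train_set = train_set[:n_train]
    val_set = []
    for s in val_seeds:
        val_set += _case_roi_pairs(s, target, phantom, roi_size)
    val_set = val_set[:n_val]
    test_cases = [_case_roi_pairs(s, target, phantom, roi_size) for s in test_seeds]
    return train_set, val_set, test_cases


def learning_capability(seed: int, n_epochs: int = 12) -> dict:
    """Train the tiny improved network and evaluate held-out phantoms.

    Returns held-out mean dice, per-case PGC / DM / APD summaries on the
    test cases, and the sizes used.
    """
    train_set, val_set, test_cases = build_benchmark_sets(seed)
    arch = dataclasses.replace(BENCH_ARCH, seed=seed % (2**31))
    tcfg = TrainConfig(n_epochs=n_epochs, lr_end_epoch=n_epochs, batch_size=16,
                       seed=seed % (2**31))
    model = build_model(arch)
    model, history = train(model, train_set, val_set, tcfg)
    heldout = validation_dice(model, val_set)
    case_metrics = []
    for pairs in test_cases:
        preds = [predict(model, img)[1] for img, _ in pairs]
        case_metrics.append(evaluate_case(preds, [m for _, m in pairs],
                                          BENCH_PHANTOM.pixel_spacing_mm))
    s = summarize(case_metrics)
    return {
        "heldout_dice": heldout,
        "pgc_percent": s.pgc_mean,
        "mean_dm": s.dm_mean,
        "mean_apd_mm": s.apd_mean,
        "n_train": len(train_set),
        "n_val": len(val_set),
        "n_test_slices": sum(len(p) for p in test_cases),
        "history": history,
    }


def epoch_time_comparison(seed: int, n_epochs: int = 1, n_samples: int = 32) -> dict:
    """Seconds of compute per training epoch: separable vs standard twin.

    Both networks train on the identical data with identical settings;
    only conv_type differs.  The comparison runs channel-heavy (32 px
    inputs, 64 base channels): the separable block's saving is in
    convolution arithmetic, so at toy widths — where width-independent
    bookkeeping and data movement dominate the step — epoch times say
    nothing about the convolution cost.  Epochs are timed with process
    CPU time, which for this single-process engine equals wall-clock up
    to scheduler jitter; first-call compilation is excluded.
    """
    from .model import normalize_image
    from .nn import autograd as ag
    from .nn.autograd import Tensor, no_grad
    from .nn.layers import DTYPE
    from .nn.optim import Adam

    train_set, val_set, _ = build_benchmark_sets(
        seed, n_train=n_samples, n_val=8, n_test_cases=1,
        phantom=TIMING_PHANTOM, roi_size=TIMING_ARCH.input_size)
    variants = ("depthwise_separable", "standard")
    batch = 16
    x_all = np.stack([normalize_image(i) for i, _ in train_set]).astype(DTYPE)[:, None]
    y_all = np.stack([np.asarray(m) > 0 for _, m in train_set]).astype(np.int64)
    x_val = np.stack([normalize_image(i) for i, _ in val_set]).astype(DTYPE)[:, None]

    models, opts = {}, {}
    for ct in variants:
        arch = dataclasses.replace(TIMING_ARCH, conv_type=ct, seed=seed % (2**31))
        models[ct] = build_model(arch).train()
        opts[ct] = Adam(models[ct].parameters(), lr=1e-3)

    def train_step(ct, lo, hi):
        logits = models[ct].forward(Tensor(x_all[lo:hi]))
        loss = ag.softmax_cross_entropy(logits, y_all[lo:hi])
        models[ct].zero_grad()
        loss.backward()
        opts[ct].step()

    def val_pass(ct):
        models[ct].eval()
        with no_grad():
            models[ct].forward_probs(Tensor(x_val))
        models[ct].train()

    # warm-up: first-call JIT/allocator effects stay outside the timed loop
    for ct in variants:
        train_step(ct, 0, batch)
        val_pass(ct)

    # the variants alternate batch by batch inside one loop, so slow
    # machine phases (frequency scaling, contention) hit both equally;
    # one epoch = all training batches plus the validation forward pass,
    # and the best-of-five epochs per variant filters throttled windows
    out = {ct: np.inf for ct in variants}
    for _ in range(n_epochs * 5):
        rep = {ct: 0.0 for ct in variants}
        for lo in range(0, len(train_set), batch):
            for ct in variants:
                t0 = time.process_time()
                train_step(ct, lo, lo + batch)
                rep[ct] += time.process_time() - t0
        for ct in variants:
            t0 = time.process_time()
            val_pass(ct)
            rep[ct] += time.process_time() - t0
            out[ct] = min(out[ct], rep[ct])
    out["ratio"] = out["depthwise_separable"] / out["standard"]
    return out
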