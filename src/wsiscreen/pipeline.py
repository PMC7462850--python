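"""Desk-scale end-to-end experiments.

These runners wire the whole pipeline together on synthetic cohorts small
enough for a single CPU: generate a multi-center cohort, train a reduced
U-Net on sparsely annotated patches, produce tumor-likelihood maps for
held-out slides, score them with T07, and evaluate the slide-level ROC.
The normalization experiment additionally re-renders the held-out slides
under a second scanner style (the re-scanning scenario), trains a small
cycle-GAN between the styles, and measures the AUC recovery and
domain-gap reduction that normalization buys.

Problem sizes (1024-px slides, 32-px patches, depth-3/base-8 U-Net) are
the package's screening-study defaults; every knob is an argument.
"""

from __future__ import annotations

import numpy as np

from .evaluation import bootstrap_ci, roc_auc
from .inference import derive_tumor_map, predict_slide
from .patch_dataset import (
    AugmentationConfig,
    augment,
    extract_patches,
    load_patch,
    make_target,
    plan_balanced_sampling,
)
from .segmentation_models import TrainConfig, UNetConfig, build_unet, train
from .slide_classification import t07
from .style_normalization import (
    CycleGanConfig,
    domain_gap,
    normalize_slide,
    sample_training_patches,
    train_cyclegan,
)
from .synthetic_data import CenterStyle, cohort_specs, generate_slide, splitmix64
from .wsi_io import compute_tissue_mask

__all__ = [
    "default_styles",
    "run_screening_experiment",
    "run_normalization_experiment",
]


def default_styles() -> tuple[CenterStyle, CenterStyle]:
    """The two scanner styles of the synthetic multi-center study.

    Style A plays the development-set scanner (near-neutral rendering);
    style B is a second vendor with a washed-out rendering: hue-rotated,
    strongly desaturated, brighter, lower-contrast and markedly blurrier.
    """
    style_a = CenterStyle(style_id="scanner_a", hue_shift=0.0, saturation_scale=1.0,
                          brightness_scale=1.0, contrast_scale=1.0,
                          blur_sigma=0.0, noise_sigma=2.0)
    style_b = CenterStyle(style_id="scanner_b", hue_shift=40.0, saturation_scale=0.5,
                          brightness_scale=1.2, contrast_scale=0.7,
                          blur_sigma=0.5, noise_sigma=1.0)
    return style_a, style_b


def _cohort_with_both_classes(n, prevalence, style, seed, size):
    """Slide specs whose label draw contains both classes (reseeded if not)."""
    for bump in range(100):
        pairs = cohort_specs(n, prevalence, [style], (seed + bump) % 2**31, size=size)
        labels = [s.label for s, _ in pairs]
        if "cancer" in labels and "normal" in labels:
            return pairs
    raise RuntimeError("could not draw a two-class cohort")


def _training_patches(pairs, patch_size, stride, max_per_class, rng):
    """Generate slides one at a time and harvest balanced annotated patches."""
    by_class: dict[str, list[np.ndarray]] = {}
    for spec, style in pairs:
        slide, annotations, _ = generate_slide(spec, style)
        records = extract_patches(annotations, patch_size, stride=stride,
                                  slide_id=spec.slide_id)
        for r in records:
            by_class.setdefault(r.class_label, []).append(load_patch(slide, r))

    # class-balancing by augmentation multipliers, then a per-class cap
    counts = {c: len(v) for c, v in by_class.items()}
    aug_cfg = AugmentationConfig()
    from .patch_dataset import PatchRecord  # counts-only records for the planner

    dummy = [PatchRecord(None, 0, 0, patch_size, c) for c, n in counts.items() for _ in range(n)]
    plan = plan_balanced_sampling(dummy, aug_cfg)

    xs, ys = [], []
    for cls, patches in by_class.items():
        mult = plan.get(cls, 1)
        pool = []
        for p in patches:
            pool.append(p)
            for _ in range(mult - 1):
                pool.append(augment(p, aug_cfg, rng))
        if len(pool) > max_per_class:
            keep = rng.choice(len(pool), size=max_per_class, replace=False)
            pool = [pool[i] for i in keep]
        for p in pool:
            xs.append(p.astype(np.float32) / 255.0)
            ys.append(make_target(cls, patch_size))
    order = rng.permutation(len(xs))
    return np.stack(xs)[order], np.stack(ys)[order]


def _score_slides(model, pairs, patch_size, render_style=None):
    """Generate each slide, map it, and return (t07 scores, binary labels)."""
    scores, labels = [], []
    for spec, style in pairs:
        slide, _, label = generate_slide(spec, render_style or style)
        mask = compute_tissue_mask(slide, level=0)
        lmap = predict_slide(model, slide, mask, patch_size)
        scores.append(t07(derive_tumor_map(lmap)))
        labels.append(1 if label == "cancer" else 0)
    return np.asarray(scores), np.asarray(labels)


def run_screening_experiment(seed: int, n_train: int = 40, n_test: int = 20,
                             prevalence: float = 0.25, slide_size: int = 1024,
                             patch_size: int = 32, max_per_class: int = 350,
                             max_epochs: int = 20, n_boot: int = 0) -> dict:
    """Train the reduced U-Net on style-A slides and score held-out style-A slides.

    Returns a dict with the trained model, the held-out slide specs, T07
    scores and labels, and the slide-level AUC (plus a bootstrap CI when
    ``n_boot`` > 0).
    """
    style_a, style_b = default_styles()
    rng = np.random.default_rng(splitmix64(seed, 11) % 2**31)

    train_pairs = _cohort_with_both_classes(n_train, prevalence, style_a,
                                            splitmix64(seed, 21) % 2**31, slide_size)
    test_pairs = _cohort_with_both_classes(n_test, prevalence, style_a,
                                           splitmix64(seed, 22) % 2**31, slide_size)

    x, y = _training_patches(train_pairs, patch_size, stride=patch_size,
                             max_per_class=max_per_class, rng=rng)
    n_val = max(8, int(0.15 * len(x)))
    x_tr, y_tr, x_va, y_va = x[n_val:], y[n_val:], x[:n_val], y[:n_val]

    ucfg = UNetConfig(depth=3, base_filters=8, spatial_dropout=0.1, n_classes=5,
                      input_size=patch_size, seed=splitmix64(seed, 31) % 2**31)
    model = build_unet(ucfg)
    tcfg = TrainConfig(batch_size=8, learning_rate=0.005, momentum=0.9,
                       max_epochs=max_epochs, patience=8, monitor="val_loss",
                       seed=splitmix64(seed, 32) % 2**31)
    model, history = train(model, (x_tr, y_tr), (x_va, y_va), tcfg)

    scores, labels = _score_slides(model, test_pairs, patch_size)
    roc = roc_auc(scores, labels)
    result = {
        "model": model,
        "history": history,
        "patch_size": patch_size,
        "test_pairs": test_pairs,
        "train_pairs": train_pairs,
        "scores": scores,
        "labels": labels,
        "auc": roc.auc,
        "val_dice": history["val_dice"][-1],
    }
    if n_boot:
        result["ci"] = bootstrap_ci(scores, labels, n_boot=n_boot,
                                    seed=splitmix64(seed, 33) % 2**31)
    return result


def run_normalization_experiment(seed: int, screening: dict | None = None,
                                 gan_epochs: int = 60, gan_iters: int = 40,
                                 n_gap_patches: int = 160) -> dict:
    """Cross-scanner evaluation and cycle-GAN recovery.

    Re-renders the screening experiment's held-out slides under scanner
    style B (the re-scanning scenario), scores them with the unchanged
    model (the cross-scanner AUC), trains a small cycle-GAN between the
    two styles, normalizes the style-B slides into the style-A domain,
    and rescores.  Reports the three AUCs and the domain gap before and
    after normalization.
    """
    if screening is None:
        screening = run_screening_experiment(seed)
    style_a, style_b = default_styles()
    model = screening["model"]
    patch_size = screening["patch_size"]
    test_pairs = screening["test_pairs"]
    rng = np.random.default_rng(splitmix64(seed, 41) % 2**31)

    # cross-scanner scoring: same slides, second scanner
    scores_b, labels = _score_slides(model, test_pairs, patch_size,
                                     render_style=style_b)
    auc_cross = roc_auc(scores_b, labels).auc

    gcfg = CycleGanConfig(patch_size=32, epochs=gan_epochs,
                          iterations_per_epoch=gan_iters, batch_size=4,
                          lr=0.0005, lr_decay_every=max(1, gan_epochs // 3),
                          gen_depth=2, gen_filters=12, disc_filters=12,
                          n_slides_per_domain=5,
                          seed=splitmix64(seed, 42) % 2**31)

    # 5 slides per domain: dev style-A slides and re-rendered style-B slides
    dev_pairs = screening["train_pairs"][: gcfg.n_slides_per_domain]
    src_pairs = test_pairs[: gcfg.n_slides_per_domain]
    dom_a_slides, dom_a_masks = [], []   # source: scanner B
    dom_b_slides, dom_b_masks = [], []   # target: scanner A (dev domain)
    src_a_renders = []                   # scanner-A renders of the source slides
    for spec, _ in src_pairs:
        s, _, _ = generate_slide(spec, style_b)
        dom_a_slides.append(s)
        dom_a_masks.append(compute_tissue_mask(s, level=0))
        sa, _, _ = generate_slide(spec, style_a)
        src_a_renders.append(sa)
    for spec, style in dev_pairs:
        s, _, _ = generate_slide(spec, style)
        dom_b_slides.append(s)
        dom_b_masks.append(compute_tissue_mask(s, level=0))

    def _stream(slides, masks):
        def f(stream_rng, n):
            return sample_training_patches(slides, masks, gcfg, stream_rng, n=n)
        return f

    pair = train_cyclegan(_stream(dom_a_slides, dom_a_masks),
                          _stream(dom_b_slides, dom_b_masks), gcfg)

    # style gap with content controlled: the scanner-B slides are re-renders
    # of the same specs, so patches at identical coordinates isolate the
    # style difference (the re-scanning pairing) from slide content
    ps = gcfg.patch_size
    src_list, ref_list = [], []
    for _ in range(n_gap_patches):
        i = int(rng.integers(len(dom_a_slides)))
        mask = dom_a_masks[i].mask
        ys, xs = np.nonzero(mask)
        j = int(rng.integers(ys.size))
        h, w = mask.shape
        cy = int(np.clip(ys[j], ps // 2, h - ps // 2))
        cx = int(np.clip(xs[j], ps // 2, w - ps // 2))
        sl = (slice(cy - ps // 2, cy + ps // 2), slice(cx - ps // 2, cx + ps // 2))
        src_list.append(dom_a_slides[i].level_array(0)[sl])
        ref_list.append(src_a_renders[i].level_array(0)[sl])
    src = np.stack(src_list)
    ref = np.stack(ref_list)
    from .style_normalization import apply_generator

    src_norm = apply_generator(pair.g_ab, src)
    gap_before = domain_gap(src, ref)
    gap_after = domain_gap(src_norm, ref)

    # normalize the cross-scanner slides and rescore
    scores_n = []
    for spec, _ in test_pairs:
        slide, _, _ = generate_slide(spec, style_b)
        mask = compute_tissue_mask(slide, level=0)
        norm = normalize_slide(slide, pair.g_ab, mask, tile_size=gcfg.patch_size,
                               overlap=8)
        nmask = compute_tissue_mask(norm, level=0)
        lmap = predict_slide(model, norm, nmask, patch_size)
        scores_n.append(t07(derive_tumor_map(lmap)))
    scores_n = np.asarray(scores_n)
    auc_norm = roc_auc(scores_n, labels).auc

    return {
        "auc_same": screening["auc"],
        "auc_cross": auc_cross,
        "auc_normalized": auc_norm,
        "gap_before": gap_before,
        "gap_after": gap_after,
        "scores_cross": scores_b,
        "scores_normalized": scores_n,
        "labels": labels,
        "gan": pair,
    }
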