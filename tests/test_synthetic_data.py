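"""Cohort generator: determinism, label statistics, styles, separability."""

import numpy as np
import pytest
from skimage.color import hsv2rgb, rgb2hsv

from wsiscreen.synthetic_data import (
    TEXTURES,
    CenterStyle,
    SlideSpec,
    apply_center_style,
    cohort_specs,
    generate_cohort,
    generate_slide,
    splitmix64,
)
from wsiscreen.wsi_io import CLASSES, read_annotations, read_slide


def test_same_spec_and_seed_bit_identical():
    spec = SlideSpec("s", width=1024, height=1024, label="cancer", seed=5)
    a, _, _ = generate_slide(spec, CenterStyle())
    b, _, _ = generate_slide(spec, CenterStyle())
    np.testing.assert_array_equal(a.level_array(0), b.level_array(0))
    np.testing.assert_array_equal(a.level_array(1), b.level_array(1))


def test_normal_slide_has_no_cancer_annotation(normal_slide_bundle):
    ann = normal_slide_bundle["annotations"]
    assert all(r.class_label != "cancer" for r in ann)
    assert (normal_slide_bundle["truth"] != CLASSES.index("cancer")).all()


def test_cancer_slide_has_cancer_annotation(cancer_slide_bundle):
    assert any(r.class_label == "cancer" for r in cancer_slide_bundle["annotations"])


def test_slide_too_small_rejected():
    with pytest.raises(ValueError):
        SlideSpec("s", width=512, height=512)


def test_cohort_labels_replay_rng_draws():
    """Label assignment is exactly the seeded Bernoulli stream."""
    pairs = cohort_specs(100, 0.25, [CenterStyle()], seed=7, size=1024)
    labels = np.array([s.label == "cancer" for s, _ in pairs])
    expect = np.random.default_rng(7).random(100) < 0.25
    np.testing.assert_array_equal(labels, expect)


def test_cohort_prevalence_within_binomial_error():
    pairs = cohort_specs(200, 0.25, [CenterStyle()], seed=11, size=1024)
    n_cancer = sum(s.label == "cancer" for s, _ in pairs)
    # 50 +/- 4 sd of Binomial(200, 0.25)
    assert abs(n_cancer - 50) <= 4 * np.sqrt(200 * 0.25 * 0.75)
    again = cohort_specs(200, 0.25, [CenterStyle()], seed=11, size=1024)
    assert sum(s.label == "cancer" for s, _ in again) == n_cancer


def test_cohort_validation():
    with pytest.raises(ValueError):
        cohort_specs(0, 0.5, [CenterStyle()], seed=1)
    with pytest.raises(ValueError):
        cohort_specs(5, 0.5, [], seed=1)
    manifest = generate_cohort(4, 1.0, [CenterStyle()], seed=1, size=1024)
    assert (manifest["label"] == "cancer").all()


def test_style_round_robin_assignment():
    styles = [CenterStyle(style_id="a"), CenterStyle(style_id="b")]
    pairs = cohort_specs(6, 0.5, styles, seed=0, size=1024)
    assert [st.style_id for _, st in pairs] == ["a", "b"] * 3


def test_written_cohort_roundtrips(tmp_path):
    manifest = generate_cohort(2, 0.5, [CenterStyle()], seed=3, out_dir=tmp_path, size=1024)
    assert list(manifest.columns) == ["slide_id", "path", "annotation_path",
                                      "label", "center_style_id"]
    slide = read_slide(manifest["path"][0])
    assert slide.n_levels == 2
    assert slide.dimensions == (1024, 1024)
    xml_ann = read_annotations(manifest["annotation_path"][0], "asap_xml")
    gj_ann = read_annotations(str(manifest["annotation_path"][0]).replace(".xml", ".geojson"),
                              "geojson")
    assert [r.class_label for r in xml_ann] == [r.class_label for r in gj_ann]


# ----------------------------------------------------------- center styles

def test_identity_style_bit_identical(rng):
    img = rng.integers(0, 255, (32, 32, 3), dtype=np.uint8)
    out = apply_center_style(img, CenterStyle())
    np.testing.assert_array_equal(out, img)
    assert out is not img


def test_brightness_scaling_linear():
    img = np.full((8, 8, 3), 200, np.uint8)
    out = apply_center_style(img, CenterStyle(style_id="dim", brightness_scale=0.5))
    np.testing.assert_array_equal(out, 100)


def test_hue_rotation_composes_to_identity(rng):
    img = rng.integers(30, 220, (16, 16, 3), dtype=np.uint8)
    style = CenterStyle(style_id="h120", hue_shift=120.0)
    out = img
    for _ in range(3):
        out = apply_center_style(out, style)
    # reference: one 360-degree rotation in HSV space is the identity
    hsv = rgb2hsv(img / 255.0)
    hsv[..., 0] = (hsv[..., 0] + 1.0) % 1.0
    ref = np.clip(np.rint(hsv2rgb(hsv) * 255), 0, 255)
    assert np.abs(out.astype(int) - ref.astype(int)).max() <= 3  # uint8 rounding x3


def test_style_rejects_non_rgb():
    with pytest.raises(ValueError):
        apply_center_style(np.zeros((8, 8)), CenterStyle())


def test_style_scales_must_be_positive():
    with pytest.raises(ValueError):
        CenterStyle(brightness_scale=0.0)


def test_style_effect_exceeds_seed_effect():
    """Two styles on one slide differ more than two seeds under one style."""
    from wsiscreen.style_normalization import domain_gap

    style_a = CenterStyle(style_id="a")
    style_b = CenterStyle(style_id="b", hue_shift=120, brightness_scale=0.8,
                          contrast_scale=1.25, blur_sigma=1.2)
    s1 = SlideSpec("s1", width=1024, height=1024, label="cancer", seed=1)
    s2 = SlideSpec("s2", width=1024, height=1024, label="cancer", seed=2)
    a1, _, _ = generate_slide(s1, style_a)
    a2, _, _ = generate_slide(s2, style_a)
    b1, _, _ = generate_slide(s1, style_b)
    seed_gap = domain_gap(a1.level_array(1), a2.level_array(1))
    style_gap = domain_gap(a1.level_array(1), b1.level_array(1))
    assert style_gap > seed_gap


def test_textures_linearly_separable():
    """A nearest-mean-color patch classifier reads the class structure (> 0.9)."""
    centroids = {c: np.array(TEXTURES[c]["base"], float) for c in CLASSES}
    rng = np.random.default_rng(31)
    spec = SlideSpec("sep", width=1024, height=1024, label="cancer", seed=777)
    slide, ann, _, truth = generate_slide(spec, CenterStyle(), return_truth=True)
    arr = slide.level_array(0).astype(float)
    ys, xs = np.nonzero(truth[8:-8, 8:-8] >= 0)
    picks = rng.choice(ys.size, size=400, replace=False)
    hits = total = 0
    for p in picks:
        y, x = ys[p] + 8, xs[p] + 8
        cls = truth[y, x]
        block = truth[y - 4 : y + 4, x - 4 : x + 4]
        if not (block == cls).all():
            continue  # single-class patches only
        mean = arr[y - 4 : y + 4, x - 4 : x + 4].reshape(-1, 3).mean(axis=0)
        pred = min(centroids, key=lambda c: np.linalg.norm(mean - centroids[c]))
        hits += pred == CLASSES[cls]
        total += 1
    assert total > 50
    assert hits / total > 0.9


def test_annotations_are_sparse_subsets(cancer_slide_bundle):
    """Each annotation covers 30-60% of a tissue region and lies inside it."""
    truth = cancer_slide_bundle["truth"]
    from skimage.draw import polygon as draw_polygon

    for region in cancer_slide_bundle["annotations"]:
        rr, cc = draw_polygon(region.polygon[:, 1], region.polygon[:, 0],
                              shape=truth.shape)
        labels = truth[rr, cc]
        cls_idx = CLASSES.index(region.class_label)
        assert (labels == cls_idx).mean() > 0.99  # annotation inside its region
        region_area = (truth == cls_idx).sum()
        assert rr.size < 0.7 * region_area  # sparse: well below full coverage


def test_splitmix_hash_spreads_and_repeats():
    a = splitmix64(1, 2)
    assert a == splitmix64(1, 2)
    assert a != splitmix64(2, 1)
    assert 0 <= a < 2**63
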