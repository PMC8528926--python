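import numpy as np
import pandas as pd
import pytest

from mitoscreen.image_core import LabelMaps
from mitoscreen.pipeline import (calibrate_from_fields, match_cells_to_truth,
                                 score_field)
from mitoscreen.ratiometric import (ChannelWeight, RatioConfig,
                                    RegionTooSmallError,
                                    calibrate_channel_weight,
                                    channel_intensity_ratio,
                                    classify_objects_by_integrated_ratio,
                                    compute_ratio_map,
                                    detect_red_only_structures, grid_quantify,
                                    puncta_mitophagy_frequency,
                                    quantify_per_cell)
from mitoscreen.synthetic_data import (SceneConfig, generate_field,
                                       generate_object_field,
                                       generate_puncta_field)


def _flat_labelmaps(shape, cells=None):
    z = np.zeros(shape, dtype=np.int32)
    return LabelMaps(nuclei=z, cells=cells if cells is not None
                     else np.ones(shape, dtype=np.int32),
                     mito=np.zeros(shape, dtype=bool))


# --- calibration ----------------------------------------------------------

def test_weight_one_for_balanced_channels(ratio_cfg):
    g = np.full((50, 50), 200.0)
    mask = np.ones((50, 50), dtype=bool)
    w = calibrate_channel_weight([(g, g, mask)], ratio_cfg)
    assert w.w == pytest.approx(1.0)
    assert w.n_calibration_pixels == 2500


def test_weight_halved_for_doubled_red(ratio_cfg):
    g = np.full((50, 50), 100.0)
    w = calibrate_channel_weight([(g, 2 * g, np.ones_like(g, bool))], ratio_cfg)
    assert w.w == pytest.approx(0.5)


def test_weight_recovers_channel_gain(ratio_cfg, seg_cfg):
    cfg = SceneConfig(rng_seed=19, channel_gain=1.7,
                      mitolysosomes_per_cell=0.3)
    field, _ = generate_field(cfg)
    w = calibrate_from_fields([field], seg_cfg, ratio_cfg)
    assert w.w == pytest.approx(1 / 1.7, rel=0.02)


def test_empty_calibration_mask_errors(ratio_cfg):
    g = np.ones((20, 20))
    with pytest.raises(ValueError):
        calibrate_channel_weight([(g, g, np.zeros((20, 20), bool))], ratio_cfg)


def test_bimodal_controls_warn(ratio_cfg):
    g = np.full((40, 40), 100.0)
    r = np.full((40, 40), 100.0)
    r[:16] = 1000.0  # 40% of pixels look strongly red -> low green/red mode
    with pytest.warns(UserWarning, match="bimodal"):
        calibrate_channel_weight([(g, r, np.ones_like(g, bool))], ratio_cfg)


def test_robust_regression_estimator(ratio_cfg):
    rng = np.random.default_rng(0)
    r = rng.uniform(100, 1000, (60, 60))
    g = 0.7 * r + rng.normal(0, 5, (60, 60))
    cfg = RatioConfig(weight_estimator="robust_regression")
    w = calibrate_channel_weight([(g, r, np.ones_like(g, bool))], cfg)
    assert w.w == pytest.approx(0.7, rel=0.02)


# --- ratio map ------------------------------------------------------------

def test_ratio_pixel_values(ratio_cfg):
    g = np.full((10, 10), 80.0)
    r = np.full((10, 10), 80.0)
    rmap = compute_ratio_map(g, r, ChannelWeight(w=1.0, n_calibration_pixels=1),
                             ratio_cfg)
    assert rmap.ratio[5, 5] == pytest.approx(1.0)


def test_ratio_red_dominant_pixel(ratio_cfg):
    # green 40 against weighted red 100 -> 0.4: red more than twice green
    g = np.full((10, 10), 40.0)
    r = np.full((10, 10), 100.0)
    rmap = compute_ratio_map(g, r, ChannelWeight(w=1.0, n_calibration_pixels=1),
                             ratio_cfg)
    assert rmap.ratio[0, 0] == pytest.approx(0.4)
    assert rmap.ratio[0, 0] < ratio_cfg.red_only_threshold


def test_low_intensity_pixels_floored(ratio_cfg):
    g = np.full((20, 20), 50.0)
    r = np.full((20, 20), 500.0)
    r[0, 0] = 0.1  # far below 1% of the 99th percentile
    rmap = compute_ratio_map(g, r, ChannelWeight(w=1.0, n_calibration_pixels=1),
                             ratio_cfg)
    assert not rmap.valid[0, 0]
    assert np.isnan(rmap.ratio[0, 0])


def test_rescale_with_recalibration_leaves_ratio_unchanged(ratio_cfg):
    rng = np.random.default_rng(3)
    g = rng.uniform(50, 500, (40, 40))
    r = rng.uniform(50, 500, (40, 40))
    mask = np.ones((40, 40), bool)
    for gain in (0.5, 2.0, 3.7):
        w1 = calibrate_channel_weight([(g, r, mask)], ratio_cfg)
        w2 = calibrate_channel_weight([(g, gain * r, mask)], ratio_cfg)
        m1 = compute_ratio_map(g, r, w1, ratio_cfg)
        m2 = compute_ratio_map(g, gain * r, w2, ratio_cfg)
        np.testing.assert_allclose(m1.ratio, m2.ratio, rtol=1e-9)


# --- structure detection --------------------------------------------------

def test_pure_yellow_scene_no_structures(ratio_cfg):
    g = np.full((30, 30), 300.0)
    rmap = compute_ratio_map(g, g, ChannelWeight(w=1.0, n_calibration_pixels=1),
                             ratio_cfg)
    out = detect_red_only_structures(rmap, _flat_labelmaps((30, 30)), ratio_cfg)
    assert out == []


def test_structure_above_threshold_not_detected(ratio_cfg):
    g = np.full((30, 30), 300.0)
    r = np.full((30, 30), 300.0)
    r[10:20, 10:20] = 500.0  # ratio 0.6 there
    rmap = compute_ratio_map(g, r, ChannelWeight(w=1.0, n_calibration_pixels=1),
                             ratio_cfg)
    assert detect_red_only_structures(rmap, _flat_labelmaps((30, 30)),
                                      ratio_cfg) == []


def test_planted_structures_recovered_in_their_cells(seg_cfg, ratio_cfg):
    weight = calibrate_from_fields(
        [generate_field(SceneConfig(rng_seed=55, psf_sigma=0.8,
                                    mitolysosomes_per_cell=0.2))[0]],
        seg_cfg, ratio_cfg)
    exact = n_cells = total_est = total_truth = 0
    for seed in (23, 24, 25):
        cfg = SceneConfig(rng_seed=seed, psf_sigma=0.8,
                          mitolysosomes_per_cell=3.0)
        field, truth = generate_field(cfg)
        cells, _, maps = score_field(field, weight, seg_cfg, ratio_cfg)
        mapping = match_cells_to_truth(maps.cells, truth.nuclei_mask)
        est = {c.cell_id: c.n_red_only_structures for c in cells}
        truth_counts = dict(zip(truth.per_cell_truth["cell_id"],
                                truth.per_cell_truth["n_mitolysosomes"]))
        exact += sum(1 for tc, n in truth_counts.items()
                     if est.get(mapping[tc], -1) == n)
        n_cells += len(truth_counts)
        total_est += sum(est.values())
        total_truth += sum(truth_counts.values())
    assert exact / n_cells >= 0.9
    assert abs(total_est - total_truth) <= max(1, 0.1 * total_truth)


# --- per-cell quantification ---------------------------------------------

def test_per_cell_sums(ratio_cfg):
    from mitoscreen.ratiometric import StructureRecord
    cells = np.ones((20, 20), dtype=np.int32)
    maps = _flat_labelmaps((20, 20), cells)
    recs = [StructureRecord(1, 1, 10, 0.3, 1, 1, (5, 5)),
            StructureRecord(2, 1, 15, 0.2, 1, 1, (10, 10))]
    out, n_un = quantify_per_cell(recs, maps)
    assert n_un == 0
    assert out[0].red_only_area_px == 25
    assert out[0].n_red_only_structures == 2


def test_cells_without_structures_get_zeros():
    cells = np.zeros((20, 20), dtype=np.int32)
    cells[:10] = 1
    cells[10:] = 2
    maps = _flat_labelmaps((20, 20), cells)
    out, _ = quantify_per_cell([], maps)
    assert len(out) == 2
    assert all(c.red_only_area_px == 0 for c in out)


def test_unassigned_structures_counted(ratio_cfg):
    from mitoscreen.ratiometric import StructureRecord
    maps = _flat_labelmaps((20, 20), np.ones((20, 20), dtype=np.int32))
    recs = [StructureRecord(1, 0, 10, 0.3, 1, 1, (5, 5))]
    with pytest.warns(UserWarning):
        out, n_un = quantify_per_cell(recs, maps)
    assert n_un == 1
    assert out[0].n_red_only_structures == 0


# --- gain invariance + monotonicity properties ----------------------------

def test_gain_invariance_red_only_area(seg_cfg, ratio_cfg, clean_field):
    field, _ = clean_field
    areas = {}
    for gain in (0.5, 1.0, 2.0):
        scaled = field.__class__(
            nuclei=field.nuclei, green=field.green,
            red=np.clip(field.red.astype(np.float64) * gain, 0, None),
            metadata=field.metadata)
        w = calibrate_from_fields([scaled], seg_cfg, ratio_cfg)
        cells, _, _ = score_field(scaled, w, seg_cfg, ratio_cfg)
        areas[gain] = sum(c.red_only_area_px for c in cells)
    base = areas[1.0]
    assert base > 0
    for gain in (0.5, 2.0):
        assert abs(areas[gain] - base) / base < 0.01


def test_mean_area_monotone_in_planted_rate(seg_cfg, ratio_cfg):
    weight_field, _ = generate_field(SceneConfig(
        rng_seed=77, mitolysosomes_per_cell=0.2))
    weight = calibrate_from_fields([weight_field], seg_cfg, ratio_cfg)
    means = []
    for rate in (0.5, 2.0, 5.0):
        vals = []
        for seed in range(4):
            field, _ = generate_field(SceneConfig(
                rng_seed=100 + seed, mitolysosomes_per_cell=rate))
            cells, _, _ = score_field(field, weight, seg_cfg, ratio_cfg)
            vals.extend(c.red_only_area_px for c in cells)
        means.append(np.mean(vals))
    assert means[0] <= means[1] <= means[2]


# --- object-integrated variants ------------------------------------------

def test_object_ratio_trivial_calls(ratio_cfg):
    labels = np.zeros((20, 20), dtype=np.int32)
    labels[2:6, 2:6] = 1    # yellow: green == weighted red
    labels[10:14, 10:14] = 2  # red-only: green = 0.3 x weighted red
    g = np.zeros((20, 20))
    r = np.zeros((20, 20))
    g[labels == 1] = 100.0
    r[labels == 1] = 100.0
    g[labels == 2] = 30.0
    r[labels == 2] = 100.0
    out = classify_objects_by_integrated_ratio(
        g, r, labels, ChannelWeight(w=1.0, n_calibration_pixels=1), ratio_cfg)
    assert out.set_index("object_id")["call"].to_dict() == \
        {1: "yellow", 2: "red_only"}


def test_object_calls_match_brute_force(ratio_cfg):
    g, r, truth = generate_object_field(image_size=(300, 300), n_objects=60,
                                        seed=4)
    w = ChannelWeight(w=1 / 1.5, n_calibration_pixels=1)
    out = classify_objects_by_integrated_ratio(g, r, truth.object_labels, w,
                                               ratio_cfg)
    for _, row in out.iterrows():
        pix = truth.object_labels == row["object_id"]
        expected = g[pix].sum() / (w.w * r[pix].sum())
        assert row["ratio"] == pytest.approx(expected, rel=1e-12)
        assert row["call"] == ("red_only" if expected < 0.5 else "yellow")


def test_object_field_truth_recovered(ratio_cfg):
    g, r, truth = generate_object_field(image_size=(400, 400), n_objects=80,
                                        red_only_fraction=0.3, seed=9)
    w = ChannelWeight(w=1 / 1.5, n_calibration_pixels=1)
    out = classify_objects_by_integrated_ratio(g, r, truth.object_labels, w,
                                               ratio_cfg)
    merged = out.merge(truth.per_object, on="object_id")
    agree = (merged["call"].eq("red_only") == merged["is_red_only"]).mean()
    assert agree >= 0.95


def test_zero_red_object_flagged(ratio_cfg):
    labels = np.zeros((10, 10), dtype=np.int32)
    labels[2:4, 2:4] = 1
    g = np.ones((10, 10))
    r = np.zeros((10, 10))
    with pytest.warns(UserWarning):
        out = classify_objects_by_integrated_ratio(
            g, r, labels, ChannelWeight(w=1.0, n_calibration_pixels=1),
            ratio_cfg)
    assert bool(out.loc[0, "flagged"])


# --- grid quantification --------------------------------------------------

def test_grid_defaults_four_windows():
    region = np.ones((600, 600), dtype=bool)
    labels = np.zeros((600, 600), dtype=np.int32)
    mean, corners = grid_quantify(labels, region, seed=1)
    assert len(corners) == 4
    for (y, x) in corners:
        assert region[y:y + 250, x:x + 250].all()


def test_grid_windows_nonoverlapping():
    region = np.ones((600, 600), dtype=bool)
    _, corners = grid_quantify(np.zeros((600, 600), np.int32), region, seed=3)
    for i, (y1, x1) in enumerate(corners):
        for y2, x2 in corners[i + 1:]:
            assert abs(y1 - y2) >= 250 or abs(x1 - x2) >= 250


def test_grid_constant_density_mean():
    # one object per 100x100 tile -> every 200x200 window holds exactly 4
    region = np.ones((640, 640), dtype=bool)
    labels = np.zeros((640, 640), dtype=np.int32)
    k = 0
    for y in range(50, 640, 100):
        for x in range(50, 640, 100):
            k += 1
            labels[y, x] = k
    mean, _ = grid_quantify(labels, region, grid_size=200, n_grids=4, seed=0)
    assert mean == pytest.approx(4.0)


def test_grid_region_too_small():
    region = np.zeros((300, 300), dtype=bool)
    region[:260, :260] = True
    with pytest.raises(RegionTooSmallError) as exc:
        grid_quantify(np.zeros((300, 300), np.int32), region, grid_size=250,
                      n_grids=4, seed=0)
    assert exc.value.max_feasible < 4


def test_grid_monte_carlo_density():
    rng = np.random.default_rng(8)
    labels = np.zeros((500, 500), dtype=np.int32)
    n = 200
    ys = rng.integers(0, 500, n)
    xs = rng.integers(0, 500, n)
    for i, (y, x) in enumerate(zip(ys, xs), 1):
        labels[y, x] = i
    n_objects = len(np.unique(labels)) - 1
    region = np.ones((500, 500), dtype=bool)
    means = [grid_quantify(labels, region, grid_size=100, n_grids=4,
                           seed=s)[0] for s in range(40)]
    expected = n_objects * (100 * 100) / (500 * 500)
    assert np.mean(means) == pytest.approx(expected, rel=0.15)


# --- puncta + intensity ratio --------------------------------------------

def test_all_puncta_colocalised_zero_percent():
    labels = np.zeros((50, 50), dtype=np.int32)
    labels[5:8, 5:8] = 1
    labels[20:23, 20:23] = 2
    green = labels > 0
    assert puncta_mitophagy_frequency(labels, green) == 0.0


def test_three_of_ten_disjoint_is_30_percent():
    labels = np.zeros((40, 120), dtype=np.int32)
    green = np.zeros((40, 120), dtype=bool)
    for i in range(10):
        labels[10:13, 10 * i + 2:10 * i + 5] = i + 1
        if i >= 3:
            green[10:13, 10 * i + 2:10 * i + 5] = True
    assert puncta_mitophagy_frequency(labels, green) == pytest.approx(30.0)


def test_zero_puncta_flagged():
    with pytest.warns(UserWarning):
        out = puncta_mitophagy_frequency(np.zeros((10, 10), np.int32),
                                         np.zeros((10, 10), bool))
    assert np.isnan(out)


def test_planted_quenched_fraction_recovered():
    fracs = []
    for seed in range(6):
        labels, green_mask, truth = generate_puncta_field(
            n_puncta=40, quenched_fraction=0.25, seed=seed)
        fracs.append(puncta_mitophagy_frequency(labels, green_mask))
        expected = 100.0 * truth["quenched"].mean()
        assert fracs[-1] == pytest.approx(expected, abs=1e-9)
    assert np.mean(fracs) == pytest.approx(25.0, abs=10.0)


def test_channel_intensity_ratio_basics(rng):
    g = rng.uniform(10, 100, (20, 20))
    mask = rng.random((20, 20)) > 0.3
    assert channel_intensity_ratio(g, g, mask) == pytest.approx(1.0)
    assert channel_intensity_ratio(g / 2, g, mask) == pytest.approx(0.5)
    expected = g[mask].sum() / (2 * g)[mask].sum()
    assert channel_intensity_ratio(g, 2 * g, mask) == pytest.approx(expected)


def test_channel_intensity_ratio_zero_red_flagged():
    g = np.ones((10, 10))
    with pytest.warns(UserWarning):
        out = channel_intensity_ratio(g, np.zeros((10, 10)),
                                      np.ones((10, 10), bool))
    assert np.isnan(out)


def test_ratio_config_invariants():
    with pytest.raises(ValueError):
        RatioConfig(red_only_threshold=1.2).validate()
    with pytest.raises(ValueError):
        RatioConfig(red_only_threshold=0.0).validate()
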