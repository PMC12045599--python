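"""Mask construction, background-subtracted measurement and the
relocalization / cytoplasmic-loss ratio arithmetic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

from invkit.capture_quant import (FieldImage, MaskSet, build_masks,
                                  compute_ratios, cytoplasmic_loss,
                                  make_cytoplasm_mask, measure_cell,
                                  measure_field, register_channels,
                                  segment_mitochondria)
from invkit.errors import ConfigurationError
from invkit.synthetic_data import CHANNEL_INDEX


# ---------------------------------------------------------------------------
# registration
# ---------------------------------------------------------------------------

def test_register_recovers_constructed_translation(rng):
    base = ndimage.gaussian_filter(rng.random((64, 64)), 2)
    shifted = np.roll(np.roll(base, 3, axis=0), -2, axis=1)
    _, shifts = register_channels(np.stack([base, shifted]))
    np.testing.assert_allclose(shifts[1], (3, -2), atol=0.1)


def test_register_identical_channels_zero_shift(rng):
    img = rng.random((48, 48))
    _, shifts = register_channels(np.stack([img, img]))
    np.testing.assert_allclose(shifts, 0, atol=1e-6)


def test_register_flat_channel_warns_zero_shift(rng):
    stack = np.stack([rng.random((32, 32)), np.ones((32, 32))])
    with pytest.warns(UserWarning, match="flat"):
        _, shifts = register_channels(stack)
    np.testing.assert_array_equal(shifts[1], (0, 0))


# ---------------------------------------------------------------------------
# segmentation and masks
# ---------------------------------------------------------------------------

def test_segmentation_overlaps_ground_truth(noise_free_pair):
    _, post, gt = noise_free_pair
    mask = segment_mitochondria(post[CHANNEL_INDEX["mitotrap"]])
    inter = (mask & gt.mito_mask).sum()
    union = (mask | gt.mito_mask).sum()
    assert inter / union >= 0.7


def test_segmentation_flat_image_empty_mask():
    with pytest.warns(UserWarning, match="flat"):
        mask = segment_mitochondria(np.zeros((32, 32)))
    assert not mask.any()


def test_segmentation_inverted_contrast_symmetric(rng):
    img = ndimage.gaussian_filter(rng.random((64, 64)), 1) * 100
    upright = segment_mitochondria(img)
    flipped = segment_mitochondria(img.max() - img, invert=True)
    np.testing.assert_array_equal(upright, flipped)


def test_single_pixel_eight_dilations_gives_288_cytoplasm_pixels():
    m = np.zeros((25, 25), dtype=bool)
    m[12, 12] = True
    cyto = make_cytoplasm_mask(m, n_dilations=8)
    assert cyto.sum() == 17 * 17 - 1 == 288


def test_empty_mito_mask_gives_empty_cyto():
    assert not make_cytoplasm_mask(np.zeros((16, 16), bool)).any()


def test_invalid_dilation_count():
    with pytest.raises(ConfigurationError):
        make_cytoplasm_mask(np.ones((4, 4), bool), n_dilations=0)


@settings(derandomize=True, max_examples=25)
@given(seed=st.integers(0, 10_000), n=st.integers(1, 8))
def test_cyto_mask_set_algebra(seed, n):
    """cyto = dilate(mito, n) \\ mito: disjoint from mito, inside the dilated
    mask, and monotone in the number of dilations."""
    r = np.random.default_rng(seed)
    mito = r.random((40, 40)) > 0.97
    cyto = make_cytoplasm_mask(mito, n)
    dilated = ndimage.binary_dilation(mito, structure=np.ones((3, 3)),
                                      iterations=n)
    assert not (cyto & mito).any()
    assert (cyto <= dilated).all() and ((cyto | mito) == dilated).all()
    bigger = make_cytoplasm_mask(mito, n + 1) | mito
    assert (bigger >= dilated).all()


# ---------------------------------------------------------------------------
# measurement
# ---------------------------------------------------------------------------

def _toy_masks():
    labels = np.zeros((10, 10), dtype=np.int32)
    mito = np.zeros((10, 10), bool)
    cyto = np.zeros((10, 10), bool)
    mito[2, 2:7] = True                  # 5 px
    cyto[3:5, 0:10] = True               # 20 px
    labels[(mito | cyto)] = 1
    return MaskSet(mito, cyto, labels)


def test_measure_uniform_arithmetic():
    masks = _toy_masks()
    img = np.full((10, 10), 10.0)
    m = measure_cell(img, masks, 1, background=2.0)
    assert (m.f_mito, m.f_cyto, m.f_total) == (40.0, 160.0, 200.0)


def test_measure_background_equal_to_signal_gives_zero():
    masks = _toy_masks()
    m = measure_cell(np.full((10, 10), 7.0), masks, 1, background=7.0)
    assert m.f_total == 0.0


def test_measure_matches_naive_loop_oracle(rng):
    masks = _toy_masks()
    img = rng.random((10, 10)) * 50
    bg = 20.0
    m = measure_cell(img, masks, 1, background=bg)
    f_mito = f_cyto = 0.0
    for y in range(10):
        for x in range(10):
            v = max(img[y, x] - bg, 0.0)
            if masks.mito_mask[y, x]:
                f_mito += v
            elif masks.cyto_mask[y, x]:
                f_cyto += v
    assert m.f_mito == pytest.approx(f_mito)
    assert m.f_cyto == pytest.approx(f_cyto)
    assert m.f_total == m.f_mito + m.f_cyto      # exact identity


def test_disjoint_masks_enforced():
    both = np.ones((4, 4), bool)
    with pytest.raises(ConfigurationError):
        MaskSet(both, both, np.ones((4, 4), np.int32))


# ---------------------------------------------------------------------------
# ratios
# ---------------------------------------------------------------------------

def _meas_row(cell, channel, f_mito, f_cyto, frame=None, replicate=0):
    return {"cell_id": cell, "channel": channel, "frame": frame,
            "replicate": replicate, "condition": "", "F_mito": f_mito,
            "F_cyto": f_cyto, "F_total": f_mito + f_cyto}


def test_fixed_ratio_arithmetic():
    df = pd.DataFrame([_meas_row(1, "fkbp_marker", 40.0, 160.0)])
    rec = compute_ratios(df, mode="fixed")
    assert rec.loc[0, "ratio_fixed"] == pytest.approx(0.2)
    assert rec.loc[0, "cyto_fraction"] == pytest.approx(0.8)
    # partition of unity per record
    assert rec.loc[0, "ratio_fixed"] + rec.loc[0, "cyto_fraction"] == 1.0


def test_responder_rule_boundary():
    """F_mito/F_cyto < 1 excludes; == 1 is kept (strict inequality)."""
    df = pd.DataFrame([
        _meas_row(1, "fkbp_marker", 90.0, 100.0),   # 0.9  -> non-responder
        _meas_row(2, "fkbp_marker", 100.0, 100.0),  # 1.0  -> kept
        _meas_row(1, "poi", 10.0, 100.0),
        _meas_row(2, "poi", 10.0, 100.0),
    ])
    rec = compute_ratios(df, mode="fixed")
    by_cell = rec.set_index(["cell_id", "channel"])["responder"]
    assert not by_cell[(1, "poi")]       # exclusion propagates to all channels
    assert by_cell[(2, "poi")]
    # filter off for untreated references
    ref = compute_ratios(df, mode="fixed", apply_responder_filter=False)
    assert ref["responder"].all()


def test_zero_total_dropped_with_warning():
    df = pd.DataFrame([_meas_row(1, "fkbp_marker", 0.0, 0.0),
                       _meas_row(2, "fkbp_marker", 10.0, 10.0)])
    with pytest.warns(UserWarning, match="F_total"):
        rec = compute_ratios(df, mode="fixed")
    assert list(rec["cell_id"]) == [2]


def test_live_ratio_uses_pre_and_post_mito_fluorescence():
    df = pd.DataFrame([
        _meas_row(1, "fkbp_marker", 50.0, 100.0, frame=0),
        _meas_row(1, "fkbp_marker", 150.0, 50.0, frame=5),
        _meas_row(1, "poi", 20.0, 100.0, frame=0),
        _meas_row(1, "poi", 40.0, 80.0, frame=5),
    ])
    rec = compute_ratios(df, mode="live").set_index("channel")
    assert rec.loc["fkbp_marker", "ratio_live"] == pytest.approx(3.0)
    assert rec.loc["poi", "ratio_live"] == pytest.approx(2.0)
    assert rec.loc["poi", "cyto_fraction"] == pytest.approx(80 / 120)


# ---------------------------------------------------------------------------
# cytoplasmic loss
# ---------------------------------------------------------------------------

def _records(cfs, replicate=0):
    return pd.DataFrame({
        "cell_id": range(len(cfs)), "channel": "poi",
        "cyto_fraction": cfs, "responder": True, "replicate": replicate,
    })


def test_cytoplasmic_loss_matches_worked_example():
    """Reference cytoplasmic fraction 0.80, treated 0.228 -> 71.5% loss."""
    res = cytoplasmic_loss(_records([0.228]), _records([0.80]))
    assert res.grand_mean == pytest.approx(71.5)


def test_no_change_gives_zero_loss():
    res = cytoplasmic_loss(_records([0.6, 0.7]), _records([0.6, 0.7]))
    assert res.grand_mean == pytest.approx(0.0)


def test_negative_loss_flagged():
    with pytest.warns(UserWarning, match="negative"):
        res = cytoplasmic_loss(_records([0.9]), _records([0.5]))
    assert res.grand_mean < 0 and res.flagged_negative


def test_zero_reference_errors():
    with pytest.raises(ConfigurationError):
        cytoplasmic_loss(_records([0.5]), _records([0.0]))


# ---------------------------------------------------------------------------
# pipeline-level invariants on simulated data
# ---------------------------------------------------------------------------

def test_measured_field_identities_and_mask_disjointness(noise_free_pair):
    _, post, _ = noise_free_pair
    masks = build_masks(post[CHANNEL_INDEX["mitotrap"]])
    assert not (masks.mito_mask & masks.cyto_mask).any()
    field = FieldImage(post, {"fkbp_marker": 0, "poi": 1, "mitotrap": 2})
    meas = measure_field(field, masks)
    assert (meas["F_total"] == meas["F_mito"] + meas["F_cyto"]).all()
    assert (meas[["F_mito", "F_cyto"]] >= 0).all().all()


def test_noise_free_loss_recovers_pool_fraction(noise_free_config):
    """Full pipeline on a noise-free simulation recovers the configured
    relocalizable pool fraction within 2 percentage points."""
    from invkit.pipeline import quantify_capture_pair
    from invkit.synthetic_data import simulate_fixed_capture_pair

    cfg = noise_free_config.replace(fkbp_channel="A", seed=21)
    pre, post, _ = simulate_fixed_capture_pair(cfg)
    treated, reference = quantify_capture_pair(
        pre, post, {"fkbp_marker": 0, "poi": 1, "mitotrap": 2})
    res = cytoplasmic_loss(treated, reference, channel="fkbp_marker")
    assert res.grand_mean == pytest.approx(100 * cfg.pool_fraction_A, abs=2.0)
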