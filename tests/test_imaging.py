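"""Puncta detection, colocalization, per-cell counting and filters."""

import numpy as np
import pandas as pd
import pytest

from thermalplex.imaging import (
    Punctum,
    colocalize,
    compute_threshold,
    detect_puncta,
    filter_cells,
    max_z_projection,
    overlay_reconstruction,
    per_cell_counts,
)
from thermalplex.simulate import ImageSimSpec, simulate_images


@pytest.fixture(scope="module")
def snr10_field():
    spec = ImageSimSpec(n_spots=50, rng_seed=42)
    return spec, simulate_images(spec)


def test_projection_identity_and_oracle():
    rng = np.random.default_rng(0)
    single = rng.uniform(size=(1, 16, 16))
    assert np.array_equal(max_z_projection(single), single[0])

    stack = rng.uniform(size=(5, 12, 12))
    naive = np.empty((12, 12))
    for r in range(12):
        for c in range(12):
            naive[r, c] = max(stack[z, r, c] for z in range(5))
    assert np.array_equal(max_z_projection(stack), naive)

    with pytest.raises(ValueError):
        max_z_projection(np.zeros((4, 4)))


def test_threshold_spec_forms():
    img = np.zeros((8, 8))
    img[0, 0] = 8.0
    assert compute_threshold(img, 3.5) == 3.5
    expected = img.mean() + 5 * img.std()
    assert compute_threshold(img, "mean+5sd") == pytest.approx(expected)
    assert compute_threshold(img, ("mean_sd", 5)) == pytest.approx(expected)
    with pytest.raises(ValueError):
        compute_threshold(img, "otsu-ish")


def test_blank_image_has_no_puncta():
    assert detect_puncta(np.full((64, 64), 7.0), threshold=10.0) == []


def test_detection_recovers_planted_spots(snr10_field):
    spec, result = snr10_field
    puncta = detect_puncta(result.images["A"])
    assert len(puncta) == spec.n_spots
    truth = result.truth[result.truth.channel == "A"]
    found = np.array([p.centroid for p in puncta])
    for _, row in truth.iterrows():
        d = np.min(np.hypot(found[:, 0] - row.row, found[:, 1] - row.col))
        assert d <= 1.0


def test_punctum_intensity_is_max_pixel():
    img = np.zeros((32, 32))
    img[10:13, 10:13] = 50.0
    img[11, 11] = 80.0
    (p,) = detect_puncta(img, threshold=25.0, min_area_px=2)
    assert p.intensity == 80.0
    assert p.area == 9
    assert p.centroid == (11.0, 11.0)


def test_min_area_and_dimension_checks():
    img = np.zeros((16, 16))
    img[3, 3] = 100.0  # single-pixel spot
    assert detect_puncta(img, threshold=50.0, min_area_px=2) == []
    assert len(detect_puncta(img, threshold=50.0, min_area_px=1)) == 1
    with pytest.raises(ValueError):
        detect_puncta(np.zeros((4, 4, 4)), threshold=1.0)


def _puncta_at(points):
    return [Punctum(centroid=tuple(p), intensity=1.0, area=4) for p in points]


def test_colocalize_identical_and_disjoint():
    pts = [(5.0, 5.0), (20.0, 20.0), (40.0, 10.0)]
    same = colocalize(_puncta_at(pts), _puncta_at(pts), radius_px=2.0)
    assert same.n_both == 3
    assert same.pct_both_a == 100.0 and same.pct_both_b == 100.0
    assert same.pct_only_a == 0.0

    far = colocalize(_puncta_at([(5.0, 5.0)]), _puncta_at([(50.0, 50.0)]), 2.0)
    assert far.n_both == 0 and far.pct_both_a == 0.0


def test_colocalize_fractions_conserved_and_one_to_one():
    a = _puncta_at([(5, 5), (6, 5), (30, 30)])
    b = _puncta_at([(5.5, 5.0), (31, 30), (50, 50)])
    res = colocalize(a, b, radius_px=2.0)
    matched_a = {i for i, _ in res.pairs}
    matched_b = {j for _, j in res.pairs}
    assert len(matched_a) == len(res.pairs) == len(matched_b)
    assert res.pct_only_a + res.pct_both_a == pytest.approx(100.0)
    assert res.pct_only_b + res.pct_both_b == pytest.approx(100.0)


def test_colocalize_empty_channel_flagged():
    res = colocalize([], _puncta_at([(1, 1)]), 2.0)
    assert res.pct_both_a is None and res.pct_both_b == 0.0


def test_planted_colocalization_fraction_recovered():
    """80% planted colocalization at n = 200: recovered 'both' fraction
    within the 95% binomial interval of the planted rate."""
    spec = ImageSimSpec(shape=(512, 512), n_spots=200, coloc_fraction=0.8,
                        rng_seed=7)
    result = simulate_images(spec)
    pa = detect_puncta(result.images["A"])
    pb = detect_puncta(result.images["B"])
    res = colocalize(pa, pb, radius_px=2.0)
    half = 1.96 * np.sqrt(0.8 * 0.2 / spec.n_spots) * 100
    assert abs(res.pct_both_a - 80.0) <= half
    assert abs(res.pct_both_b - 80.0) <= half


def test_per_cell_counts_whole_frame_and_background():
    masks = np.ones((64, 64), dtype=int)
    puncta = {"geneA": _puncta_at([(i * 5.0, i * 5.0) for i in range(12)])}
    counts, background = per_cell_counts(puncta, masks)
    assert counts.loc[1, "geneA"] == 12
    assert background["geneA"] == 0

    masks[0:8, 0:8] = 0  # background corner holds the first two puncta
    counts, background = per_cell_counts(puncta, masks)
    assert counts.loc[1, "geneA"] == 10
    assert background["geneA"] == 2
    # conservation
    assert counts["geneA"].sum() + background["geneA"] == 12


def test_per_cell_counts_exact_recovery_on_planted_regions():
    rng = np.random.default_rng(5)
    masks = np.zeros((60, 60), dtype=int)
    masks[:30, :30] = 1
    masks[:30, 30:] = 2
    masks[30:, :] = 3
    planted = {1: 4, 2: 7, 3: 2}
    pts = []
    for lbl, n in planted.items():
        rows, cols = np.where(masks == lbl)
        idx = rng.choice(len(rows), size=n, replace=False)
        pts.extend((float(rows[i]), float(cols[i])) for i in idx)
    counts, background = per_cell_counts({"g": _puncta_at(pts)}, masks)
    for lbl, n in planted.items():
        assert counts.loc[lbl, "g"] == n
    assert background["g"] == 0

    with pytest.raises(ValueError):
        per_cell_counts({"g": _puncta_at([(100.0, 5.0)])}, masks)


def test_filter_cells_thresholds():
    counts = pd.DataFrame(
        {"hi": [4, 5, 12], "lo": [1, 2, 0]}, index=[1, 2, 3]
    )
    out = filter_cells(counts, {"hi": "high", "lo": "low"})
    assert np.isnan(out.loc[1, "hi"])  # 4 < 5 excluded
    assert out.loc[2, "hi"] == 5  # boundary retained
    assert np.isnan(out.loc[1, "lo"])  # 1 < 2 excluded
    assert out.loc[2, "lo"] == 2  # 2 is not fewer than 2
    assert np.isnan(out.loc[3, "lo"])

    zero = pd.DataFrame({"hi": [0, 0]}, index=[1, 2])
    res = filter_cells(zero, {"hi": "high"})
    assert res["hi"].isna().all()

    with pytest.raises(ValueError):
        filter_cells(counts, {"hi": "high", "lo": "mystery"})


def test_overlay_conserves_puncta_counts():
    chans = [
        ("geneA", 0, "Atto488", _puncta_at([(1, 1), (2, 2)])),
        ("geneB", 0, "Atto565", _puncta_at([(3, 3)])),
        ("geneC", 4, "Alexa647", _puncta_at([])),
    ]
    table = overlay_reconstruction(chans)
    assert len(table) == 3
    assert set(table.columns) == {"row", "col", "target", "round", "fluor",
                                  "intensity"}
    assert overlay_reconstruction([]).empty

    fifteen = [(f"g{i}", i // 3, "dye", _puncta_at([(i, i)])) for i in range(15)]
    assert len(overlay_reconstruction(fifteen)) == 15
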