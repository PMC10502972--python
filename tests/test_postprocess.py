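"""Post-processing: thresholding, component filtering, fovea, thickness."""

import logging

import numpy as np
import pytest

from choroidseg import (
    BScan, PhantomSpec, binarize, clean_mask, generate_phantom,
    largest_component, locate_fovea, measure_sfcht, thickness_profile,
)
from conftest import random_mask


# ---------------------------------------------------------------------- #
# binarize


def test_binarize_threshold_is_inclusive():
    p = np.full((3, 3), 0.5)
    assert binarize(p).all()
    assert not binarize(np.zeros((3, 3))).any()
    checker = np.indices((4, 4)).sum(0) % 2
    p = np.where(checker, 0.7, 0.3)
    np.testing.assert_array_equal(binarize(p), checker)


def test_binarize_rejects_out_of_range():
    with pytest.raises(ValueError, match=r"\[0, 1\]"):
        binarize(np.full((2, 2), 1.5))


# ---------------------------------------------------------------------- #
# largest component


def flood_fill_components(m, connectivity=8):
    """BFS labelling oracle; returns list of pixel sets."""
    m = np.asarray(m).astype(bool)
    if connectivity == 8:
        steps = [(a, b) for a in (-1, 0, 1) for b in (-1, 0, 1)
                 if (a, b) != (0, 0)]
    else:
        steps = [(1, 0), (-1, 0), (0, 1), (0, -1)]
    seen = np.zeros_like(m)
    comps = []
    H, W = m.shape
    for r in range(H):
        for c in range(W):
            if m[r, c] and not seen[r, c]:
                comp, stack = set(), [(r, c)]
                seen[r, c] = True
                while stack:
                    rr, cc = stack.pop()
                    comp.add((rr, cc))
                    for dr, dc in steps:
                        nr, nc = rr + dr, cc + dc
                        if (0 <= nr < H and 0 <= nc < W and m[nr, nc]
                                and not seen[nr, nc]):
                            seen[nr, nc] = True
                            stack.append((nr, nc))
                comps.append(comp)
    return comps


@pytest.mark.parametrize("connectivity", [4, 8])
def test_largest_component_matches_flood_fill_oracle(connectivity, rng):
    for _ in range(50):
        m = random_mask(rng, (10, 10), p=0.3)
        got = largest_component(m, connectivity=connectivity)
        comps = flood_fill_components(m, connectivity)
        if not comps:
            assert got.sum() == 0
            continue
        # tie-break: among equal sizes, the component whose smallest
        # (row, col) pixel is lexicographically least
        best = sorted(comps, key=lambda c: (-len(c), min(c)))[0]
        assert {tuple(p) for p in np.argwhere(got == 1)} == best


def test_largest_component_sizes_5_vs_3():
    m = np.zeros((6, 10), np.uint8)
    m[1, 1:6] = 1  # size 5
    m[4, 1:4] = 1  # size 3
    out = largest_component(m)
    assert out.sum() == 5
    assert out[1, 1:6].all()


def test_largest_component_tie_break_and_identity():
    m = np.zeros((5, 9), np.uint8)
    m[3, 6:8] = 1  # later in raster order
    m[1, 1:3] = 1  # equal size, smaller (row, col)
    out = largest_component(m)
    assert out[1, 1:3].all() and out.sum() == 2
    single = np.zeros((4, 4), np.uint8)
    single[1:3, 1:3] = 1
    np.testing.assert_array_equal(largest_component(single), single)
    empty = np.zeros((3, 3), np.uint8)
    np.testing.assert_array_equal(largest_component(empty), empty)


def test_largest_component_is_subset_with_predictable_dice():
    from choroidseg import dice_score

    m = np.zeros((8, 8), np.uint8)
    m[0, 0:4] = 1
    m[7, 0:2] = 1
    out = largest_component(m)
    assert (out <= m).all()
    expected = 2 * out.sum() / (out.sum() + m.sum())
    assert dice_score(out, m) == expected


# ---------------------------------------------------------------------- #
# fovea localization


def test_locate_fovea_finds_centered_and_shifted_pits():
    for shift in (0, 5, -7):
        spec = PhantomSpec.tiny(pit_shift=shift, seed=1)
        bscan, mask = generate_phantom(spec)
        assert locate_fovea(bscan, choroid_mask=mask) == spec.fovea_column
        assert locate_fovea(bscan) == spec.fovea_column


def test_locate_fovea_translation_equivariant_within_band():
    # 96-wide image, band columns 35..59 (centred left): pit shifts
    # -13..+11 relative to column 48 stay inside the band
    cols = {}
    for shift in range(-13, 12):
        spec = PhantomSpec.tiny(pit_shift=shift, speckle_sigma=0.0,
                                lacunae_density=0.0)
        bscan, _ = generate_phantom(spec)
        cols[shift] = locate_fovea(bscan)
    assert all(cols[s] == 48 + s for s in cols)


def test_locate_fovea_flat_retina_tie_breaks_to_center():
    """No pit, no noise: every column count ties; the documented
    tie-break picks the column nearest the image centre (leftward)."""
    width = 96
    retina = np.full(width, 20)
    retina[48] = 19  # needed only to satisfy the spec invariant
    spec = PhantomSpec(
        height=64, width=width, ilm_depth=8,
        retina_thickness_profile=retina,
        choroid_thickness_profile=np.full(width, 14),
        fovea_column=48, speckle_sigma=0.0,
    )
    bscan, _ = generate_phantom(spec)
    flat = bscan.pixels.copy()
    flat[:, 48] = flat[:, 47]  # remove the pit -> truly flat retina
    assert locate_fovea(BScan(flat)) == 47  # 96 wide: centre-left column


def test_locate_fovea_rejects_constant_band():
    with pytest.raises(ValueError, match="Otsu"):
        locate_fovea(BScan(np.full((32, 64), 0.5)))
    with pytest.raises(ValueError, match="width"):
        locate_fovea(BScan(np.zeros((32, 20))), band_width=25)


# ---------------------------------------------------------------------- #
# thickness


def test_thickness_profile_examples():
    m = np.zeros((80, 6), np.uint8)
    m[10:60] = 1  # uniform 50 px
    prof = thickness_profile(m, axial_scale=4.0)
    assert (prof.thickness_um == 200.0).all()
    assert prof.valid.all()
    empty = thickness_profile(np.zeros((8, 4), np.uint8), 4.0)
    assert not empty.valid.any()
    single = np.zeros((8, 1), np.uint8)
    single[2:5, 0] = 1
    assert thickness_profile(single, 3.87).at(0) == pytest.approx(11.61)


def test_thickness_profile_rejects_bad_scale(tiny_phantom):
    with pytest.raises(ValueError, match="axial_scale"):
        thickness_profile(tiny_phantom[1], 0.0)


# ---------------------------------------------------------------------- #
# SfChT measurement


def test_measure_sfcht_six_identical_scans(tiny_spec):
    bscan, mask = generate_phantom(tiny_spec)
    m = measure_sfcht([(bscan, mask)] * 6)
    assert m.mean_um == pytest.approx(tiny_spec.subfoveal_thickness_um)
    assert len(m.per_scan_um) == 6


def test_measure_sfcht_mean_and_order_invariance(tiny_spec):
    scans = []
    for extra in (-1, 0, 1, -1, 0, 1):  # subfoveal 13/14/15 px
        spec = PhantomSpec.tiny(
            choroid_px=14 + extra, speckle_sigma=0.0, lacunae_density=0.0)
        scans.append(generate_phantom(spec))
    m = measure_sfcht(scans)
    # tiny preset: subfoveal thickness is choroid_px + 2 (cosine bulge)
    assert m.per_scan_um == [px * 3.87 for px in (15, 16, 17, 15, 16, 17)]
    assert m.mean_um == pytest.approx(16.0 * 3.87)
    m_rev = measure_sfcht(scans[::-1])
    assert m_rev.mean_um == pytest.approx(m.mean_um)


def test_measure_sfcht_excludes_invalid_scan(tiny_spec, caplog):
    bscan, mask = generate_phantom(tiny_spec)
    bad_mask = np.zeros_like(mask)
    bad_mask[2, 0] = 1  # a stray pixel far from the fovea column
    scans = [(bscan, mask)] * 5 + [(bscan, bad_mask)]
    with caplog.at_level(logging.WARNING, logger="choroidseg.postprocess"):
        m = measure_sfcht(scans)
    assert len(m.per_scan_um) == 5
    assert any("excluded" in r.message for r in caplog.records)
    all_bad = [(bscan, bad_mask)]
    with pytest.raises(ValueError, match="all scans excluded"):
        measure_sfcht(all_bad)


def test_full_chain_recovers_ground_truth_exactly():
    """binarize -> largest component -> hole fill -> measure applied to
    the ground-truth mask cast to probabilities recovers the configured
    SfChT exactly."""
    for seed in range(5):
        spec = PhantomSpec.tiny(seed=seed, pit_shift=(seed - 2) * 3,
                                lacunae_density=0.5)
        bscan, mask = generate_phantom(spec)
        cleaned = clean_mask(mask.astype(float))
        m = measure_sfcht([(bscan, cleaned)])
        assert m.fovea_columns == [spec.fovea_column]
        assert m.mean_um == pytest.approx(spec.subfoveal_thickness_um)
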