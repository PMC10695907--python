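"""Volume, inner/outer integrity ratios and compression-score aggregation."""

import numpy as np
import pytest

from biopsy3d import (BinaryMask, CompressionScores, aggregate_compression,
                      compute_volume, inner_integrity, outer_integrity,
                      summarize_specimen)

from ._oracles import brute_close, brute_fill_holes, brute_open
from .conftest import mask_of, random_mask, solid_cube


def test_volume_is_count_times_voxel_volume():
    data = np.zeros((100, 100, 100), dtype=bool)
    data[:40, :50, :50] = True  # 100,000 voxels
    assert compute_volume(mask_of(data, 2.0)) == pytest.approx(100_000 * 8e-9)
    assert compute_volume(mask_of(np.zeros((3, 3, 3), bool))) == 0.0


def test_volume_of_discrete_ellipsoid_by_enumeration():
    zz, yy, xx = np.ogrid[0:31, 0:31, 0:31]
    inside = ((zz - 15) / 12.0) ** 2 + ((yy - 15) / 8.0) ** 2 + ((xx - 15) / 6.0) ** 2 <= 1
    count = sum(1 for idx in np.ndindex(31, 31, 31) if inside[idx])  # direct enumeration
    assert compute_volume(mask_of(inside, 2.0)) == pytest.approx(count * 8e-9)


def test_solid_cube_has_perfect_integrity():
    cube = solid_cube(21, 31)
    assert cube.n_foreground == 9261
    summary = summarize_specimen(cube)
    assert summary.inner_integrity == 1.0
    assert summary.outer_integrity == 1.0
    assert summary.n_seg == summary.n_closed == summary.n_filled_inner == 9261
    assert summary.volume_mm3 == pytest.approx(9261 * 8e-9)


def test_inner_integrity_with_central_cavity():
    """A 5-wide cavity survives the 3x3x3 closing and is filled by hole filling."""
    cube = solid_cube(21, 31)
    data = cube.data.copy()
    data[13:18, 13:18, 13:18] = False
    closed = brute_close(data, np.ones((3, 3, 3), bool))
    assert (~closed[13:18, 13:18, 13:18]).sum() == 125  # oracle: cavity intact
    n_seg, n_closed, n_filled, ratio = inner_integrity(mask_of(data))
    assert (n_seg, n_filled) == (9136, 9261)
    assert ratio == pytest.approx(9136 / 9261)


def test_inner_integrity_single_voxel_void_closed_not_filled():
    cube = solid_cube(21, 31)
    data = cube.data.copy()
    data[15, 15, 15] = False
    closed = brute_close(data, np.ones((3, 3, 3), bool))
    assert closed[15, 15, 15]  # oracle: closing alone repairs a 1-voxel void
    n_seg, n_closed, n_filled, ratio = inner_integrity(mask_of(data))
    assert (n_seg, n_closed, n_filled) == (9260, 9261, 9261)
    assert ratio == pytest.approx(9260 / 9261)


def test_outer_integrity_with_surface_spike():
    cube = solid_cube(21, 35)
    data = cube.data.copy()
    data[17, 17, 28:34] = True  # 6-voxel spike off the +x face
    assert data.sum() == 9267
    opened = brute_open(data, np.ones((3, 3, 3), bool))
    assert opened.sum() == 9261  # oracle: spike removed, body intact
    n_filled, n_smoothed, ratio, opened_away = outer_integrity(mask_of(data))
    assert (n_filled, n_smoothed) == (9267, 9261)
    assert ratio == pytest.approx(9261 / 9267)
    assert not opened_away


def test_sphere_outer_integrity_curvature_limited():
    zz, yy, xx = np.ogrid[0:21, 0:21, 0:21]
    sphere = (zz - 10) ** 2 + (yy - 10) ** 2 + (xx - 10) ** 2 <= 64
    n_filled, n_smoothed, ratio, _ = outer_integrity(mask_of(sphere))
    expected = brute_open(brute_fill_holes(sphere, 6), np.ones((3, 3, 3), bool)).sum()
    assert n_smoothed == expected
    assert 0.95 <= ratio < 1.0


def test_tiny_specimen_opened_away_flagged():
    data = np.zeros((7, 7, 7), dtype=bool)
    data[3, 3, 3] = True
    with pytest.warns(UserWarning, match="removed by opening"):
        n_filled, n_smoothed, ratio, opened_away = outer_integrity(mask_of(data))
    assert ratio == 0.0 and opened_away


def test_empty_mask_is_an_error():
    empty = mask_of(np.zeros((5, 5, 5), bool))
    with pytest.raises(ValueError, match="empty"):
        inner_integrity(empty)
    with pytest.raises(ValueError, match="empty"):
        outer_integrity(empty)


@pytest.mark.parametrize("scores,expected", [
    ((0, 1, 1), 1),
    ((2, 2, 0), 2),
    ((1, 2), 1),       # even count: lower median keeps the score attainable
    ((0,), 0),
])
def test_compression_median(scores, expected):
    assert aggregate_compression(CompressionScores(scores)) == expected


def test_compression_validation():
    with pytest.raises(ValueError, match="at least one"):
        CompressionScores(())
    with pytest.raises(ValueError, match="in \\{0, 1, 2\\}"):
        CompressionScores((0, 3))


def test_summary_composes_cavity_and_spike():
    """Each summary field equals the value from the individually tested ops."""
    data = solid_cube(21, 31).data.copy()
    data[13:18, 13:18, 13:18] = False     # cavity: inner defect
    data[15, 15, 26:30] = True            # 4-voxel spike: outer defect
    summary = summarize_specimen(mask_of(data), scores=CompressionScores((1, 2, 1)))
    n_seg, n_closed, n_filled_inner, inner = inner_integrity(mask_of(data))
    n_filled_outer, n_smoothed, outer, _ = outer_integrity(mask_of(data))
    assert summary.n_seg == n_seg == 9140
    assert summary.inner_integrity == inner
    assert summary.outer_integrity == outer
    assert summary.n_filled_outer == n_filled_outer
    assert summary.compression_score == 1
    assert summary.n_seg <= summary.n_closed <= summary.n_filled_inner
    assert summary.n_smoothed <= summary.n_filled_outer


def test_summary_ratios_bounded_on_random_masks(rng):
    for _ in range(20):
        mask = random_mask(rng, dims=(14, 14, 14), density=0.6)
        if mask.n_foreground == 0:
            continue
        summary = summarize_specimen(mask)
        assert 0 < summary.inner_integrity <= 1
        assert 0 <= summary.outer_integrity <= 1


def test_generator_void_fraction_recovered():
    """Designed enclosed-void fraction f is read back as inner = 1 - f."""
    from biopsy3d import Ellipsoid, PhantomSpec, generate_phantom

    spec = PhantomSpec(
        voids=(Ellipsoid(center=(35.5, 27.5, 22.0), semi_axes=(5.0, 4.0, 4.0)),),
        rng_seed=11)
    _, truth_mask, truth = generate_phantom(spec)
    summary = summarize_specimen(truth_mask)
    f = truth.true_enclosed_void_voxels / (
        truth.true_tissue_voxels + truth.true_enclosed_void_voxels)
    assert summary.inner_integrity == pytest.approx(1 - f, abs=0.005)
    assert truth.expected_inner_integrity == pytest.approx(1 - f)
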