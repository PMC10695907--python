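"""Phantom generator: exact truth, determinism, designed-contrast presets."""

import numpy as np
import pytest

from biopsy3d import (Ellipsoid, PhantomSpec, Pinch, SeedPoint, Slit, Spike,
                      generate_group_cohort, generate_phantom, region_grow,
                      summarize_specimen)
from biopsy3d.phantom import PhantomSpecError


def _dice(a, b):
    return 2 * (a & b).sum() / (a.sum() + b.sum())


def test_same_seed_is_bit_identical():
    spec = PhantomSpec(rng_seed=5)
    v1, m1, t1 = generate_phantom(spec)
    v2, m2, t2 = generate_phantom(spec)
    np.testing.assert_array_equal(v1.data, v2.data)
    np.testing.assert_array_equal(m1.data, m2.data)
    assert t1 == t2


def test_truth_conservation_and_volume():
    _, mask, truth = generate_phantom(PhantomSpec(rng_seed=3))
    assert truth.true_tissue_voxels == mask.n_foreground
    assert truth.true_volume_mm3 == pytest.approx(mask.n_foreground * 8e-9)


def test_defect_free_phantom_measures_perfect_integrity():
    _, mask, truth = generate_phantom(PhantomSpec(rng_seed=4))
    summary = summarize_specimen(mask)
    assert summary.inner_integrity == 1.0
    assert summary.outer_integrity == 1.0
    assert truth.expected_inner_integrity == 1.0


def test_wide_void_truth_recovered_by_pipeline():
    spec = PhantomSpec(
        voids=(Ellipsoid(center=(30.0, 27.5, 27.5), semi_axes=(3.5, 3.5, 3.5)),),
        rng_seed=6)
    volume, mask, truth = generate_phantom(spec)
    v = truth.true_enclosed_void_voxels
    t = truth.true_tissue_voxels
    assert truth.expected_inner_integrity == pytest.approx(1 - v / (t + v))
    # on the exact mask the recovery is exact; through segmentation, near-exact
    assert summarize_specimen(mask).inner_integrity == pytest.approx(
        truth.expected_inner_integrity)
    from biopsy3d.phantom import deepest_tissue_voxel
    grown = region_grow(volume, SeedPoint(*deepest_tissue_voxel(mask.data)))
    measured = summarize_specimen(grown).inner_integrity
    assert measured == pytest.approx(truth.expected_inner_integrity, abs=0.005)


def test_thin_crack_closed_by_kernel_and_counted():
    spec = PhantomSpec(
        thin_cracks=(Slit(center=(35.5, 27.5, 27.5), normal_axis=0,
                          thickness=2, half_extent=4),),
        rng_seed=8)
    _, mask, truth = generate_phantom(spec)
    assert truth.true_thin_crack_voxels == 2 * 9 * 9
    summary = summarize_specimen(mask)
    # the crack is repaired by closing alone, before hole filling
    assert summary.n_closed >= summary.n_seg + truth.true_thin_crack_voxels
    assert summary.inner_integrity == pytest.approx(truth.expected_inner_integrity,
                                                    abs=1e-3)


def test_spikes_reduce_outer_integrity_as_designed():
    spec = PhantomSpec(
        spikes=tuple(Spike(axis=2, direction=1, transverse=(30 + 2 * i, 24 + i),
                           length=4) for i in range(4)),
        rng_seed=9)
    _, mask, truth = generate_phantom(spec)
    assert truth.true_spike_voxels == 16
    summary = summarize_specimen(mask)
    expected = 1 - truth.true_spike_voxels / (
        truth.true_tissue_voxels + truth.true_enclosed_void_voxels)
    assert summary.outer_integrity == pytest.approx(expected, abs=0.005)
    assert summary.outer_integrity >= truth.expected_outer_integrity_lower_bound


@pytest.mark.parametrize("bad_spec,message", [
    (PhantomSpec(voids=(Ellipsoid(center=(35.5, 27.5, 40.0),
                                  semi_axes=(3.0, 3.0, 3.0)),)),
     "voids\\[0\\]"),
    (PhantomSpec(pinches=(Pinch(center=(35.5, 27.5, 45.0), radius=3.0,
                                intensity_boost=40.0),)),
     "pinches\\[0\\]"),
    (PhantomSpec(noise_sd=30.0), "contrast"),
    (PhantomSpec(body=Ellipsoid(center=(35.5, 27.5, 27.5),
                                semi_axes=(35.0, 14.0, 14.0))),
     "margin"),
    (PhantomSpec(voids=(Ellipsoid(center=(35.5, 27.5, 27.5),
                                  semi_axes=(1.0, 3.0, 3.0)),)),
     "thin_cracks"),
])
def test_invalid_specs_name_the_offending_field(bad_spec, message):
    with pytest.raises(PhantomSpecError, match=message):
        generate_phantom(bad_spec)


def test_void_growth_monotonically_degrades_inner_integrity():
    inners = []
    for semi in (2.5, 3.5, 4.5, 5.5):
        spec = PhantomSpec(
            voids=(Ellipsoid(center=(30.0, 27.5, 27.5), semi_axes=(semi,) * 3),),
            rng_seed=10)
        _, mask, _ = generate_phantom(spec)
        inners.append(summarize_specimen(mask).inner_integrity)
    assert all(a > b for a, b in zip(inners, inners[1:]))


def test_spike_count_monotonically_degrades_outer_integrity():
    outers = []
    for n in (0, 3, 6, 9):
        spikes = tuple(Spike(axis=1, direction=1, transverse=(28 + 2 * i, 24 + i),
                             length=5) for i in range(n))
        _, mask, _ = generate_phantom(PhantomSpec(spikes=spikes, rng_seed=12))
        outers.append(summarize_specimen(mask).outer_integrity)
    assert all(a > b for a, b in zip(outers, outers[1:]))


def test_cohort_determinism_and_ids():
    c1 = generate_group_cohort("cn_like", 3, base_seed=77)
    c2 = generate_group_cohort("cn_like", 3, base_seed=77)
    for a, b in zip(c1, c2):
        np.testing.assert_array_equal(a.volume.data, b.volume.data)
        assert a.observer_scores == b.observer_scores
    assert [c.specimen_id for c in c1] == ["cn_like-000", "cn_like-001", "cn_like-002"]


def test_control_cohort_measures_high_integrity():
    for cs in generate_group_cohort("cn_like", 6, base_seed=42):
        grown = region_grow(cs.volume, SeedPoint(*cs.seed_point))
        summary = summarize_specimen(grown)
        assert summary.inner_integrity >= 0.97
        assert summary.outer_integrity >= 0.97


def test_cohort_segmentability_dice(rng):
    """Region growing with defaults recovers every phantom at Dice >= 0.99."""
    for preset, seed in (("cn_like", 300), ("b1_like", 310), ("b2_like", 320)):
        for cs in generate_group_cohort(preset, 4, base_seed=seed):
            grown = region_grow(cs.volume, SeedPoint(*cs.seed_point))
            assert _dice(grown.data, cs.truth_mask.data) >= 0.99


def test_designed_group_contrast_on_inner_integrity():
    from biopsy3d import mann_whitney

    def inner_values(preset, n, seed):
        values = []
        for cs in generate_group_cohort(preset, n, base_seed=seed):
            grown = region_grow(cs.volume, SeedPoint(*cs.seed_point))
            values.append(summarize_specimen(grown).inner_integrity)
        return values

    cn = inner_values("cn_like", 6, 500)
    b2 = inner_values("b2_like", 10, 510)
    b1 = inner_values("b1_like", 10, 520)
    assert mann_whitney(b2, cn).p_two_sided < 0.05
    assert mann_whitney(b1, cn).p_two_sided >= 0.05


def test_unknown_preset_rejected():
    with pytest.raises(ValueError, match="unknown preset"):
        generate_group_cohort("b3_like", 2, base_seed=1)
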