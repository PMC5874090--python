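"""Mutual information, reference volume, surrogate and phase sorting."""

import numpy as np
import pytest

from pancmotion.recon import (
    SurrogateSignal,
    assign_phases,
    build_reference_volume,
    extract_surrogate,
    mutual_information,
    reconstruct_4d,
)
from pancmotion.types import DynamicSliceSeries


def brute_force_mi(a, b, n_bins):
    """Independent MI oracle: explicit joint-histogram double loop."""

    def scaled(x):
        x = np.asarray(x, float).ravel()
        lo, hi = x.min(), x.max()
        return np.zeros_like(x) if hi == lo else (x - lo) / (hi - lo)

    xa, xb = scaled(a), scaled(b)
    joint = np.zeros((n_bins, n_bins))
    for va, vb in zip(xa, xb):
        ia = min(int(va * n_bins), n_bins - 1)
        ib = min(int(vb * n_bins), n_bins - 1)
        joint[ia, ib] += 1
    p = joint / joint.sum()
    mi = 0.0
    for i in range(n_bins):
        for j in range(n_bins):
            if p[i, j] > 0:
                mi += p[i, j] * np.log2(p[i, j] / (p[i].sum() * p[:, j].sum()))
    return mi


def test_mi_equals_brute_force_on_random_images():
    rng = np.random.default_rng(0)
    for _ in range(10):
        a = rng.random((16, 16))
        b = rng.random((16, 16))
        assert abs(mutual_information(a, b, 8) - brute_force_mi(a, b, 8)) < 1e-12


def test_mi_of_constant_image_is_zero():
    c = np.full((8, 8), 3.5)
    assert mutual_information(c, c, 16) == 0.0
    assert mutual_information(c, np.random.default_rng(1).random((8, 8)), 16) == 0.0


def test_mi_self_information_of_two_level_image_is_one_bit():
    img = np.zeros((8, 8))
    img[:, 4:] = 7.0  # two equally frequent levels -> H = 1 bit
    assert abs(mutual_information(img, img, 8) - 1.0) < 1e-12


def test_mi_symmetry_and_nonnegativity():
    rng = np.random.default_rng(3)
    a, b = rng.random((12, 12)), rng.random((12, 12))
    mab = mutual_information(a, b, 6)
    assert mab >= 0.0
    assert abs(mab - mutual_information(b, a, 6)) < 1e-12


def test_mi_independent_noise_has_small_bias():
    rng = np.random.default_rng(4)
    a, b = rng.random((64, 64)), rng.random((64, 64))
    # chance MI of independent images is bounded by the histogram bias
    assert mutual_information(a, b, 8) < 0.05


def _toy_series(n_slices=2, n_meas=3, corrupt=(1, 0), seed=0):
    """Tiny series: one measurement per position is heavily corrupted."""
    rng = np.random.default_rng(seed)
    base = rng.random((16, 16))
    images, slice_idx, times = [], [], []
    t = 0.0
    for m in range(n_meas):
        for z in range(n_slices):
            img = np.roll(base, z, axis=0) + rng.normal(0, 0.02, base.shape)
            if m == corrupt[z]:
                img = rng.random((16, 16))  # destroys shared structure
            images.append(img)
            slice_idx.append(z)
            times.append(t)
            t += 100.0
    return DynamicSliceSeries(
        images=np.array(images),
        slice_index=np.array(slice_idx),
        time_ms=np.array(times),
        spacing_mm=(1.0, 1.0, 1.0),
        n_slices=n_slices,
        n_measurements=n_meas,
    )


def test_reference_pair_matches_exhaustive_argmax():
    series = _toy_series()
    ref = build_reference_volume(series, n_bins=16)
    g0, g1 = series.group(0), series.group(1)
    table = np.array(
        [
            [mutual_information(series.images[i], series.images[j], 16) for j in g1]
            for i in g0
        ]
    )
    bi, bj = np.unravel_index(int(np.argmax(table)), table.shape)
    assert tuple(ref.chosen_measurement) == (bi, bj)


def test_reference_avoids_corrupted_measurements():
    series = _toy_series(n_slices=4, n_meas=5, corrupt=(0, 3, 1, 4), seed=2)
    ref = build_reference_volume(series, n_bins=16)
    for z, bad in enumerate((0, 3, 1, 4)):
        assert ref.chosen_measurement[z] != bad


def test_reference_requires_all_slice_positions():
    series = _toy_series()
    series.slice_index[:] = 0  # position 1 now missing
    series.n_slices = 2
    with pytest.raises(ValueError, match="no measurements"):
        build_reference_volume(series, n_bins=16)


def test_surrogate_peaks_at_reference_slice():
    series = _toy_series(n_slices=2, n_meas=4, corrupt=(3, 3), seed=5)
    ref = build_reference_volume(series, n_bins=16)
    sig = extract_surrogate(series, ref, n_bins=16)
    for z in range(2):
        g = series.group(z)
        chosen = g[ref.chosen_measurement[z]]
        assert sig.values[chosen] == max(sig.values[g])


def _synthetic_surrogate(n_slices=2, per_cycle=6, n_cycles=4, phase0=0.0):
    """Surrogate sampled exactly per_cycle times per cycle, minima at f=0."""
    values, times, slices = [], [], []
    t = 0.0
    for m in range(per_cycle * n_cycles):
        f = (m / per_cycle + phase0) % 1.0
        for z in range(n_slices):
            values.append(-np.cos(2 * np.pi * f + np.pi))  # minimum at f = 0
            times.append(t)
            slices.append(z)
            t += 1.0
    return SurrogateSignal(np.array(values), np.array(times), np.array(slices))


def test_phase_bins_receive_equal_counts_on_exact_sampling():
    sig = _synthetic_surrogate()
    labels = assign_phases(sig, 6)
    counts = np.bincount(labels, minlength=7)[1:]
    assert counts.min() == counts.max()


def test_phase_assignment_invariant_to_full_period_time_shift():
    sig = _synthetic_surrogate()
    shifted = SurrogateSignal(sig.values, sig.times_ms + 6.0 * 2, sig.slice_index)
    assert np.array_equal(assign_phases(sig, 6), assign_phases(shifted, 6))


def test_flat_surrogate_raises():
    sig = SurrogateSignal(np.ones(24), np.arange(24.0), np.zeros(24, int))
    with pytest.raises(ValueError):
        assign_phases(sig, 6)


def _labelled_series(n_slices=3, n_phases=4, reps=2):
    rng = np.random.default_rng(0)
    images, slices, times, labels = [], [], [], []
    t = 0.0
    for r in range(reps):
        for p in range(1, n_phases + 1):
            for z in range(n_slices):
                images.append(np.full((4, 4), float(10 * p + z)) + rng.normal(0, 0.01, (4, 4)))
                slices.append(z)
                times.append(t)
                labels.append(p)
                t += 1.0
    series = DynamicSliceSeries(
        images=np.array(images),
        slice_index=np.array(slices),
        time_ms=np.array(times),
        spacing_mm=(1.0, 1.0, 1.0),
        n_slices=n_slices,
        n_measurements=n_phases * reps,
    )
    return series, np.array(labels)


def test_reconstruct_averages_members_and_logs_nothing_when_full():
    series, labels = _labelled_series()
    vol = reconstruct_4d(series, labels, n_phases=4)
    assert vol.fill_log == []
    for p in range(4):
        for z in range(3):
            members = [
                series.images[i]
                for i in range(len(series))
                if labels[i] == p + 1 and series.slice_index[i] == z
            ]
            assert np.allclose(vol.phases[p][:, :, z], np.mean(members, axis=0))


def test_gap_fill_uses_cyclic_nearest_with_earlier_tie():
    series, labels = _labelled_series(n_slices=2, n_phases=4, reps=1)
    # empty cell (phase 3, slice 0): donors at distance 1 are phases 2 and 4
    labels = labels.copy()
    sel = (labels == 3) & (series.slice_index == 0)
    labels[sel] = 2
    vol = reconstruct_4d(series, labels, n_phases=4)
    assert (0, 3, 2) in vol.fill_log  # earlier phase wins the tie
    assert np.allclose(vol.phases[2][:, :, 0], vol.phases[1][:, :, 0])


def test_slice_empty_in_all_phases_raises():
    series, labels = _labelled_series(n_slices=2, n_phases=3, reps=1)
    labels = labels.copy()
    labels[series.slice_index == 1] = 0  # label 0 never matches any phase
    with pytest.raises(ValueError, match="empty in all phases"):
        reconstruct_4d(series, labels, n_phases=3)


def test_labels_must_cover_series():
    series, labels = _labelled_series()
    with pytest.raises(ValueError):
        reconstruct_4d(series, labels[:-1], n_phases=4)
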