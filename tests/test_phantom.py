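"""Phantom generator and dynamic-acquisition simulator."""

import numpy as np
import pytest

from pancmotion.motion import com_trajectory
from pancmotion.phantom import (
    AcqConfig,
    PhantomConfig,
    breathing_phase,
    generate_phantom,
    simulate_dynamic_acquisition,
    slice_schedule,
)

ZERO_AMP = {s: (0.0, 0.0, 0.0) for s in ("head", "body", "tail")}


def test_zero_amplitude_freezes_all_phases():
    ph = generate_phantom(PhantomConfig(amplitude_mm=dict(ZERO_AMP)), with_intensity=False)
    for m in ph.masks.masks[1:]:
        assert np.array_equal(m, ph.masks.masks[0])
    for s, d in ph.truth_displacement_mm.items():
        assert np.all(d == 0.0), s


def test_truth_com_trace_follows_waveform_exactly():
    wf = (1.0, 0.6, 0.0, 0.1, 0.5, 0.9)
    amp = {s: (2.5, 2.5, 2.5) for s in ("head", "body", "tail")}
    ph = generate_phantom(
        PhantomConfig(amplitude_mm=amp, phase_waveform=wf), with_intensity=False
    )
    for s in ("pancreas", "head", "body", "tail"):
        trace = ph.truth_com_mm[s][:, 2]
        base = trace[2]  # waveform is 0 at phase 3
        assert np.allclose(trace - base, 2.5 * np.asarray(wf), atol=1e-12)


def test_voxelised_com_matches_analytic_truth(default_phantom):
    half_voxel = np.asarray(default_phantom.config.spacing_mm) / 2.0
    for s in ("pancreas", "head", "body", "tail"):
        traj = com_trajectory(
            default_phantom.structure_masks(s), default_phantom.config.spacing_mm
        )
        err = np.abs(traj - default_phantom.truth_com_mm[s])
        assert np.all(err < half_voxel), s


def test_oversized_amplitude_names_phase_and_axis():
    amp = dict(ZERO_AMP)
    amp["tail"] = (0.0, 0.0, 500.0)
    with pytest.raises(ValueError, match="phase 1.*axis SI"):
        generate_phantom(PhantomConfig(amplitude_mm=amp), with_intensity=False)


def test_whole_voxel_shift_conserves_voxel_count():
    # LL shifts that are exact voxel multiples at every phase
    sp = PhantomConfig().spacing_mm
    amp = {s: (2 * sp[0], 0.0, 0.0) for s in ("head", "body", "tail")}
    wf = (1.0, 0.5, 0.0, 0.0, 0.5, 1.0)
    ph = generate_phantom(
        PhantomConfig(amplitude_mm=amp, phase_waveform=wf), with_intensity=False
    )
    counts = {m.sum() for m in ph.masks.masks}
    assert len(counts) == 1


def test_truth_displacement_scales_linearly_with_amplitude():
    amp1 = {s: (1.0, 0.5, 2.0) for s in ("head", "body", "tail")}
    amp2 = {s: (2.0, 1.0, 4.0) for s in ("head", "body", "tail")}
    d1 = generate_phantom(
        PhantomConfig(amplitude_mm=amp1), with_intensity=False
    ).truth_displacement_mm
    d2 = generate_phantom(
        PhantomConfig(amplitude_mm=amp2), with_intensity=False
    ).truth_displacement_mm
    for s in d1:
        assert np.allclose(d2[s], 2.0 * d1[s], atol=1e-12)


def test_same_seed_bit_identical_other_seed_differs_only_in_noise():
    a = generate_phantom(PhantomConfig(seed=5))
    b = generate_phantom(PhantomConfig(seed=5))
    c = generate_phantom(PhantomConfig(seed=6))
    for va, vb, vc in zip(a.intensity, b.intensity, c.intensity):
        assert np.array_equal(va, vb)
        assert not np.array_equal(va, vc)
    for ma, mc in zip(a.masks.masks, c.masks.masks):
        assert np.array_equal(ma, mc)  # anatomy independent of the noise seed
    for va, vc in zip(a.intensity_clean, c.intensity_clean):
        assert np.array_equal(va, vc)


def test_simulation_emits_expected_slice_count(default_phantom):
    ph = generate_phantom(PhantomConfig(seed=1))
    series = simulate_dynamic_acquisition(ph, AcqConfig(seed=1))
    assert len(series) == 25 * 30
    assert series.n_slices == 25 and series.n_measurements == 30
    counts = np.bincount(series.slice_index, minlength=25)
    assert np.all(counts == 30)


def test_zero_motion_zero_noise_series_is_constant_per_slice():
    cfg = PhantomConfig(amplitude_mm=dict(ZERO_AMP), noise_sd=0.0)
    ph = generate_phantom(cfg)
    series = simulate_dynamic_acquisition(ph, AcqConfig(n_measurements=4, seed=0))
    for z in range(series.n_slices):
        g = series.group(z)
        for i in g[1:]:
            assert np.array_equal(series.images[i], series.images[g[0]])


def test_true_phases_equal_analytic_phase_of_timestamps():
    ph = generate_phantom(PhantomConfig(seed=2))
    acq = AcqConfig(seed=2, breathing_period_s=5.5, slice_order="sequential")
    series = simulate_dynamic_acquisition(ph, acq)
    # independent closed form: quantise the cycle fraction of each timestamp
    frac = (series.time_ms / 1000.0 / acq.breathing_period_s) % 1.0
    expected = (np.rint(frac * 6).astype(int) % 6) + 1
    assert np.array_equal(series.true_phase, expected)


def test_interleaved_schedule_covers_all_positions():
    acq = AcqConfig(n_slices=7)
    order = slice_schedule(acq)
    assert sorted(order.tolist()) == list(range(7))
    assert order.tolist() == [0, 2, 4, 6, 1, 3, 5]


def test_breathing_phase_is_periodic():
    t = np.array([0.0, 100.0, 900.0])
    period = 4.0
    a = breathing_phase(t, period, 6)
    b = breathing_phase(t + period * 1000.0, period, 6)
    assert np.array_equal(a, b)


@pytest.mark.parametrize(
    "kwargs",
    [
        {"n_phases": 1},
        {"segment_fractions": (0.5, 0.5, 0.5)},
        {"phase_waveform": (1.0, 0.0)},
        {"noise_sd": -1.0},
    ],
)
def test_invalid_phantom_config_rejected(kwargs):
    with pytest.raises(ValueError):
        PhantomConfig(**kwargs)


def test_invalid_acq_config_rejected():
    with pytest.raises(ValueError):
        AcqConfig(breathing_period_s=0.1)
    with pytest.raises(ValueError):
        AcqConfig(slice_order="spiral")
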