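"""Digital 4D breathing phantom of the pancreas and dynamic MR simulator.

The phantom emulates the data a respiratory-resolved abdominal MR study
produces: a three-lobed, pancreas-like gland (head, body, tail modelled
as separated ellipsoids along the LL axis) that moves quasi-rigidly over
a breathing cycle sampled at a small number of phases, embedded in a
smoothly structured abdominal background that breathes with it.  Each
segment is displaced rigidly by ``amplitude * waveform[phase]``; the
displacement is applied to the continuous ellipsoid centre before
voxelisation, so masks stay binary and ground-truth centre-of-mass (COM)
positions are known analytically.

The acquisition simulator reproduces a dynamic interleaved multi-slice
protocol: every axial slice position is imaged repeatedly during free
breathing, each 2D image drawn from the phantom phase active at its
acquisition time, with additive Gaussian noise.  Ground-truth phase
labels are stored per slice so retrospective sorting can be validated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter, shift as ndimage_shift

from pancmotion.types import AXES, STRUCTURES, DynamicSliceSeries, Mask4D

#: Peak-to-trough motion amplitude (mm) per segment along (LL, AP, SI).
#: LL and SI exceed AP, and the tail moves 1.5x the head, reflecting the
#: direction- and segment-dependence expected for the pancreas.
DEFAULT_AMPLITUDES_MM = {
    "head": (2.0, 0.8, 2.4),
    "body": (2.5, 1.0, 3.0),
    "tail": (3.0, 1.2, 3.6),
}

#: Fractional gland displacement per phase, phase 1 = end inhalation.
#: The cycle has the two canonical features of relaxed breathing: a long,
#: flat exhale plateau (flattest around phase 3, which therefore becomes
#: the most stable reference phase) and a short, sharp inhale peak (so
#: end inhalation is the isolated extreme state of the cycle).
DEFAULT_WAVEFORM = (1.0, 0.20, 0.06, 0.10, 0.30, 0.55)

_SEGMENTS = ("head", "body", "tail")

# Fixed abdominal-background geometry (blob centres/sizes/amplitudes and
# the tissue texture are part of the phantom anatomy, not of the random
# noise, so they must not change with the user seed).
_BACKGROUND_RNG_SEED = 424_242
_N_BACKGROUND_BLOBS = 16
_TEXTURE_AMPLITUDE = 0.15
# sharp in plane (so millimetre shifts decorrelate, giving the MI
# surrogate its respiratory sensitivity) but smooth across slices (so
# adjacent slice positions share structure and the reference chain stays
# on one respiratory state)
_TEXTURE_SIGMA_VOX = (1.5, 1.5, 2.0)


@dataclass
class PhantomConfig:
    """Geometry, motion and noise parameters of the digital phantom.

    Defaults give a ~40 cc three-lobed gland on a 128 x 64 x 25 grid at
    1.17 x 1.17 x 4 mm voxels, moving over a 6-phase cycle with larger
    LL/SI than AP excursions and a tail that moves 1.5x the head.
    """

    grid_shape: tuple[int, int, int] = (128, 64, 25)
    spacing_mm: tuple[float, float, float] = (1.17, 1.17, 4.0)
    n_phases: int = 6
    amplitude_mm: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_AMPLITUDES_MM)
    )
    phase_waveform: tuple[float, ...] = DEFAULT_WAVEFORM
    segment_fractions: tuple[float, float, float] = (0.40, 0.31, 0.29)
    #: rigid offset of the whole gland (mm), emulating inter-scan
    #: repositioning; sub-voxel values decorrelate voxelisation error
    #: between repeated acquisitions
    origin_offset_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    noise_sd: float = 0.05
    contrast: float = 1.5
    position_label: str = "supine"
    device_label: str = "vacuum"
    seed: int = 0

    def __post_init__(self) -> None:
        if any(int(n) <= 0 for n in self.grid_shape):
            raise ValueError("grid_shape entries must be positive")
        if self.n_phases < 2:
            raise ValueError("n_phases must be >= 2")
        if len(self.phase_waveform) != self.n_phases:
            raise ValueError("phase_waveform length must equal n_phases")
        if abs(sum(self.segment_fractions) - 1.0) > 1e-9:
            raise ValueError("segment_fractions must sum to 1")
        for seg in _SEGMENTS:
            if seg not in self.amplitude_mm:
                raise ValueError(f"amplitude_mm missing segment {seg!r}")
            if any(a < 0 for a in self.amplitude_mm[seg]):
                raise ValueError("amplitudes must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class AcqConfig:
    """Dynamic interleaved multi-slice acquisition parameters.

    Defaults follow a free-breathing axial protocol of 30 measurements of
    each of 25 slices at 216.97 ms per 2D image (~162 s total).
    """

    n_slices: int = 25
    n_measurements: int = 30
    slice_time_ms: float = 216.97
    slice_order: str = "interleaved"
    breathing_period_s: float = 4.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_slices <= 0 or self.n_measurements <= 0:
            raise ValueError("slice and measurement counts must be positive")
        if self.slice_order not in ("interleaved", "sequential"):
            raise ValueError("slice_order must be 'interleaved' or 'sequential'")
        if self.breathing_period_s * 1000.0 <= 2.0 * self.slice_time_ms:
            raise ValueError("breathing period must exceed twice the slice time")


@dataclass
class Phantom4D:
    """Generated phantom: per-phase masks, intensities and ground truth.

    ``truth_com_mm[s]`` is an ``(n_phases, 3)`` array of analytic COM
    positions for structure ``s``; ``truth_displacement_mm`` holds the
    same trajectories referenced to ``reference_phase`` (1-based label,
    the flattest phase of the waveform).
    """

    masks: Mask4D
    segment_labels: list[np.ndarray]
    intensity: list[np.ndarray]
    intensity_clean: list[np.ndarray]
    truth_com_mm: dict[str, np.ndarray]
    truth_displacement_mm: dict[str, np.ndarray]
    reference_phase: int
    config: PhantomConfig

    @property
    def n_phases(self) -> int:
        return self.masks.n_phases

    def structure_masks(self, structure: str) -> list[np.ndarray]:
        """Binary per-phase masks of one structure (gland or a segment)."""
        if structure == "pancreas":
            return self.masks.masks
        if structure not in _SEGMENTS:
            raise ValueError(f"unknown structure {structure!r}")
        code = _SEGMENTS.index(structure) + 1
        return [lab == code for lab in self.segment_labels]


def _segment_geometry(cfg: PhantomConfig):
    """Base ellipsoid centres (mm) and semi-axes (mm) for the three lobes."""
    extent = np.asarray(cfg.grid_shape, float) * np.asarray(cfg.spacing_mm, float)
    gland_len = 0.72 * extent[0]
    start = (extent[0] - gland_len) / 2.0
    # Cross-sections: head is the bulkiest lobe, tail the slimmest.
    cross = {"head": (15.0, 21.0), "body": (11.0, 16.0), "tail": (10.0, 15.0)}
    ap_offset = {"head": -5.0, "body": 0.0, "tail": 4.0}
    centers, semi = {}, {}
    pos = start
    for seg, frac in zip(_SEGMENTS, cfg.segment_fractions):
        seg_len = gland_len * frac
        centers[seg] = np.array(
            [pos + seg_len / 2.0, extent[1] / 2.0 + ap_offset[seg], extent[2] / 2.0]
        )
        semi[seg] = np.array([0.42 * seg_len, cross[seg][0], cross[seg][1]])
        pos += seg_len
    return centers, semi, extent


def _voxel_center_grids(cfg: PhantomConfig):
    sp = np.asarray(cfg.spacing_mm, float)
    coords = [
        (np.arange(n, dtype=float) + 0.5) * s for n, s in zip(cfg.grid_shape, sp)
    ]
    return np.meshgrid(*coords, indexing="ij")


def _background_field(cfg: PhantomConfig, grids, shift_mm: np.ndarray) -> np.ndarray:
    """Smooth abdominal-like background: Gaussian blobs breathing rigidly."""
    rng = np.random.default_rng(_BACKGROUND_RNG_SEED)
    extent = np.asarray(cfg.grid_shape, float) * np.asarray(cfg.spacing_mm, float)
    centers = rng.uniform(0.0, 1.0, size=(_N_BACKGROUND_BLOBS, 3)) * extent
    amps = rng.uniform(0.2, 0.5, size=_N_BACKGROUND_BLOBS)
    sigmas = rng.uniform(8.0, 25.0, size=_N_BACKGROUND_BLOBS)
    out = np.zeros(cfg.grid_shape, dtype=float)
    for c, a, s in zip(centers, amps, sigmas):
        cc = c + shift_mm
        d2 = sum((g - ci) ** 2 for g, ci in zip(grids, cc))
        out += a * np.exp(-d2 / (2.0 * s * s))
    return out


def _tissue_texture(cfg: PhantomConfig) -> np.ndarray:
    """Fixed band-limited texture emulating fine tissue detail."""
    rng = np.random.default_rng(_BACKGROUND_RNG_SEED + 1)
    tex = gaussian_filter(
        rng.standard_normal(cfg.grid_shape), sigma=_TEXTURE_SIGMA_VOX
    )
    sd = tex.std()
    return _TEXTURE_AMPLITUDE * tex / (sd if sd > 0 else 1.0)


def generate_phantom(
    config: PhantomConfig | None = None, with_intensity: bool = True
) -> Phantom4D:
    """Build the 4D phantom: per-phase masks, intensities and ground truth.

    Each lobe is voxelised from its displaced continuous ellipsoid, so a
    segment's analytic COM (``truth_com_mm``) is exact by construction and
    the voxel-mask COM agrees with it to well under half a voxel.
    ``with_intensity=False`` skips the MR intensity volumes (masks and
    ground truth only), which is enough for motion/statistics cohorts.

    Raises
    ------
    ValueError
        If the configured motion pushes a segment outside the grid; the
        message names the offending phase and axis.
    """
    from pancmotion.motion import com_stability  # local import, no cycle

    cfg = config or PhantomConfig()
    centers, semi, extent = _segment_geometry(cfg)
    grids = _voxel_center_grids(cfg)
    waveform = np.asarray(cfg.phase_waveform, float)

    seg_masks: list[dict[str, np.ndarray]] = []
    truth = {s: np.zeros((cfg.n_phases, 3)) for s in STRUCTURES}
    analytic_vol = {
        s: 4.0 / 3.0 * np.pi * float(np.prod(semi[s])) for s in _SEGMENTS
    }
    total_vol = sum(analytic_vol.values())

    for p in range(cfg.n_phases):
        phase_masks = {}
        for seg in _SEGMENTS:
            disp = np.asarray(cfg.amplitude_mm[seg], float) * waveform[p]
            c = centers[seg] + np.asarray(cfg.origin_offset_mm, float) + disp
            for ax in range(3):
                if c[ax] - semi[seg][ax] < 0 or c[ax] + semi[seg][ax] > extent[ax]:
                    raise ValueError(
                        f"segment {seg!r} leaves the grid at phase {p + 1} "
                        f"along axis {AXES[ax]}"
                    )
            d2 = sum(
                ((g - ci) / ai) ** 2 for g, ci, ai in zip(grids, c, semi[seg])
            )
            phase_masks[seg] = d2 <= 1.0
            truth[seg][p] = c
        seg_masks.append(phase_masks)
        truth["pancreas"][p] = (
            sum(analytic_vol[s] * truth[s][p] for s in _SEGMENTS) / total_vol
        )

    pancreas = [
        phase_masks["head"] | phase_masks["body"] | phase_masks["tail"]
        for phase_masks in seg_masks
    ]
    labels = []
    for phase_masks in seg_masks:
        lab = np.zeros(cfg.grid_shape, dtype=np.uint8)
        for code, seg in enumerate(_SEGMENTS, start=1):
            lab[phase_masks[seg]] = code
        labels.append(lab)

    # Reference phase: the flattest point of the waveform, i.e. the phase
    # with minimal cyclic 3D COM stability index of the whole gland.
    stab = com_stability(truth["pancreas"])
    ref = stab.reference_phase
    truth_disp = {s: truth[s] - truth[s][ref - 1] for s in STRUCTURES}

    rng = np.random.default_rng(cfg.seed)
    intensity_clean, intensity = [], []
    texture = _tissue_texture(cfg) if with_intensity else None
    sp = np.asarray(cfg.spacing_mm, float)
    for p in range(cfg.n_phases) if with_intensity else ():
        body_shift = (
            np.asarray(cfg.amplitude_mm["body"], float) * waveform[p]
        )
        vol = cfg.contrast * gaussian_filter(
            pancreas[p].astype(float), sigma=(1.0, 1.0, 0.5)
        )
        vol += _background_field(cfg, grids, body_shift)
        vol += ndimage_shift(texture, body_shift / sp, order=1, mode="nearest")
        intensity_clean.append(vol)
        intensity.append(vol + rng.normal(0.0, cfg.noise_sd, size=vol.shape))

    return Phantom4D(
        masks=Mask4D(pancreas, cfg.spacing_mm),
        segment_labels=labels,
        intensity=intensity,
        intensity_clean=intensity_clean,
        truth_com_mm=truth,
        truth_displacement_mm=truth_disp,
        reference_phase=ref,
        config=cfg,
    )


def slice_schedule(acq: AcqConfig) -> np.ndarray:
    """Slice positions in acquisition order for one full sweep."""
    idx = np.arange(acq.n_slices)
    if acq.slice_order == "interleaved":
        return np.concatenate([idx[::2], idx[1::2]])
    return idx


def breathing_phase(time_ms: np.ndarray, period_s: float, n_phases: int) -> np.ndarray:
    """Ground-truth phase label (1-based) at each acquisition time.

    The continuous cycle fraction ``t / period mod 1`` is quantised to the
    nearest of the ``n_phases`` sampled phantom phases (phase 1 centred at
    fraction 0, end inhalation).
    """
    frac = (np.asarray(time_ms, float) / 1000.0 / period_s) % 1.0
    return (np.rint(frac * n_phases).astype(int) % n_phases) + 1


def simulate_dynamic_acquisition(
    phantom: Phantom4D, acq: AcqConfig | None = None
) -> DynamicSliceSeries:
    """Simulate the dynamic interleaved acquisition of the phantom.

    Emits ``n_slices * n_measurements`` 2D axial images.  Each image is
    sampled from the clean intensity volume of the breathing phase active
    at its acquisition time, with fresh additive Gaussian noise
    (``config.noise_sd``) per image.
    """
    acq = acq or AcqConfig()
    cfg = phantom.config
    if cfg.grid_shape[2] < acq.n_slices:
        raise ValueError(
            f"phantom SI extent ({cfg.grid_shape[2]} slices) smaller than "
            f"n_slices ({acq.n_slices})"
        )
    order = slice_schedule(acq)
    n_total = acq.n_slices * acq.n_measurements
    g = np.arange(n_total)
    slice_idx = np.tile(order, acq.n_measurements)
    time_ms = g * acq.slice_time_ms
    labels = breathing_phase(time_ms, acq.breathing_period_s, cfg.n_phases)

    rng = np.random.default_rng(acq.seed)
    images = np.empty((n_total, cfg.grid_shape[0], cfg.grid_shape[1]))
    for i in range(n_total):
        img = phantom.intensity_clean[labels[i] - 1][:, :, slice_idx[i]]
        if cfg.noise_sd > 0:
            img = img + rng.normal(0.0, cfg.noise_sd, size=img.shape)
        images[i] = img

    return DynamicSliceSeries(
        images=images,
        slice_index=slice_idx,
        time_ms=time_ms,
        spacing_mm=cfg.spacing_mm,
        n_slices=acq.n_slices,
        n_measurements=acq.n_measurements,
        true_phase=labels,
    )
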