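"""Retrospective phase-sorted 4D reconstruction of dynamic MR slices.

Image-based sorting without any external breathing signal:

1. A *reference volume* is assembled by picking, per slice position, the
   repeated measurement that is most mutually informative with the
   measurement already chosen at the neighbouring position (greedy chain
   seeded at the central adjacent pair with an exhaustive search).
   Candidates are first restricted to the *typical* half of each
   position's measurements (highest median MI to the other measurements
   at the same position); relaxed breathing dwells on the exhale
   plateau, making it the densest -- most typical -- respiratory state,
   so the reference settles there coherently across slice positions.
2. Mutual information (MI) between every acquired slice and the
   reference slice at the same position forms an internal respiratory
   surrogate.
3. Within each slice-position group, cycle landmarks are detected on the
   surrogate and every slice receives a continuous cycle fraction by
   linear interpolation between landmarks, then a phase bin.  The state
   *most dissimilar* from the exhale-plateau reference is end
   inhalation, so surrogate minima anchor phase 1 and the label
   convention "phase 1 = end inhalation" holds by construction.
4. Per (phase, slice) cell, member slices are averaged into the 4D
   volume; empty cells borrow from the cyclically nearest populated
   phase (ties toward the earlier phase) and are logged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from pancmotion.types import DynamicSliceSeries

DEFAULT_MI_BINS = 64


def mutual_information(a: np.ndarray, b: np.ndarray, n_bins: int = DEFAULT_MI_BINS) -> float:
    """Mutual information (bits) of two equally shaped images.

    Each image is min-max scaled independently, the joint histogram taken
    on an ``n_bins x n_bins`` grid, and MI computed with base-2 logs.
    A constant image carries zero entropy, so the result is 0 without any
    degenerate division.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")

    def _scaled(x: np.ndarray) -> np.ndarray:
        lo, hi = x.min(), x.max()
        if hi == lo:
            return np.zeros(x.size)
        return (x.ravel() - lo) / (hi - lo)

    joint, _, _ = np.histogram2d(
        _scaled(a), _scaled(b), bins=n_bins, range=[[0, 1], [0, 1]]
    )
    p = joint / joint.sum()
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    nz = p > 0
    outer = np.outer(px, py)
    return float(np.sum(p[nz] * np.log2(p[nz] / outer[nz])))


@dataclass
class ReferenceVolume:
    """Reference stack: one chosen measurement per slice position."""

    volume: np.ndarray  # (nLL, nAP, n_slices)
    chosen_measurement: np.ndarray  # (n_slices,) measurement index per position
    spacing_mm: tuple[float, float, float]


@dataclass
class SurrogateSignal:
    """MI respiratory surrogate, one value per acquired slice (time order)."""

    values: np.ndarray
    times_ms: np.ndarray
    slice_index: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("surrogate contains non-finite values")


@dataclass
class Volume4D:
    """Phase-resolved reconstruction plus a log of gap-filled cells."""

    phases: list[np.ndarray]
    fill_log: list[tuple[int, int, int]]  # (slice_index, phase, donor_phase)
    spacing_mm: tuple[float, float, float]

    @property
    def n_phases(self) -> int:
        return len(self.phases)


def _grouped(series: DynamicSliceSeries) -> list[np.ndarray]:
    """Per slice position, time-ordered indices into the series; validates gaps."""
    groups = [series.group(z) for z in range(series.n_slices)]
    missing = [z for z, g in enumerate(groups) if len(g) == 0]
    if missing:
        raise ValueError(f"no measurements for slice positions {missing}")
    return groups


def _typical_candidates(
    series: DynamicSliceSeries, groups: list[np.ndarray], n_bins: int
) -> list[np.ndarray]:
    """Per position, the measurements in the typical (densest) state.

    A measurement's typicality is its median MI to the other measurements
    at the same slice position, computed on 2x-downsampled images for
    speed.  The upper half (>= group median typicality) is kept: relaxed
    breathing dwells on the exhale plateau, so these measurements sit on
    a single coherent respiratory state.  Positions with fewer than 4
    measurements are passed through unfiltered.
    """
    eligible = []
    for g in groups:
        if len(g) < 4:
            eligible.append(np.arange(len(g)))
            continue
        small = [series.images[i][::2, ::2] for i in g]
        typ = np.empty(len(g))
        for a in range(len(g)):
            typ[a] = np.median(
                [
                    mutual_information(small[a], small[b], n_bins)
                    for b in range(len(g))
                    if b != a
                ]
            )
        eligible.append(np.flatnonzero(typ >= np.median(typ)))
    return eligible


def build_reference_volume(
    series: DynamicSliceSeries, n_bins: int = DEFAULT_MI_BINS
) -> ReferenceVolume:
    """Select the most mutually informative measurement per slice position.

    Among the typical candidates of each position (see
    :func:`_typical_candidates`), the central adjacent pair of positions
    is chosen by exhaustive search over all candidate pairs; the chain is
    then extended outward, each new position taking the candidate with
    maximal MI to the already chosen neighbouring slice.  Ties resolve to
    the lowest measurement index.
    """
    if series.n_slices < 2:
        raise ValueError("need at least 2 slice positions")
    groups = _grouped(series)
    imgs = series.images
    eligible = _typical_candidates(series, groups, n_bins)
    c = (series.n_slices - 1) // 2
    lo, hi = groups[c][eligible[c]], groups[c + 1][eligible[c + 1]]
    table = np.array(
        [[mutual_information(imgs[i], imgs[j], n_bins) for j in hi] for i in lo]
    )
    bi, bj = np.unravel_index(int(np.argmax(table)), table.shape)
    chosen = np.full(series.n_slices, -1, dtype=int)
    chosen[c], chosen[c + 1] = eligible[c][bi], eligible[c + 1][bj]

    def _extend(z: int, anchor: int) -> None:
        ref_img = imgs[groups[anchor][chosen[anchor]]]
        cand = eligible[z]
        scores = [
            mutual_information(imgs[groups[z][m]], ref_img, n_bins) for m in cand
        ]
        chosen[z] = int(cand[int(np.argmax(scores))])

    for z in range(c - 1, -1, -1):
        _extend(z, z + 1)
    for z in range(c + 2, series.n_slices):
        _extend(z, z - 1)

    volume = np.stack(
        [imgs[groups[z][chosen[z]]] for z in range(series.n_slices)], axis=2
    )
    return ReferenceVolume(volume, chosen, series.spacing_mm)


def extract_surrogate(
    series: DynamicSliceSeries, ref: ReferenceVolume, n_bins: int = DEFAULT_MI_BINS
) -> SurrogateSignal:
    """MI of every acquired slice against its same-position reference slice."""
    if ref.volume.shape[2] != series.n_slices:
        raise ValueError("reference volume does not match series geometry")
    values = np.array(
        [
            mutual_information(series.images[i], ref.volume[:, :, series.slice_index[i]], n_bins)
            for i in range(len(series))
        ]
    )
    return SurrogateSignal(values, series.time_ms, series.slice_index)


def _detect_landmarks(values: np.ndarray) -> np.ndarray:
    """End-inhalation landmarks of one group: prominent surrogate minima.

    The reference volume is constructed on the typical (exhale-plateau)
    state, so the state most dissimilar from it -- the surrogate minimum
    -- is end inhalation, the isolated extreme of the breathing cycle.
    The prominence scale uses an inner percentile range so that the large
    self-match value of the reference measurement itself cannot swamp the
    respiratory oscillation.
    """
    s = -np.asarray(values, float)
    scale = np.percentile(s, 90) - np.percentile(s, 10)
    if scale == 0:
        raise ValueError("flat surrogate: cannot detect breathing cycles")
    peaks, _ = find_peaks(s, prominence=0.3 * scale)
    if len(peaks) < 2:
        raise ValueError(
            f"only {len(peaks)} surrogate landmark(s) found in a group; "
            "acquire a longer series (more measurements per slice)"
        )
    return peaks


def _cycle_fractions(n: int, landmarks: np.ndarray) -> np.ndarray:
    """Cycle fraction in [0, 1) per sample by interpolation between landmarks.

    Fractions grow linearly between successive landmarks (fraction 0 at
    each landmark) and extrapolate with the nearest interval length
    outside the first/last landmark.
    """
    m = np.arange(n, dtype=float)
    cyc = np.interp(m, landmarks, np.arange(len(landmarks), dtype=float))
    d_first = landmarks[1] - landmarks[0]
    d_last = landmarks[-1] - landmarks[-2]
    before = m < landmarks[0]
    after = m > landmarks[-1]
    cyc[before] = (m[before] - landmarks[0]) / d_first
    cyc[after] = (len(landmarks) - 1) + (m[after] - landmarks[-1]) / d_last
    return cyc % 1.0


def assign_phases(sig: SurrogateSignal, n_phases: int = 6) -> np.ndarray:
    """Phase label (1-based) per acquired slice from the MI surrogate.

    Each slice-position group is processed independently: end-inhalation
    landmarks are detected on the group's surrogate (see
    :func:`_detect_landmarks`), cycle fractions interpolate linearly
    between successive landmarks, and fractions are binned into
    ``n_phases`` equal bins centred on the landmark, anchoring bin 1 at
    end inhalation.
    """
    if n_phases < 2:
        raise ValueError("n_phases must be >= 2")
    labels = np.zeros(len(sig.values), dtype=int)
    for z in np.unique(sig.slice_index):
        idx = np.flatnonzero(sig.slice_index == z)
        order = idx[np.argsort(sig.times_ms[idx], kind="stable")]
        landmarks = _detect_landmarks(sig.values[order])
        frac = _cycle_fractions(len(order), landmarks)
        labels[order] = (np.rint(frac * n_phases).astype(int) % n_phases) + 1
    return labels


def reconstruct_4d(
    series: DynamicSliceSeries, labels: np.ndarray, n_phases: int = 6
) -> Volume4D:
    """Average member slices per (phase, slice) cell into phase volumes.

    Empty cells are filled from the cyclically nearest populated phase at
    the same slice position (distance ties resolve to the earlier phase)
    and recorded in ``fill_log``.
    """
    labels = np.asarray(labels, int)
    if len(labels) != len(series):
        raise ValueError("labels must cover the series")
    groups = _grouped(series)
    nx, ny = series.images.shape[1:]
    cells: list[list[np.ndarray | None]] = [
        [None] * series.n_slices for _ in range(n_phases)
    ]
    for p in range(1, n_phases + 1):
        for z in range(series.n_slices):
            members = groups[z][labels[groups[z]] == p]
            if len(members):
                cells[p - 1][z] = series.images[members].mean(axis=0)

    fill_log: list[tuple[int, int, int]] = []
    for z in range(series.n_slices):
        populated = [p for p in range(n_phases) if cells[p][z] is not None]
        if not populated:
            raise ValueError(f"slice position {z} empty in all phases")
        for p in range(n_phases):
            if cells[p][z] is None:
                # cyclic nearest donor; ties toward the earlier phase label
                donor = min(
                    populated,
                    key=lambda q: (
                        min((q - p) % n_phases, (p - q) % n_phases),
                        q,
                    ),
                )
                cells[p][z] = cells[donor][z]
                fill_log.append((z, p + 1, donor + 1))

    phases = [
        np.stack([cells[p][z] for z in range(series.n_slices)], axis=2)
        for p in range(n_phases)
    ]
    return Volume4D(phases, fill_log, series.spacing_mm)
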