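"""Segmentation-reliability indexes across breathing phases.

Contours drawn (or propagated) independently per phase should describe
the same organ, merely displaced by quasi-rigid breathing motion.  Two
indexes quantify this:

* **Pearson profile index** -- the integral map profile of a binary map
  along an axis is its 1D marginal (voxel counts summed over the other
  two axes).  Profiles of all phases are rigidly registered onto a
  reference phase by the nearest-integer voxel offset of their COM
  difference, then correlated pairwise; with motion compensated, any
  residual decorrelation reflects shape changes of the segmentation.
* **Volume consistency** -- the per-phase percentage volume deficit
  relative to the maximum phase volume, 100 * (Vmax - V) / Vmax.

Both are summarised as median and interquartile range across phases.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from pancmotion.motion import quartiles
from pancmotion.types import AXES, axis_index


@dataclass
class IntegralProfile:
    """1D marginal of a binary map along one anatomical axis."""

    axis: str
    values: np.ndarray
    origin_voxel: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if self.values.ndim != 1:
            raise ValueError("profile must be 1D")

    @property
    def com_bins(self) -> float:
        """Profile centre of mass in (fractional) bin units."""
        total = self.values.sum()
        if total == 0:
            raise ValueError("empty profile has no COM")
        return float(np.arange(len(self.values)) @ self.values / total)


def integral_profile(mask: np.ndarray, axis: str) -> IntegralProfile:
    """Sum a 3D binary map over the two axes orthogonal to ``axis``."""
    mask = np.asarray(mask)
    if mask.ndim != 3:
        raise ValueError("expected a 3D map")
    ax = axis_index(axis)
    other = tuple(i for i in range(3) if i != ax)
    return IntegralProfile(AXES[ax], mask.sum(axis=other).astype(float))


def _round_half_away(x: float) -> int:
    return int(np.sign(x) * np.floor(abs(x) + 0.5))


def register_profile(
    p: IntegralProfile, ref: IntegralProfile
) -> tuple[IntegralProfile, int]:
    """Shift ``p`` onto ``ref`` by their rounded COM offset (in bins).

    The applied integer shift is ``round(ref_com - p_com)`` with
    round-half-away-from-zero; vacated bins are zero-filled.  Returns the
    shifted profile and the shift.  Bins ``[max(0, s), L + min(0, s))``
    of the result hold translated data; the rest is padding.
    """
    if p.axis != ref.axis:
        raise ValueError(f"axis mismatch: {p.axis} vs {ref.axis}")
    shift = _round_half_away(ref.com_bins - p.com_bins)
    n = len(p.values)
    shifted = np.zeros(n)
    if shift >= 0:
        shifted[shift:] = p.values[: n - shift]
    else:
        shifted[:shift] = p.values[-shift:]
    return IntegralProfile(p.axis, shifted, p.origin_voxel), shift


def _valid_range(shift: int, n: int) -> tuple[int, int]:
    return max(0, shift), n + min(0, shift)


def profile_correlations(
    masks: list[np.ndarray], axis: str, ref_phase: int = 1
) -> np.ndarray:
    """Pairwise Pearson matrix of COM-registered profiles across phases.

    Every phase's profile is registered onto the reference phase's
    profile; correlations are computed on the common valid (non-padded)
    support of each pair.  A zero-variance profile yields NaN entries
    with a warning.
    """
    n_ph = len(masks)
    if n_ph < 2:
        raise ValueError("need at least 2 phases")
    ref = integral_profile(masks[ref_phase - 1], axis)
    registered, shifts = [], []
    for m in masks:
        prof, s = register_profile(integral_profile(m, axis), ref)
        registered.append(prof.values)
        shifts.append(s)
    n = len(ref.values)
    corr = np.eye(n_ph)
    for i in range(n_ph):
        for j in range(i + 1, n_ph):
            lo = max(_valid_range(shifts[i], n)[0], _valid_range(shifts[j], n)[0])
            hi = min(_valid_range(shifts[i], n)[1], _valid_range(shifts[j], n)[1])
            a, b = registered[i][lo:hi], registered[j][lo:hi]
            if a.std() == 0 or b.std() == 0:
                warnings.warn(
                    f"zero-variance profile in phase pair ({i + 1}, {j + 1}); "
                    "correlation undefined",
                    stacklevel=2,
                )
                corr[i, j] = corr[j, i] = np.nan
            else:
                corr[i, j] = corr[j, i] = float(np.corrcoef(a, b)[0, 1])
    return corr


def pearson_profile_index(
    masks: list[np.ndarray], axis: str, ref_phase: int = 1
) -> dict:
    """Median +/- IQR Pearson profile index for one structure and axis.

    The per-phase scalar is the median of that phase's correlations with
    every other phase; the summary is the median and IQR of those
    per-phase values.
    """
    corr = profile_correlations(masks, axis, ref_phase)
    n_ph = corr.shape[0]
    per_phase = np.array(
        [
            np.nanmedian(np.delete(corr[p], p))
            for p in range(n_ph)
        ]
    )
    q1, q3 = quartiles(per_phase[~np.isnan(per_phase)])
    return {
        "axis": axis,
        "per_phase": per_phase,
        "median": float(np.nanmedian(per_phase)),
        "iqr": float(q3 - q1),
    }


def volume_consistency(masks: list[np.ndarray], spacing_mm) -> dict:
    """Per-phase % volume deficit vs the maximum phase volume, plus summary.

    Volumes are in cc (voxel count times voxel volume); the consistency
    value of phase p is ``100 * (Vmax - V_p) / Vmax``.
    """
    if len(masks) < 2:
        raise ValueError("need at least 2 phases")
    voxel_cc = float(np.prod(np.asarray(spacing_mm, float))) / 1000.0
    counts = np.array([int(np.asarray(m, bool).sum()) for m in masks])
    if (counts == 0).any():
        empty = [p + 1 for p in np.flatnonzero(counts == 0)]
        raise ValueError(f"structure empty in phase(s) {empty}")
    volumes_cc = counts * voxel_cc
    vmax = volumes_cc.max()
    pct = 100.0 * (vmax - volumes_cc) / vmax
    q1, q3 = quartiles(pct)
    vq1, vq3 = quartiles(volumes_cc)
    return {
        "volumes_cc": volumes_cc,
        "per_phase_pct": pct,
        "median_pct": float(np.median(pct)),
        "iqr_pct": float(q3 - q1),
        "volume_median_cc": float(np.median(volumes_cc)),
        "volume_iqr_cc": float(vq3 - vq1),
    }


def reliability_report(
    structures: dict[str, list[np.ndarray]], spacing_mm, ref_phase: int = 1
) -> pd.DataFrame:
    """Reliability summary table over structures, one row per structure.

    Columns mirror the conventional layout: Pearson median +/- IQR per
    axis, volume (cc, median +/- IQR) and volume consistency (%).
    Percentages are rounded to two decimals, volumes to three.
    """
    rows = []
    for name, masks in structures.items():
        row: dict = {"structure": name}
        for axis in AXES:
            idx = pearson_profile_index(masks, axis, ref_phase)
            row[f"pearson_{axis}_median"] = round(idx["median"], 3)
            row[f"pearson_{axis}_iqr"] = round(idx["iqr"], 3)
        vc = volume_consistency(masks, spacing_mm)
        row["volume_cc_median"] = round(vc["volume_median_cc"], 3)
        row["volume_cc_iqr"] = round(vc["volume_iqr_cc"], 3)
        row["volume_consistency_median_pct"] = round(vc["median_pct"], 2)
        row["volume_consistency_iqr_pct"] = round(vc["iqr_pct"], 2)
        rows.append(row)
    return pd.DataFrame(rows)
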