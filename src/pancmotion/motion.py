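"""Centre-of-mass trajectories, phase stability and displacement.

The COM of each binary structure map is tracked over the breathing
phases.  The per-phase stability index is the mean absolute COM change
relative to the two adjacent phases,

    stability(ph) = (|COM_{ph-1} - COM_ph| + |COM_{ph+1} - COM_ph|) / 2,

evaluated per direction on the components and in 3D on the Euclidean
norms of the two adjacent difference vectors.  Breathing is periodic, so
adjacency is cyclic by default (phase 1 neighbours phases P and 2); a
truncated variant using the single existing neighbour at the cycle ends
is available for sensitivity checks.  The phase minimising the 3D index
is the reference (gating) phase, and motion is reported as signed COM
displacement of every phase relative to it.

Phase labels are 1-based everywhere (phase 1 = end inhalation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from pancmotion.types import AXES, STRUCTURES, Mask4D


def com(mask: np.ndarray, spacing_mm) -> np.ndarray:
    """Unweighted centre of mass of a binary map, in mm.

    Coordinates are voxel centres: ``(index + 0.5) * spacing``.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("cannot compute COM of an empty mask")
    idx = np.argwhere(mask).astype(float) + 0.5
    return idx.mean(axis=0) * np.asarray(spacing_mm, float)


def com_trajectory(masks: Mask4D | list[np.ndarray], spacing_mm=None) -> np.ndarray:
    """Per-phase COM, shape (n_phases, 3)."""
    if isinstance(masks, Mask4D):
        spacing_mm = masks.spacing_mm
        masks = masks.masks
    if spacing_mm is None:
        raise ValueError("spacing_mm required when masks is a plain list")
    return np.array([com(m, spacing_mm) for m in masks])


@dataclass
class StabilityResult:
    """Per-phase COM stability and the selected reference phase.

    ``per_direction`` has shape (n_phases, 3) in mm along (LL, AP, SI);
    ``three_d`` has shape (n_phases,); ``reference_phase`` is 1-based.
    """

    per_direction: np.ndarray
    three_d: np.ndarray
    reference_phase: int
    adjacency: str = "cyclic"


def _neighbour_pairs(n: int, adjacency: str):
    """For each phase index, the list of adjacent phase indices."""
    if adjacency == "cyclic":
        return [[(p - 1) % n, (p + 1) % n] for p in range(n)]
    if adjacency == "truncated":
        return [
            [q for q in (p - 1, p + 1) if 0 <= q < n] for p in range(n)
        ]
    raise ValueError("adjacency must be 'cyclic' or 'truncated'")


def com_stability(traj: np.ndarray, adjacency: str = "cyclic") -> StabilityResult:
    """Mean absolute COM change of each phase relative to its neighbours.

    Parameters
    ----------
    traj
        (n_phases, 3) COM trajectory in mm.
    adjacency
        ``"cyclic"`` (default; phase 1 neighbours P and 2) or
        ``"truncated"`` (boundary phases use their single neighbour).
    """
    traj = np.asarray(traj, float)
    n = traj.shape[0]
    if n < 3:
        raise ValueError("stability needs at least 3 phases")
    per_dir = np.zeros((n, 3))
    three_d = np.zeros(n)
    for p, nbrs in enumerate(_neighbour_pairs(n, adjacency)):
        diffs = traj[nbrs] - traj[p]
        per_dir[p] = np.abs(diffs).mean(axis=0)
        three_d[p] = np.linalg.norm(diffs, axis=1).mean()
    ref = select_reference_phase_from_values(three_d)
    return StabilityResult(per_dir, three_d, ref, adjacency)


def select_reference_phase_from_values(three_d: np.ndarray) -> int:
    """Argmin of the 3D stability values; ties go to the lower phase."""
    three_d = np.asarray(three_d, float)
    ref = int(np.argmin(three_d)) + 1
    ties = np.flatnonzero(three_d == three_d[ref - 1])
    if len(ties) > 1:
        warnings.warn(
            f"stability tie among phases {[int(t) + 1 for t in ties]}; "
            f"keeping phase {ref}",
            stacklevel=2,
        )
    return ref


def select_reference_phase(stab: StabilityResult) -> int:
    """The phase with maximal stability (minimum 3D index), 1-based."""
    return select_reference_phase_from_values(stab.three_d)


def com_displacement(traj: np.ndarray, ref_phase: int):
    """Signed per-phase COM displacement vs the reference phase.

    Returns ``(disp, magnitude)`` where ``disp`` is (n_phases, 3) signed
    mm along (LL, AP, SI) and ``magnitude`` the per-phase Euclidean norm.
    """
    traj = np.asarray(traj, float)
    if not 1 <= ref_phase <= traj.shape[0]:
        raise ValueError(f"reference phase {ref_phase} out of range")
    disp = traj - traj[ref_phase - 1]
    return disp, np.linalg.norm(disp, axis=1)


def motion_records(
    structures: dict[str, list[np.ndarray]],
    spacing_mm,
    dataset: str,
    position: str,
    device: str,
    adjacency: str = "cyclic",
    ref_phase: int | None = None,
) -> pd.DataFrame:
    """Long-format per-phase displacement table for one acquisition.

    Parameters
    ----------
    structures
        Mapping structure name -> per-phase binary masks (e.g. pancreas
        plus head/body/tail).  The reference phase is selected from the
        whole-pancreas stability when present, else from the first
        structure, unless ``ref_phase`` is given.

    Returns
    -------
    DataFrame with columns dataset, position, device, structure, phase
    (1-based), is_reference, LL, AP, SI (signed mm) and D3D (mm).
    """
    key = "pancreas" if "pancreas" in structures else next(iter(structures))
    if ref_phase is None:
        stab = com_stability(
            com_trajectory(structures[key], spacing_mm), adjacency
        )
        ref_phase = stab.reference_phase
    rows = []
    for structure, masks in structures.items():
        traj = com_trajectory(masks, spacing_mm)
        disp, mag = com_displacement(traj, ref_phase)
        for p in range(traj.shape[0]):
            rows.append(
                {
                    "dataset": dataset,
                    "position": position,
                    "device": device,
                    "structure": structure,
                    "phase": p + 1,
                    "is_reference": p + 1 == ref_phase,
                    "LL": disp[p, 0],
                    "AP": disp[p, 1],
                    "SI": disp[p, 2],
                    "D3D": mag[p],
                }
            )
    return pd.DataFrame(rows)


def quartiles(x: np.ndarray) -> tuple[float, float]:
    """Q1 and Q3 by linear interpolation of the empirical CDF.

    Uses Weibull plotting positions (quantile type 6), the convention of
    common box-plot implementations: quartiles of {-1, 0, 1, 2, 3} are
    (-0.5, 2.5), giving IQR 3.
    """
    q1, q3 = np.percentile(np.asarray(x, float), [25, 75], method="weibull")
    return float(q1), float(q3)


def iqr(x: np.ndarray) -> float:
    """Interquartile range Q3 - Q1 (see :func:`quartiles`)."""
    q1, q3 = quartiles(x)
    return q3 - q1


def summarize_motion(records: pd.DataFrame) -> pd.DataFrame:
    """Median +/- IQR of displacement per setup, excluding the reference phase.

    Groups by (dataset, position, device, structure) and summarises the
    signed LL/AP/SI displacements and the 3D magnitude over the
    non-reference phases, the layout used for per-setup motion tables.
    """
    data = records[~records["is_reference"]]
    if data.empty:
        warnings.warn("no non-reference records to summarise", stacklevel=2)
        return pd.DataFrame()
    out = []
    for keys, grp in data.groupby(
        ["dataset", "position", "device", "structure"], sort=True
    ):
        row = dict(zip(["dataset", "position", "device", "structure"], keys))
        for col in ("LL", "AP", "SI", "D3D"):
            vals = grp[col].to_numpy(float)
            row[f"{col}_median"] = float(np.median(vals))
            row[f"{col}_iqr"] = iqr(vals)
        row["n_phases"] = int(len(grp))
        out.append(row)
    return pd.DataFrame(out)


def outlier_flags(values: np.ndarray) -> np.ndarray:
    """Box-plot fence rule: flag x > q3 + 1.5*(q3-q1) or x < q1 - 1.5*(q3-q1).

    Used for plotting only; flagged points are never excluded from
    statistics.
    """
    values = np.asarray(values, float)
    q1, q3 = quartiles(values)
    fence = 1.5 * (q3 - q1)
    return (values > q3 + fence) | (values < q1 - fence)
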