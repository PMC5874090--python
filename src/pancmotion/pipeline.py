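"""End-to-end analysis pipeline and synthetic study-cohort builder.

``run_pipeline`` chains the full method on one acquisition: simulate (or
load) the dynamic series, reconstruct the 6-phase 4D volume via the MI
surrogate, segment the gland by intensity thresholding, partition it
into head/body/tail, compute the reliability indexes, the COM stability
/ displacement records, and the Friedman/Conover comparison suite; every
stage's outputs are written under the run directory.

``cohort_motion_records`` builds the multi-setup displacement table a
patient study would yield: per (dataset, position, device) it generates
a phantom with patient-specific amplitude scaling and optional
position/segment effects, measures COM displacements from the voxelised
masks, and perturbs the trajectories with a small contouring-noise term.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.measure import label as sk_label

from pancmotion import io as pio
from pancmotion.metrics import reliability_report
from pancmotion.motion import (
    com_displacement,
    com_stability,
    com_trajectory,
)
from pancmotion.partition import partition_4d
from pancmotion.phantom import (
    AcqConfig,
    PhantomConfig,
    generate_phantom,
    simulate_dynamic_acquisition,
)
from pancmotion.recon import (
    Volume4D,
    assign_phases,
    build_reference_volume,
    extract_surrogate,
    reconstruct_4d,
)
from pancmotion.stats import build_comparison_suite, render_symbol_table
from pancmotion.types import STRUCTURES, Mask4D

log = logging.getLogger(__name__)


def segment_by_threshold(
    vol4d: Volume4D, threshold: float | None = None, min_size: int = 64
) -> Mask4D:
    """Threshold-segment the gland from the reconstructed phase volumes.

    The gland is the brightest structure by construction; with no
    explicit threshold the cut is placed midway between the bright tail
    (99.5th percentile, gland interior) and the background median of the
    pooled intensities.  Connected components below ``min_size`` voxels
    are removed as speckle.
    """
    if threshold is None:
        pooled = np.concatenate([v.ravel() for v in vol4d.phases])
        bright, background = np.percentile(pooled, [99.5, 50.0])
        threshold = 0.5 * (bright + background)
    masks = []
    for v in vol4d.phases:
        m = v > threshold
        comp = sk_label(m)
        sizes = np.bincount(comp.ravel())
        keep = np.flatnonzero(sizes >= min_size)
        m = np.isin(comp, keep[keep > 0])
        masks.append(m)
    return Mask4D(masks, vol4d.spacing_mm)


def structure_mask_sets(masks: Mask4D, labels4d) -> dict[str, list[np.ndarray]]:
    """Whole-gland plus per-segment mask lists keyed by structure name."""
    sets: dict[str, list[np.ndarray]] = {"pancreas": masks.masks}
    for name in ("head", "body", "tail"):
        sets[name] = labels4d.structure_masks(name)
    return sets


def motion_records_with_noise(
    structures: dict[str, list[np.ndarray]],
    spacing_mm,
    dataset: str,
    position: str,
    device: str,
    com_noise_sd_mm: float = 0.0,
    rng: np.random.Generator | None = None,
    adjacency: str = "cyclic",
    ref_phase: int | None = None,
) -> pd.DataFrame:
    """Displacement records with optional contouring noise.

    Independent Gaussian jitter (``com_noise_sd_mm`` per axis) is added
    to every non-reference displacement, emulating phase-wise contouring
    variability; the reference-phase displacement stays exactly zero and
    the 3D magnitude is recomputed as the norm of the noisy components.
    When ``ref_phase`` is None it is selected from the whole-pancreas
    stability.
    """
    trajs = {s: com_trajectory(m, spacing_mm) for s, m in structures.items()}
    key = "pancreas" if "pancreas" in trajs else next(iter(trajs))
    ref = ref_phase or com_stability(trajs[key], adjacency).reference_phase
    if com_noise_sd_mm > 0:
        rng = rng or np.random.default_rng()
    rows = []
    for s, traj in trajs.items():
        disp, mag = com_displacement(traj, ref)
        if com_noise_sd_mm > 0:
            jitter = rng.normal(0, com_noise_sd_mm, disp.shape)
            jitter[ref - 1] = 0.0
            disp = disp + jitter
            mag = np.linalg.norm(disp, axis=1)
        for p in range(traj.shape[0]):
            rows.append(
                {
                    "dataset": dataset,
                    "position": position,
                    "device": device,
                    "structure": s,
                    "phase": p + 1,
                    "is_reference": p + 1 == ref,
                    "LL": disp[p, 0],
                    "AP": disp[p, 1],
                    "SI": disp[p, 2],
                    "D3D": mag[p],
                }
            )
    return pd.DataFrame(rows)


def cohort_motion_records(
    n_datasets: int = 5,
    seed: int = 0,
    positions: tuple[str, ...] = ("prone", "supine"),
    devices: tuple[str, ...] = ("vacuum", "mask", "compressor"),
    si_position_ratio: float = 1.0,
    tail_head_si_ratio: float = 1.5,
    patient_scale_sd: float = 0.15,
    com_noise_sd_mm: float = 0.3,
    reposition: bool = True,
    head_amplitude_mm: tuple[float, float, float] = (2.0, 0.8, 2.4),
    drop: tuple[tuple[str, str, str], ...] = (),
) -> pd.DataFrame:
    """Synthetic multi-setup cohort of COM displacement records.

    Each dataset (patient) carries a lognormal amplitude scale; prone
    acquisitions have their SI amplitudes multiplied by
    ``si_position_ratio``; segment SI amplitudes grade from head to
    ``tail_head_si_ratio`` x head (body midway); LL and AP amplitudes are
    shared by all segments.  ``drop`` removes whole (dataset, position,
    device) acquisitions, emulating unusable scans.
    """
    rng = np.random.default_rng(seed)
    records = []
    base = np.asarray(head_amplitude_mm, float)
    for d in range(n_datasets):
        ds = f"P{d + 1}"
        scale = float(np.exp(rng.normal(0.0, patient_scale_sd)))
        for position in positions:
            si_fac = si_position_ratio if position == "prone" else 1.0
            for device in devices:
                if (ds, position, device) in drop:
                    continue
                amp = {}
                for seg, seg_fac in (
                    ("head", 1.0),
                    ("body", (1.0 + tail_head_si_ratio) / 2.0),
                    ("tail", tail_head_si_ratio),
                ):
                    amp[seg] = (
                        base[0] * scale,
                        base[1] * scale,
                        base[2] * scale * si_fac * seg_fac,
                    )
                cfg = PhantomConfig(
                    amplitude_mm=amp,
                    seed=seed + 1000 * d,
                    # sub-voxel repositioning between scans decorrelates
                    # voxelisation error across the repeated acquisitions
                    origin_offset_mm=tuple(
                        rng.uniform(-0.5, 0.5, 3)
                        * np.asarray(PhantomConfig().spacing_mm)
                        * (1.0 if reposition else 0.0)
                    ),
                )
                ph = generate_phantom(cfg, with_intensity=False)
                structures = {s: ph.structure_masks(s) for s in STRUCTURES}
                rec = motion_records_with_noise(
                    structures,
                    cfg.spacing_mm,
                    ds,
                    position,
                    device,
                    com_noise_sd_mm=com_noise_sd_mm,
                    rng=rng,
                    # one reference phase for the whole study, as selected
                    # by the noise-free stability analysis
                    ref_phase=ph.reference_phase,
                )
                records.append(rec)
    return pd.concat(records, ignore_index=True)


def run_pipeline(config: pio.RunConfig) -> dict:
    """Execute the full analysis and write all outputs under ``out_dir``.

    Returns a result bundle with the intermediate objects and the paths
    of the written artefacts.  Any stage failure is re-raised with the
    stage name prepended.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"config": config}
    stage = "setup"
    try:
        stage = "simulate"
        if config.series_dir is None:
            phantom = generate_phantom(PhantomConfig(seed=config.seed))
            acq = AcqConfig(seed=config.seed)
            series = simulate_dynamic_acquisition(phantom, acq)
            pio.write_series(out / "series", series)
            pio.write_mask4d(out / "truth", phantom.masks, prefix="truth_mask")
            bundle["phantom"] = phantom
        else:
            series = pio.read_series(config.series_dir)
        bundle["series"] = series

        stage = "reconstruct"
        ref = build_reference_volume(series, config.mi_bins)
        sig = extract_surrogate(series, ref, config.mi_bins)
        labels = assign_phases(sig, config.n_phases)
        vol4d = reconstruct_4d(series, labels, config.n_phases)
        pio.write_volumes(out / "recon", vol4d.phases, vol4d.spacing_mm, "volume")
        pd.DataFrame(
            {
                "time_ms": sig.times_ms,
                "slice_index": sig.slice_index,
                "surrogate_mi_bits": sig.values,
                "phase": labels,
            }
        ).to_csv(out / "surrogate.csv", index=False)
        bundle.update(reference=ref, surrogate=sig, phase_labels=labels, vol4d=vol4d)

        stage = "segment"
        masks = segment_by_threshold(vol4d)
        pio.write_mask4d(out / "masks", masks)
        bundle["masks"] = masks

        stage = "partition"
        labels4d = partition_4d(masks, seed=config.seed, label_axis=config.label_axis)
        pio.write_labels4d(out / "segments", labels4d.labels, masks.spacing_mm)
        cent = []
        for p in range(labels4d.n_phases):
            for s_i, s in enumerate(("head", "body", "tail")):
                cent.append(
                    {
                        "phase": p + 1,
                        "segment": s,
                        "LL": labels4d.centroids_mm[p, s_i, 0],
                        "AP": labels4d.centroids_mm[p, s_i, 1],
                        "SI": labels4d.centroids_mm[p, s_i, 2],
                    }
                )
        pd.DataFrame(cent).to_csv(out / "centroids.csv", index=False)
        bundle["labels4d"] = labels4d

        structures = structure_mask_sets(masks, labels4d)

        stage = "motion"
        traj = com_trajectory(masks)
        stab = com_stability(traj, config.adjacency)
        records = motion_records_with_noise(
            structures,
            masks.spacing_mm,
            config.dataset,
            config.position,
            config.device,
            adjacency=config.adjacency,
        )
        records.to_csv(out / "motion_records.csv", index=False)
        from pancmotion.motion import summarize_motion

        summary = summarize_motion(records)
        summary.to_csv(out / "motion_summary.csv", index=False)
        bundle.update(stability=stab, records=records, motion_summary=summary)

        stage = "reliability"
        report = reliability_report(
            structures, masks.spacing_mm, ref_phase=stab.reference_phase
        )
        report.to_csv(out / "reliability.csv", index=False)
        bundle["reliability"] = report

        stage = "stats"
        suite = build_comparison_suite(records, alpha=config.alpha)
        rows = []
        for r in suite:
            rows.append(
                {
                    "dataset": r.dataset,
                    "direction": r.direction,
                    "comparison": r.comparison,
                    "testable": r.testable,
                    "statistic": r.friedman.statistic if r.testable else np.nan,
                    "dof": r.friedman.dof if r.testable else np.nan,
                    "p_value": r.friedman.p_value if r.testable else np.nan,
                    "blocks_dropped": r.n_blocks_dropped,
                    "note": r.note,
                }
            )
        pd.DataFrame(rows).to_csv(out / "friedman.csv", index=False)
        render_symbol_table(suite).to_csv(out / "symbol_table.csv")
        bundle["suite"] = suite

        (out / "run_log.json").write_text(
            json.dumps(
                {
                    "seed": config.seed,
                    "n_phases": config.n_phases,
                    "mi_bins": config.mi_bins,
                    "adjacency": config.adjacency,
                    "reference_phase": int(stab.reference_phase),
                    "n_gap_fills": len(vol4d.fill_log),
                    "fill_log": vol4d.fill_log,
                },
                indent=2,
            )
        )
    except Exception as exc:  # pragma: no cover - error path
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return bundle
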