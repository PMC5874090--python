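"""NIfTI and CSV input/output for masks, volumes and dynamic series.

Volumes are written one NIfTI file per breathing phase with a diagonal
affine built from the voxel spacing; dynamic series are written as a
single NIfTI stack (slices along the third axis in acquisition order)
with a CSV sidecar carrying per-slice metadata.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from pancmotion.types import DynamicSliceSeries, Mask4D


def _affine(spacing_mm) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing_mm
    return aff


def _spacing_from(img: nib.Nifti1Image) -> tuple[float, float, float]:
    return tuple(float(z) for z in img.header.get_zooms()[:3])


def write_volumes(
    out_dir: str | Path, volumes: list[np.ndarray], spacing_mm, prefix: str
) -> list[Path]:
    """Write one NIfTI per phase: ``<prefix>_phase01.nii.gz`` etc."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for p, vol in enumerate(volumes, start=1):
        path = out_dir / f"{prefix}_phase{p:02d}.nii.gz"
        nib.save(nib.Nifti1Image(np.asarray(vol, np.float32), _affine(spacing_mm)), path)
        paths.append(path)
    return paths


def _phase_sorted(paths: list[Path]) -> list[Path]:
    def key(p: Path):
        m = re.search(r"phase(\d+)", p.name)
        return int(m.group(1)) if m else p.name
    return sorted(paths, key=key)


def read_volumes(paths: list[str | Path]) -> tuple[list[np.ndarray], tuple]:
    """Read per-phase NIfTI volumes, enforcing consistent geometry."""
    paths = _phase_sorted([Path(p) for p in paths])
    if not paths:
        raise ValueError("no volume files given")
    vols, spacings, shapes = [], [], []
    for p in paths:
        img = nib.load(str(p))
        vols.append(np.asarray(img.dataobj, dtype=float))
        spacings.append(_spacing_from(img))
        shapes.append(vols[-1].shape)
    bad = [
        str(p)
        for p, sp, sh in zip(paths, spacings, shapes)
        if not np.allclose(sp, spacings[0]) or sh != shapes[0]
    ]
    if bad:
        raise ValueError(f"inconsistent geometry across phases: {bad}")
    return vols, spacings[0]


def write_mask4d(out_dir: str | Path, masks: Mask4D, prefix: str = "mask") -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for p, m in enumerate(masks.masks, start=1):
        path = out_dir / f"{prefix}_phase{p:02d}.nii.gz"
        nib.save(nib.Nifti1Image(m.astype(np.uint8), _affine(masks.spacing_mm)), path)
        paths.append(path)
    return paths


def read_mask4d(paths_or_dir: list[str | Path] | str | Path, prefix: str = "mask") -> Mask4D:
    """Read a per-phase binary mask set; rejects non-binary voxel values."""
    if isinstance(paths_or_dir, (str, Path)) and Path(paths_or_dir).is_dir():
        paths = sorted(Path(paths_or_dir).glob(f"{prefix}_phase*.nii*"))
    else:
        paths = [Path(p) for p in paths_or_dir]
    vols, spacing = read_volumes(paths)
    masks = []
    for p, v in enumerate(vols, start=1):
        uniq = np.unique(v)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError(
                f"phase {p} map is not binary (values {uniq[:6].tolist()}...)"
            )
        masks.append(v.astype(bool))
    return Mask4D(masks, spacing)


def write_labels4d(out_dir: str | Path, labels: list[np.ndarray], spacing_mm,
                   prefix: str = "segments") -> list[Path]:
    """Integer label maps {0 bg, 1 head, 2 body, 3 tail}, one file per phase."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for p, lab in enumerate(labels, start=1):
        path = out_dir / f"{prefix}_phase{p:02d}.nii.gz"
        nib.save(nib.Nifti1Image(lab.astype(np.uint8), _affine(spacing_mm)), path)
        paths.append(path)
    return paths


def write_series(out_dir: str | Path, series: DynamicSliceSeries,
                 stem: str = "series") -> tuple[Path, Path]:
    """Dynamic series as a NIfTI stack plus a CSV sidecar.

    Sidecar columns: slice_index, measurement_index, time_ms, true_phase
    (-1 when ground truth is absent).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stack = np.moveaxis(series.images, 0, 2).astype(np.float32)
    nii = out_dir / f"{stem}.nii.gz"
    nib.save(nib.Nifti1Image(stack, _affine(series.spacing_mm)), nii)
    meas = np.zeros(len(series), dtype=int)
    seen: dict[int, int] = {}
    for i, z in enumerate(series.slice_index):
        meas[i] = seen.get(int(z), 0)
        seen[int(z)] = meas[i] + 1
    sidecar = pd.DataFrame(
        {
            "slice_index": series.slice_index,
            "measurement_index": meas,
            "time_ms": series.time_ms,
            "true_phase": series.true_phase
            if series.true_phase is not None
            else -1,
        }
    )
    csv = out_dir / f"{stem}.csv"
    sidecar.to_csv(csv, index=False)
    meta = {
        "n_slices": series.n_slices,
        "n_measurements": series.n_measurements,
        "spacing_mm": list(series.spacing_mm),
    }
    (out_dir / f"{stem}.json").write_text(json.dumps(meta, indent=2))
    return nii, csv


def read_series(in_dir: str | Path, stem: str = "series") -> DynamicSliceSeries:
    in_dir = Path(in_dir)
    img = nib.load(str(in_dir / f"{stem}.nii.gz"))
    images = np.moveaxis(np.asarray(img.dataobj, dtype=float), 2, 0)
    side = pd.read_csv(in_dir / f"{stem}.csv")
    meta = json.loads((in_dir / f"{stem}.json").read_text())
    truth = side["true_phase"].to_numpy(int)
    return DynamicSliceSeries(
        images=images,
        slice_index=side["slice_index"].to_numpy(int),
        time_ms=side["time_ms"].to_numpy(float),
        spacing_mm=tuple(meta["spacing_mm"]),
        n_slices=int(meta["n_slices"]),
        n_measurements=int(meta["n_measurements"]),
        true_phase=None if (truth < 0).all() else truth,
    )


@dataclass
class RunConfig:
    """End-to-end pipeline configuration (see ``pancmotion run --help``)."""

    out_dir: str = "pancmotion_out"
    series_dir: str | None = None  # None -> simulate the phantom
    n_phases: int = 6
    mi_bins: int = 64
    seed: int = 0
    alpha: float = 0.05
    adjacency: str = "cyclic"
    label_axis: int = 0  # head/body/tail ordering axis (0 = LL)
    dataset: str = "phantom"
    position: str = "supine"
    device: str = "vacuum"

    def __post_init__(self) -> None:
        if self.n_phases < 2 or self.mi_bins < 2:
            raise ValueError("n_phases and mi_bins must be >= 2")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.adjacency not in ("cyclic", "truncated"):
            raise ValueError("adjacency must be 'cyclic' or 'truncated'")


def load_run_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig(**data)
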