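"""K-means partition of the gland mask into head, body and tail.

Lloyd's algorithm runs on the physical (mm) voxel-centre coordinates of
the mask with k = 3 and plain Euclidean distance.  Phase 1 starts from a
seeded random choice of three mask voxels; every subsequent phase is
initialised from the previous phase's converged centroids so clusters
track the same anatomy through the cycle; finally phase 1 is re-run from
the last phase's centroids, overwriting the random-start result and
removing any initialisation effect.  Anatomical identity is assigned by
sorting the converged centroids along LL: the head is the most
patient-right cluster (lowest LL coordinate under the package
convention, positive LL = patient left).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from pancmotion.types import Mask4D

log = logging.getLogger(__name__)

MAX_ITER = 100
SEGMENT_NAMES = ("head", "body", "tail")


@dataclass
class KMeansPhaseResult:
    labels: np.ndarray  # 3D int map: 0 background, 1..3 clusters
    centroids_mm: np.ndarray  # (3, 3)
    n_iter: int
    wcss_history: list[float]  # within-cluster sum of squares per iteration


@dataclass
class SegmentLabels4D:
    """Per-phase head/body/tail voxel labels and centroids.

    Label codes: 0 background, 1 head, 2 body, 3 tail (after anatomical
    ordering along LL).  ``centroids_mm[p]`` rows follow the same order.
    """

    labels: list[np.ndarray]
    centroids_mm: np.ndarray  # (n_phases, 3, 3)
    init_centroids_mm: np.ndarray  # (n_phases, 3, 3) initialisations used
    spacing_mm: tuple[float, float, float]

    @property
    def n_phases(self) -> int:
        return len(self.labels)

    def structure_masks(self, structure: str) -> list[np.ndarray]:
        code = SEGMENT_NAMES.index(structure) + 1
        return [lab == code for lab in self.labels]


def _mask_coords_mm(mask: np.ndarray, spacing_mm) -> tuple[np.ndarray, np.ndarray]:
    idx = np.argwhere(np.asarray(mask, bool))
    coords = (idx.astype(float) + 0.5) * np.asarray(spacing_mm, float)
    return idx, coords


def kmeans_phase(
    mask: np.ndarray, spacing_mm, init_centroids_mm: np.ndarray
) -> KMeansPhaseResult:
    """Lloyd iterations on mask voxel mm coordinates until assignments fix.

    An emptied cluster is re-seeded at the mask voxel farthest from the
    remaining centroids (logged).  Iteration stops when the assignment is
    unchanged or after 100 rounds.
    """
    init = np.asarray(init_centroids_mm, float)
    if init.shape != (3, 3):
        raise ValueError("init_centroids_mm must be (3, 3)")
    if len(np.unique(init, axis=0)) != 3:
        raise ValueError("initial centroids must be distinct")
    idx, coords = _mask_coords_mm(mask, spacing_mm)
    if len(coords) < 3:
        raise ValueError(f"mask has {len(coords)} voxels; need at least 3")

    centroids = init.copy()
    assign = np.full(len(coords), -1)
    wcss_history: list[float] = []
    n_iter = 0
    for n_iter in range(1, MAX_ITER + 1):
        d2 = ((coords[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        new_assign = np.argmin(d2, axis=1)
        for k in range(3):
            if not np.any(new_assign == k):
                others = centroids[[j for j in range(3) if j != k]]
                dist = ((coords[:, None, :] - others[None]) ** 2).sum(axis=2)
                far = int(np.argmax(dist.min(axis=1)))
                centroids[k] = coords[far]
                log.warning("cluster %d emptied; re-seeded at farthest voxel", k)
                d2 = ((coords[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
                new_assign = np.argmin(d2, axis=1)
        wcss_history.append(float(d2[np.arange(len(coords)), new_assign].sum()))
        if np.array_equal(new_assign, assign):
            break
        assign = new_assign
        for k in range(3):
            centroids[k] = coords[assign == k].mean(axis=0)

    labels = np.zeros(mask.shape, dtype=np.uint8)
    labels[tuple(idx.T)] = assign + 1
    return KMeansPhaseResult(labels, centroids, n_iter, wcss_history)


def _anatomical_order(centroids_mm: np.ndarray, label_axis: int = 0) -> np.ndarray:
    """Cluster order head->body->tail: ascending along the LL axis."""
    return np.argsort(centroids_mm[:, label_axis], kind="stable")


def _relabel(result: KMeansPhaseResult, order: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels = np.zeros_like(result.labels)
    for new_code, old in enumerate(order, start=1):
        labels[result.labels == old + 1] = new_code
    return labels, result.centroids_mm[order]


def partition_4d(
    masks: Mask4D, seed: int = 0, label_axis: int = 0
) -> SegmentLabels4D:
    """Partition every phase of a 4D mask into head/body/tail clusters.

    Phase 1 is initialised from three distinct random mask voxels, later
    phases from the preceding phase's converged centroids; phase 1 is
    then re-clustered starting from the last phase's centroids, replacing
    the first result.  Cluster identity is assigned per phase by sorting
    centroids along ``label_axis`` (default LL; head = lowest coordinate).
    """
    rng = np.random.default_rng(seed)
    _, coords0 = _mask_coords_mm(masks.masks[0], masks.spacing_mm)
    pick = rng.choice(len(coords0), size=3, replace=False)
    init0 = coords0[pick]

    results: list[KMeansPhaseResult] = []
    inits = [init0]
    res = kmeans_phase(masks.masks[0], masks.spacing_mm, init0)
    results.append(res)
    for p in range(1, masks.n_phases):
        init = results[-1].centroids_mm.copy()
        inits.append(init)
        results.append(kmeans_phase(masks.masks[p], masks.spacing_mm, init))
    # correct phase-1 random initialisation using the last phase's centroids
    init_rerun = results[-1].centroids_mm.copy()
    inits[0] = init_rerun
    results[0] = kmeans_phase(masks.masks[0], masks.spacing_mm, init_rerun)

    labels, cents = [], []
    for res in results:
        order = _anatomical_order(res.centroids_mm, label_axis)
        lab, cen = _relabel(res, order)
        labels.append(lab)
        cents.append(cen)
    return SegmentLabels4D(
        labels=labels,
        centroids_mm=np.array(cents),
        init_centroids_mm=np.array(inits),
        spacing_mm=masks.spacing_mm,
    )
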