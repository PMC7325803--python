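"""Streamline-based V1-V2 connectivity quantification.

Turns a tractogram plus a segment label volume into 6x6 connectivity and
proximity matrices: a streamline contributes to cell (i, j) iff one endpoint
falls in V1 segment i and the other in V2 segment j (endpoint order ignored)
and it does not traverse CSF; everything else is discarded.  Connectivity
strength is the streamline count normalized to the total retained count in
that hemisphere, reported as a percentage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .datatypes import (
    CSF_CODE,
    SegmentLabelVolume,
    StreamlineSet,
    V1_CODES,
    V2_CODES,
)

logger = logging.getLogger(__name__)


@dataclass
class ConnectivityMatrix:
    """6x6 streamline counts between V1 (rows) and V2 (columns) segments."""

    counts: np.ndarray
    hemisphere_id: str = ""
    acquisition_id: str = ""
    n_input: int = 0
    n_discarded_csf: int = 0
    n_discarded_termination: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (6, 6) or np.any(self.counts < 0):
            raise ValueError("counts must be a 6x6 non-negative array")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def percent(self) -> np.ndarray:
        """Counts normalized to the hemisphere total, as percentages."""
        if self.total == 0:
            raise ValueError("percentage connectivity undefined: zero retained "
                             "streamlines")
        return 100.0 * self.counts / self.total


@dataclass
class ProximityMatrix:
    """Per-cell mean reciprocal streamline length (mm^-1)."""

    mean_recip_len: np.ndarray
    defined_mask: np.ndarray

    def __post_init__(self) -> None:
        self.mean_recip_len = np.asarray(self.mean_recip_len, dtype=float)
        self.defined_mask = np.asarray(self.defined_mask, dtype=bool)


@dataclass
class ConnectivityPartition:
    """Diagonal (retinotopic) vs off-diagonal (non-retinotopic) split."""

    retinotopic_pct: float
    nonretinotopic_pct: float
    retinotopic_counts: int
    nonretinotopic_counts: int


def streamline_length(polyline: np.ndarray) -> float:
    """Arc length in mm: sum of Euclidean distances between consecutive points."""
    pts = np.asarray(polyline, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("polyline needs at least two points")
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def _codes_at(points_mm: np.ndarray, labels: SegmentLabelVolume) -> np.ndarray:
    """Label codes at mm points; 0 outside the grid. Floor(v + 0.5) convention."""
    vox = np.floor(labels.world_to_voxel(points_mm) + 0.5).astype(int)
    shape = np.array(labels.grid.shape)
    inside = np.all((vox >= 0) & (vox < shape), axis=1)
    codes = np.zeros(len(vox), dtype=int)
    if np.any(inside):
        v = vox[inside]
        codes[inside] = labels.grid[v[:, 0], v[:, 1], v[:, 2]]
    return codes


def assign_endpoint(point_mm: np.ndarray, labels: SegmentLabelVolume) -> int:
    """Label code of the voxel containing a point (0 when out of bounds)."""
    return int(_codes_at(np.atleast_2d(point_mm), labels)[0])


def traverses_csf(polyline: np.ndarray, labels: SegmentLabelVolume) -> bool:
    """True iff any polyline point falls in a CSF-labeled voxel."""
    return bool(np.any(_codes_at(np.asarray(polyline), labels) == CSF_CODE))


def _retained_cells(
    tractogram: StreamlineSet, labels: SegmentLabelVolume
) -> tuple[list[tuple[int, int] | None], int, int]:
    """Per-streamline retained cell (0-based) or None; plus discard tallies."""
    cells: list[tuple[int, int] | None] = []
    n_csf = n_term = 0
    for sl in tractogram:
        a, b = assign_endpoint(sl[0], labels), assign_endpoint(sl[-1], labels)
        if a in V2_CODES and b in V1_CODES:
            a, b = b, a
        if not (a in V1_CODES and b in V2_CODES):
            n_term += 1
            cells.append(None)
            continue
        if traverses_csf(sl, labels):
            n_csf += 1
            cells.append(None)
            continue
        cells.append((a - 1, b - 7))
    return cells, n_csf, n_term


def build_connectivity(
    tractogram: StreamlineSet,
    labels: SegmentLabelVolume,
    hemisphere_id: str = "",
    acquisition_id: str = "",
) -> ConnectivityMatrix:
    """Filter a tractogram by dual V1/V2 termination and CSF, count per cell."""
    for code in (*V1_CODES, *V2_CODES):
        if not np.any(labels.grid == code):
            raise ValueError(f"label volume is missing segment code {code}")
    cells, n_csf, n_term = _retained_cells(tractogram, labels)
    counts = np.zeros((6, 6), dtype=int)
    for cell in cells:
        if cell is not None:
            counts[cell] += 1
    if counts.sum() == 0:
        logger.warning("build_connectivity: zero retained streamlines")
    return ConnectivityMatrix(
        counts=counts,
        hemisphere_id=hemisphere_id,
        acquisition_id=acquisition_id,
        n_input=len(tractogram),
        n_discarded_csf=n_csf,
        n_discarded_termination=n_term,
    )


def partition_connectivity(m: ConnectivityMatrix) -> ConnectivityPartition:
    """Split total connectivity into retinotopic (diagonal) and the rest."""
    if m.total == 0:
        raise ValueError("cannot partition a zero-count matrix")
    diag = int(np.trace(m.counts))
    off = m.total - diag
    return ConnectivityPartition(
        retinotopic_pct=100.0 * diag / m.total,
        nonretinotopic_pct=100.0 * off / m.total,
        retinotopic_counts=diag,
        nonretinotopic_counts=off,
    )


def proximity_matrix(
    tractogram: StreamlineSet, labels: SegmentLabelVolume
) -> ProximityMatrix:
    """Mean reciprocal length of retained streamlines per segment pair."""
    cells, _, _ = _retained_cells(tractogram, labels)
    sums = np.zeros((6, 6))
    counts = np.zeros((6, 6), dtype=int)
    for sl, cell in zip(tractogram, cells):
        if cell is None:
            continue
        length = streamline_length(sl)
        if length == 0:
            logger.warning("proximity_matrix: excluding zero-length streamline")
            continue
        sums[cell] += 1.0 / length
        counts[cell] += 1
    defined = counts > 0
    mean = np.full((6, 6), np.nan)
    mean[defined] = sums[defined] / counts[defined]
    return ProximityMatrix(mean_recip_len=mean, defined_mask=defined)


def group_average(matrices: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Element-wise mean across matrices, excluding undefined (NaN) cells.

    Returns the mean matrix and the per-cell count of defined inputs; cells
    undefined in every input stay NaN.
    """
    if len(matrices) == 0:
        raise ValueError("need at least one matrix")
    stack = np.stack([np.asarray(m, dtype=float) for m in matrices])
    defined = ~np.isnan(stack)
    n_defined = defined.sum(axis=0)
    mean = np.full(stack.shape[1:], np.nan)
    any_def = n_defined > 0
    with np.errstate(invalid="ignore"):
        mean[any_def] = np.nansum(stack, axis=0)[any_def] / n_defined[any_def]
    return mean, n_defined


def turning_angle_deg(polyline: np.ndarray) -> float:
    """Total turning: sum of angles between successive segment vectors."""
    pts = np.asarray(polyline, dtype=float)
    vecs = np.diff(pts, axis=0)
    norms = np.linalg.norm(vecs, axis=1)
    keep = norms > 1e-12
    vecs, norms = vecs[keep], norms[keep]
    if len(vecs) < 2:
        return 0.0
    cosang = np.clip(
        np.sum(vecs[:-1] * vecs[1:], axis=1) / (norms[:-1] * norms[1:]),
        -1.0, 1.0,
    )
    return float(np.degrees(np.arccos(cosang)).sum())


def filter_u_shaped(
    tractogram: StreamlineSet,
    max_length_mm: float = 25.0,
    turning_threshold_deg: float = 90.0,
) -> StreamlineSet:
    """Select short, strongly curved (U-shaped) streamlines.

    Retains streamlines whose arc length is at most ``max_length_mm`` and
    whose total turning angle is at least ``turning_threshold_deg``.
    """
    if max_length_mm <= 0 or turning_threshold_deg <= 0:
        raise ValueError("thresholds must be positive")
    keep = [
        k for k, sl in enumerate(tractogram)
        if streamline_length(sl) <= max_length_mm
        and turning_angle_deg(sl) >= turning_threshold_deg
    ]
    return StreamlineSet(
        streamlines=[tractogram.streamlines[k] for k in keep],
        true_cell=None if tractogram.true_cell is None
        else [tractogram.true_cell[k] for k in keep],
        csf_tag=None if tractogram.csf_tag is None
        else tractogram.csf_tag[keep],
    )
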