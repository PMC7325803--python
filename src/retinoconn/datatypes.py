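"""Shared data containers for the V1-V2 U-fiber connectivity pipeline.

Conventions used throughout the package (documented once, here):

* World coordinates are millimetres.  Label volumes carry a 4x4 affine mapping
  0-based voxel indices to the mm coordinates of voxel *centers*; voxel
  ``(i, j, k)`` spans ``[i - 0.5, i + 0.5)`` along each axis in voxel space.
* Label codes: 0 background, 1-6 the six V1 retinotopic segments, 7-12 the six
  V2 retinotopic segments, 13 cerebrospinal fluid.
* Streamlines are polylines of mm points sampled at ~0.2 mm steps; their arc
  length is the sum of consecutive point distances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

# Label-volume code layout
BACKGROUND_CODE = 0
V1_CODES = tuple(range(1, 7))
V2_CODES = tuple(range(7, 13))
CSF_CODE = 13

#: tractography step size (mm) used when sampling synthetic streamlines
TRACK_STEP_MM = 0.2
#: streamline length tracking range (mm)
LENGTH_RANGE_MM = (3.0, 100.0)

AREA_NONE, AREA_V1, AREA_V2 = 0, 1, 2


@dataclass
class RetinoPatch:
    """Triangulated cortical patch with ground-truth retinotopy.

    Attributes
    ----------
    vertex_coords : (N, 3) float array
        Vertex positions in mm.
    faces : (M, 3) int array
        Triangle vertex-index triples.
    ecc_true : (N,) float array
        Visual eccentricity per vertex, degrees of visual angle (>= 0).
    pol_true : (N,) float array
        Polar angle per vertex, radians in [0, 2*pi).
    area_label : (N,) int array
        0 = none, 1 = V1, 2 = V2.
    segment_true : (N,) int array
        Ground-truth retinotopic segment id (0 unassigned, 1-6 V1, 7-12 V2).
    """

    vertex_coords: np.ndarray
    faces: np.ndarray
    ecc_true: np.ndarray
    pol_true: np.ndarray
    area_label: np.ndarray
    segment_true: np.ndarray

    def __post_init__(self) -> None:
        self.vertex_coords = np.asarray(self.vertex_coords, dtype=float)
        self.faces = np.asarray(self.faces, dtype=int)
        self.ecc_true = np.asarray(self.ecc_true, dtype=float)
        self.pol_true = np.asarray(self.pol_true, dtype=float)
        self.area_label = np.asarray(self.area_label, dtype=int)
        self.segment_true = np.asarray(self.segment_true, dtype=int)
        n = self.vertex_coords.shape[0]
        if not (len(self.ecc_true) == len(self.pol_true)
                == len(self.area_label) == len(self.segment_true) == n):
            raise ValueError("per-vertex arrays must all have length N")
        if np.any(self.ecc_true < 0):
            raise ValueError("eccentricity must be non-negative")
        if np.any((self.pol_true < 0) | (self.pol_true >= 2 * np.pi)):
            raise ValueError("polar angle must lie in [0, 2*pi)")

    @property
    def n_vertices(self) -> int:
        return self.vertex_coords.shape[0]

    @property
    def v1_mask(self) -> np.ndarray:
        return self.area_label == AREA_V1

    @property
    def v2_mask(self) -> np.ndarray:
        return self.area_label == AREA_V2


@dataclass
class BoldRun:
    """One phase-encoded functional run sampled on patch vertices.

    ``series`` is (N_vertices, T).  ``t0_s`` is the acquisition time of the
    first retained sample relative to stimulus onset; discarding initial
    samples advances it so that stimulus phase stays referenced to onset.
    """

    series: np.ndarray
    tr_s: float
    cycle_period_s: float
    n_cycles: float
    direction: int
    dimension: str  # "eccentricity" or "polar"
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        self.series = np.asarray(self.series, dtype=float)
        if self.direction not in (+1, -1):
            raise ValueError("direction must be +1 or -1")
        if self.dimension not in ("eccentricity", "polar"):
            raise ValueError("dimension must be 'eccentricity' or 'polar'")
        if self.tr_s <= 0 or self.cycle_period_s <= 0:
            raise ValueError("tr_s and cycle_period_s must be positive")
        if self.n_samples * self.tr_s < self.n_cycles * self.cycle_period_s - 1e-9:
            raise ValueError("run too short for the declared number of cycles")

    @property
    def n_samples(self) -> int:
        return self.series.shape[1]

    @property
    def stimulus_frequency_hz(self) -> float:
        return 1.0 / self.cycle_period_s

    @property
    def times_s(self) -> np.ndarray:
        return self.t0_s + np.arange(self.n_samples) * self.tr_s


@dataclass
class SegmentLabelVolume:
    """3D integer label grid with a voxel-center affine."""

    grid: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.grid.ndim != 3:
            raise ValueError("grid must be 3D")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        declared = {BACKGROUND_CODE, *V1_CODES, *V2_CODES, CSF_CODE}
        present = set(np.unique(self.grid).tolist())
        if not present <= declared:
            raise ValueError(f"unexpected label codes: {sorted(present - declared)}")

    def world_to_voxel(self, points_mm: np.ndarray) -> np.ndarray:
        """Map (P, 3) mm points to continuous 0-based voxel coordinates."""
        pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
        inv = np.linalg.inv(self.affine)
        return pts @ inv[:3, :3].T + inv[:3, 3]

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map (P, 3) voxel indices to the mm coordinates of voxel centers."""
        idx = np.atleast_2d(np.asarray(ijk, dtype=float))
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]

    def voxels_with_code(self, code: int) -> np.ndarray:
        return np.argwhere(self.grid == code)


@dataclass
class StreamlineSet:
    """A list of mm-space polylines, the unit of connectivity evidence.

    ``true_cell`` optionally records, per streamline, the generator's
    ground-truth (V1 segment, V2 segment) pair as 1-based indices; ``csf_tag``
    marks streamlines deliberately routed through CSF.
    """

    streamlines: list[np.ndarray]
    true_cell: list[tuple[int, int]] | None = None
    csf_tag: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.streamlines = [np.asarray(s, dtype=float) for s in self.streamlines]
        for s in self.streamlines:
            if s.ndim != 2 or s.shape[1] != 3 or s.shape[0] < 2:
                raise ValueError("each streamline must be an (k>=2, 3) array")
        if self.csf_tag is not None:
            self.csf_tag = np.asarray(self.csf_tag, dtype=bool)

    def __len__(self) -> int:
        return len(self.streamlines)

    def __iter__(self):
        return iter(self.streamlines)

    @property
    def lengths(self) -> np.ndarray:
        """Arc length (mm) of every streamline."""
        return np.array(
            [float(np.linalg.norm(np.diff(s, axis=0), axis=1).sum())
             for s in self.streamlines]
        )


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic study generator.

    Defaults emulate the study conditions: retinotopic (diagonal) streamline
    lengths 16 +/- 4 mm, non-retinotopic 32 +/- 13 mm, lengths clipped to the
    3-100 mm tracking range, 1000 streamlines per hemisphere, and a diagonal
    mass fraction of 0.7 (approximating the observed ~73% retinotopic share).
    """

    seed: int = 0
    n_streamlines: int = 1000
    n_streamlines_per_cell: np.ndarray | None = None
    retino_bias: float = 0.7
    length_mean_retino: float = 16.0
    length_sd_retino: float = 4.0
    length_mean_nonretino: float = 32.0
    length_sd_nonretino: float = 13.0
    csf_contaminant_fraction: float = 0.05
    noise_sd: float = 0.1
    hemodynamic_delay_s: float = 5.0
    drift_amplitude: float = 0.5
    baseline: float = 100.0
    response_amplitude: float = 1.0

    def __post_init__(self) -> None:
        for name in ("retino_bias", "csf_contaminant_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in ("length_sd_retino", "length_sd_nonretino", "noise_sd",
                     "drift_amplitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_streamlines_per_cell is not None:
            tab = np.asarray(self.n_streamlines_per_cell, dtype=int)
            if tab.shape != (6, 6) or np.any(tab < 0):
                raise ValueError("n_streamlines_per_cell must be 6x6 non-negative")
            self.n_streamlines_per_cell = tab

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        if d["n_streamlines_per_cell"] is not None:
            d["n_streamlines_per_cell"] = np.asarray(
                d["n_streamlines_per_cell"]).tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        return cls(**d)
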