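"""Synthetic study generator.

Produces every input the pipeline consumes with known ground truth: a
retinotopic cortical patch, phase-encoded BOLD runs, segment label volumes,
U-shaped streamline bundles, and b=0 image series with coil-dependent tSNR.

The generator emulates the study conditions: an expanding-ring / rotating-ray
phase-encoded paradigm (8.25 cycles; cycle periods 36 s eccentricity, 60 s
polar), streamline lengths of 16 +/- 4 mm for retinotopically matched and
32 +/- 13 mm for non-matched V1-V2 pairs (truncated to the 3-100 mm tracking
range, 0.2 mm step), and a surface-coil tSNR profile with a near/deep ratio
of about 1.7.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq
from scipy.stats import truncnorm

from .datatypes import (
    AREA_NONE,
    AREA_V1,
    AREA_V2,
    CSF_CODE,
    LENGTH_RANGE_MM,
    TRACK_STEP_MM,
    BoldRun,
    GeneratorConfig,
    RetinoPatch,
    SegmentLabelVolume,
    StreamlineSet,
)
from .retinotopy import assign_segments

# fixed sub-stream ids so every simulated quantity has its own RNG stream
_STREAM_BOLD = 1
_STREAM_TRACKS = 3
_STREAM_B0 = 5

DEFAULT_CYCLE_PERIOD_S = {"eccentricity": 36.0, "polar": 60.0}

# stimulus phase is mapped into this sub-range of [0, 2*pi) so that noise
# cannot push estimates across the 0/2*pi wrap, which would break the
# min-max scaling used for segmentation
_PHASE_LO_FRAC = 0.1
_PHASE_HI_FRAC = 0.9


def _rng(cfg: GeneratorConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(cfg.seed), stream])


def make_retino_patch(
    n_vertices_per_axis: int = 17,
    spacing_mm: float = 0.6,
    ecc_max_deg: float = 8.0,
    pol_max_rad: float = np.pi,
) -> RetinoPatch:
    """Build a flat two-band patch with linear ground-truth retinotopy.

    The patch is a regular grid in the z=0 plane.  Rows below the middle gap
    row are V1, rows above are V2.  Eccentricity increases along +x in both
    areas; polar angle increases with +y in V1 and decreases with +y in V2
    (mirrored), so the two areas carry opposite visual field signs and
    matched-polar segments sit adjacent across the border.
    """
    n = int(n_vertices_per_axis)
    if n < 4:
        raise ValueError("n_vertices_per_axis must be >= 4")
    rows, cols = np.mgrid[0:n, 0:n]
    rows, cols = rows.ravel(), cols.ravel()
    coords = np.column_stack(
        [cols * spacing_mm, rows * spacing_mm, np.zeros(n * n)]
    )
    # a one-row unlabeled gap separates the bands when the grid allows it
    # (each band needs >= 2 rows so polar angle varies within the band)
    if n >= 6:
        v1_top, v2_bot = (n - 1) // 2 - 1, (n - 1) // 2 + 1
    else:
        v1_top, v2_bot = n // 2 - 1, n // 2
    area = np.full(n * n, AREA_NONE, dtype=int)
    area[rows <= v1_top] = AREA_V1
    area[rows >= v2_bot] = AREA_V2
    if not np.any(area == AREA_V1) or not np.any(area == AREA_V2):
        raise ValueError("layout produced an empty V1 or V2 band")

    ecc = ecc_max_deg * cols / (n - 1)
    pol = np.full(n * n, 0.5 * pol_max_rad)
    v1, v2 = area == AREA_V1, area == AREA_V2
    pol[v1] = pol_max_rad * rows[v1] / v1_top
    pol[v2] = pol_max_rad * (n - 1 - rows[v2]) / (n - 1 - v2_bot)

    faces = []
    for r in range(n - 1):
        for c in range(n - 1):
            i = r * n + c
            faces.append((i, i + 1, i + n))
            faces.append((i + 1, i + n + 1, i + n))
    segment = assign_segments(ecc, pol, area)
    return RetinoPatch(
        vertex_coords=coords,
        faces=np.array(faces, dtype=int),
        ecc_true=ecc,
        pol_true=pol,
        area_label=area,
        segment_true=segment,
    )


def true_phase(patch: RetinoPatch, dimension: str) -> np.ndarray:
    """Ground-truth stimulus phase per vertex for one mapping dimension.

    The true retinotopic value is mapped linearly onto
    ``[0.1*2*pi, 0.9*2*pi]`` across the whole patch.
    """
    values = patch.ecc_true if dimension == "eccentricity" else patch.pol_true
    vmin, vmax = values.min(), values.max()
    frac = (values - vmin) / (vmax - vmin)
    return 2 * np.pi * (_PHASE_LO_FRAC + (_PHASE_HI_FRAC - _PHASE_LO_FRAC) * frac)


def noise_sd_for_amplitude_snr(
    amplitude: float, n_samples: int, snr: float
) -> float:
    """Time-domain noise SD giving a single-run Fourier-amplitude SNR.

    White noise of SD ``sigma`` contributes SD ``sigma*sqrt(2/T)`` per
    component of the stimulus-frequency coefficient, so
    ``sigma = amplitude * sqrt(T/2) / snr``.
    """
    return amplitude * np.sqrt(n_samples / 2.0) / snr


def simulate_phase_encoded_runs(
    patch: RetinoPatch,
    cfg: GeneratorConfig,
    dimension: str,
    tr_s: float = 3.0,
    cycle_period_s: float | None = None,
    n_cycles: float = 8.25,
) -> tuple[BoldRun, BoldRun]:
    """Simulate a forward/reversed pair of phase-encoded runs.

    Per vertex: ``baseline + A*cos(2*pi*f*t - direction*phi_true - delta)
    + drift + noise`` where ``delta = 2*pi*f*hemodynamic_delay_s`` is common
    to both runs.  Drift is a slow half-cosine plus a linear ramp with
    per-vertex random coefficients; the two runs get independent noise.
    """
    if cycle_period_s is None:
        cycle_period_s = DEFAULT_CYCLE_PERIOD_S[dimension]
    if tr_s <= 0 or cycle_period_s <= 0:
        raise ValueError("tr_s and cycle_period_s must be positive")
    if cycle_period_s <= 2 * tr_s:
        raise ValueError("cycle period must exceed two TRs")
    n_samples = int(np.ceil(n_cycles * cycle_period_s / tr_s - 1e-9))
    t = np.arange(n_samples) * tr_s
    f = 1.0 / cycle_period_s
    phi = true_phase(patch, dimension)
    delta = 2 * np.pi * f * cfg.hemodynamic_delay_s
    duration = n_samples * tr_s
    rng = _rng(cfg, _STREAM_BOLD if dimension == "eccentricity"
               else _STREAM_BOLD + 1)
    runs = []
    for direction in (+1, -1):
        signal = cfg.baseline + cfg.response_amplitude * np.cos(
            2 * np.pi * f * t[None, :] - direction * phi[:, None] - delta
        )
        c = rng.standard_normal((patch.n_vertices, 2))
        drift = cfg.drift_amplitude * (
            c[:, :1] * np.cos(np.pi * t / duration)[None, :]
            + c[:, 1:] * (t / duration - 0.5)[None, :]
        )
        noise = cfg.noise_sd * rng.standard_normal((patch.n_vertices, n_samples))
        runs.append(
            BoldRun(
                series=signal + drift + noise,
                tr_s=tr_s,
                cycle_period_s=cycle_period_s,
                n_cycles=n_cycles,
                direction=direction,
                dimension=dimension,
            )
        )
    return runs[0], runs[1]


def make_label_volume(
    patch: RetinoPatch,
    segments: np.ndarray | None = None,
    voxel_size_mm: float | None = None,
    csf_layout: str | None = "slab",
    margin_mm: float = 2.0,
    csf_offset_mm: float = 4.0,
    csf_thickness_mm: float = 2.0,
) -> SegmentLabelVolume:
    """Rasterize per-vertex segment ids into a label volume with a CSF slab.

    Each labeled vertex marks its containing voxel; by default the voxel size
    matches the patch vertex spacing so every labeled vertex owns one voxel.
    The CSF slab spans the full x-y extent at ``z in [csf_offset_mm,
    csf_offset_mm + csf_thickness_mm)``, above the patch plane; synthetic
    U-fibers bulge in -z and therefore avoid it unless deliberately routed
    through.
    """
    if voxel_size_mm is None:
        xs = np.unique(patch.vertex_coords[:, 0])
        voxel_size_mm = float(np.min(np.diff(xs))) if len(xs) > 1 else 1.0
    if voxel_size_mm <= 0:
        raise ValueError("voxel_size_mm must be positive")
    if segments is None:
        segments = patch.segment_true
    segments = np.asarray(segments, dtype=int)
    v1_bad = (patch.area_label == AREA_V1) & ~np.isin(segments, range(0, 7))
    v2_bad = (patch.area_label == AREA_V2) & \
        ~((segments == 0) | np.isin(segments, range(7, 13)))
    if np.any(v1_bad) or np.any(v2_bad):
        raise ValueError("segment ids must be 1-6 on V1 and 7-12 on V2 vertices")

    lo = patch.vertex_coords.min(axis=0) - margin_mm
    hi = patch.vertex_coords.max(axis=0) + margin_mm
    z_top = (csf_offset_mm + csf_thickness_mm + margin_mm
             if csf_layout == "slab" else hi[2])
    shape = tuple(
        int(np.floor((h - l) / voxel_size_mm)) + 1
        for l, h in zip(lo, (hi[0], hi[1], z_top))
    )
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    affine[:3, 3] = lo
    grid = np.zeros(shape, dtype=np.int16)

    vox = np.floor((patch.vertex_coords - lo) / voxel_size_mm + 0.5).astype(int)
    for idx, seg in zip(vox, segments):
        if seg > 0:
            grid[tuple(idx)] = seg

    if csf_layout == "slab":
        z_centers = lo[2] + np.arange(shape[2]) * voxel_size_mm
        in_slab = (z_centers >= csf_offset_mm) & \
                  (z_centers < csf_offset_mm + csf_thickness_mm)
        grid[:, :, in_slab] = CSF_CODE
    elif csf_layout not in (None, "none"):
        raise ValueError(f"unknown csf_layout {csf_layout!r}")
    return SegmentLabelVolume(grid=grid, affine=affine)


def cell_probabilities(retino_bias: float) -> np.ndarray:
    """6x6 cell probabilities implied by the diagonal-preference mixture.

    A fraction ``retino_bias`` of the probability mass is split evenly over
    the six diagonal (retinotopically matched) cells; the remaining mass is
    spread uniformly over all 36 cells.  The expected diagonal share is
    therefore ``retino_bias + (1 - retino_bias) / 6`` (75% at the default
    bias of 0.7), and ``retino_bias = 0`` gives the uniform chance model.
    """
    p = np.full((6, 6), (1.0 - retino_bias) / 36.0)
    p[np.diag_indices(6)] += retino_bias / 6.0
    return p


def simulate_cell_counts(
    cfg: GeneratorConfig, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Draw the 6x6 streamline count table (the generator's multinomial core)."""
    if cfg.n_streamlines_per_cell is not None:
        return np.asarray(cfg.n_streamlines_per_cell, dtype=int).copy()
    if rng is None:
        rng = _rng(cfg, _STREAM_TRACKS)
    p = cell_probabilities(cfg.retino_bias).ravel()
    return rng.multinomial(cfg.n_streamlines, p).reshape(6, 6)


def _arc_points(
    p1: np.ndarray,
    p2: np.ndarray,
    bulge: np.ndarray,
    theta: float,
    step_mm: float = TRACK_STEP_MM,
) -> np.ndarray:
    """Circular arc from p1 to p2 subtending half-angle ``theta``.

    The arc lies in the plane spanned by the chord and ``bulge`` and bulges
    toward ``bulge``.  ``theta -> 0`` degenerates to the straight segment.
    """
    chord = p2 - p1
    c = np.linalg.norm(chord)
    u = chord / c
    w = bulge - (bulge @ u) * u
    w_norm = np.linalg.norm(w)
    if w_norm < 1e-12:
        raise ValueError("bulge direction parallel to chord")
    w = w / w_norm
    if theta < 1e-6:
        n_pts = max(2, int(np.ceil(c / step_mm)) + 1)
        return p1 + np.linspace(0, 1, n_pts)[:, None] * chord
    radius = c / (2 * np.sin(theta))
    length = 2 * theta * radius
    center = 0.5 * (p1 + p2) - radius * np.cos(theta) * w
    n_pts = max(2, int(np.ceil(length / step_mm)) + 1)
    alpha = np.linspace(-theta, theta, n_pts)
    return center + radius * (
        np.sin(alpha)[:, None] * u + np.cos(alpha)[:, None] * w
    )


def _theta_for_length(chord: float, length: float) -> float:
    """Half-angle of a circular arc with given chord and arc length."""
    ratio = length / chord
    if ratio <= 1.0 + 1e-12:
        return 0.0
    return brentq(lambda th: th / np.sin(th) - ratio, 1e-9, np.pi - 1e-9)


def simulate_streamlines(
    labels: SegmentLabelVolume,
    cfg: GeneratorConfig,
    max_attempts: int = 500,
) -> StreamlineSet:
    """Generate U-shaped streamlines between V1 and V2 segment voxels.

    Cell assignment follows ``cfg.n_streamlines_per_cell`` if given, else a
    multinomial over the ``retino_bias`` cell distribution.  Lengths are drawn
    from the class truncated normal on [3, 100] mm and held fixed while
    endpoints are resampled within the target segments until feasible
    (length >= endpoint distance).  A ``csf_contaminant_fraction`` of
    streamlines is instead arched upward through the CSF slab and tagged.
    """
    rng = _rng(cfg, _STREAM_TRACKS)
    counts = simulate_cell_counts(cfg, rng)
    voxels = {}
    for code in range(1, 13):
        vox = labels.voxels_with_code(code)
        if len(vox) == 0:
            raise ValueError(f"label volume is missing segment code {code}")
        voxels[code] = vox
    vsize = float(np.abs(np.diag(labels.affine)[:3]).mean())

    total = int(counts.sum())
    specs = [(i, j) for i in range(6) for j in range(6)
             for _ in range(counts[i, j])]
    n_contam = int(round(cfg.csf_contaminant_fraction * total))
    contam = np.zeros(total, dtype=bool)
    if n_contam > 0:
        csf_vox = labels.voxels_with_code(CSF_CODE)
        if len(csf_vox) == 0:
            raise ValueError("contaminants requested but volume has no CSF")
        apex_z = labels.voxel_to_world(csf_vox)[:, 2].max() + 0.5 * vsize
        contam[rng.choice(total, size=n_contam, replace=False)] = True

    lo_mm, hi_mm = LENGTH_RANGE_MM
    down, up = np.array([0.0, 0.0, -1.0]), np.array([0.0, 0.0, 1.0])
    streamlines: list[np.ndarray] = []
    cells: list[tuple[int, int]] = []

    def draw_endpoints(i: int, j: int) -> tuple[np.ndarray, np.ndarray]:
        out = []
        for code in (i + 1, j + 7):
            vlist = voxels[code]
            vox = vlist[rng.integers(len(vlist))]
            jitter = rng.uniform(-0.499, 0.499, size=3) * vsize
            out.append(labels.voxel_to_world(vox)[0] + jitter)
        return out[0], out[1]

    for k, (i, j) in enumerate(specs):
        if contam[k]:
            p1, p2 = draw_endpoints(i, j)
            c = np.linalg.norm(p2 - p1)
            apex = apex_z - 0.5 * (p1[2] + p2[2])
            theta = 2.0 * np.arctan(2.0 * apex / c)
            streamlines.append(_arc_points(p1, p2, up, theta))
            cells.append((i + 1, j + 1))
            continue
        mu, sd = (
            (cfg.length_mean_retino, cfg.length_sd_retino) if i == j
            else (cfg.length_mean_nonretino, cfg.length_sd_nonretino)
        )
        a, b = (lo_mm - mu) / sd, (hi_mm - mu) / sd
        length = float(truncnorm.rvs(a, b, loc=mu, scale=sd, random_state=rng))
        placed = False
        for attempt in range(max_attempts):
            p1, p2 = draw_endpoints(i, j)
            c = np.linalg.norm(p2 - p1)
            if c <= length:
                placed = True
                break
            if (attempt + 1) % 50 == 0:  # length below the cell's reach
                length = float(
                    truncnorm.rvs(a, b, loc=mu, scale=sd, random_state=rng)
                )
        if not placed:
            raise RuntimeError(
                f"could not place a streamline of feasible length in cell "
                f"({i + 1}, {j + 1}) after {max_attempts} attempts"
            )
        theta = _theta_for_length(c, length)
        streamlines.append(_arc_points(p1, p2, down, theta))
        cells.append((i + 1, j + 1))

    return StreamlineSet(streamlines=streamlines, true_cell=cells, csf_tag=contam)


def simulate_b0_series(
    shape: tuple[int, int, int],
    n_volumes: int,
    coil_profile: str = "uniform",
    tsnr_target: float = 20.0,
    near_deep_ratio: float = 1.7,
    mean_intensity: float = 100.0,
    axis: int = 0,
    near_frac: float = 0.25,
    deep_frac: float = 0.6,
    seed: int = 0,
) -> np.ndarray:
    """Simulate a 4D b=0 series (time last) with a controlled tSNR profile.

    ``uniform``: every voxel targets ``tsnr_target``.  ``surface``: voxels
    within ``near_frac`` of the coil face (lowest indices along ``axis``)
    target ``tsnr_target``; voxels beyond ``deep_frac`` target
    ``tsnr_target / near_deep_ratio`` (default ratio 1.7); a linear ramp joins
    the two bands.
    """
    if n_volumes < 3:
        raise ValueError("need at least 3 volumes")
    if not np.isfinite(tsnr_target) or tsnr_target <= 0:
        raise ValueError("tsnr_target must be a finite positive number "
                         "(zero temporal noise is not representable)")
    if coil_profile == "uniform":
        tsnr_map = np.full(shape, float(tsnr_target))
    elif coil_profile == "surface":
        n = shape[axis]
        frac = np.arange(n) / max(n - 1, 1)
        deep = tsnr_target / near_deep_ratio
        ramp = np.clip((frac - near_frac) / (deep_frac - near_frac), 0.0, 1.0)
        profile = tsnr_target + (deep - tsnr_target) * ramp
        expand = [None] * 3
        expand[axis] = slice(None)
        tsnr_map = np.broadcast_to(
            profile[tuple(expand)], shape
        ).copy()
    else:
        raise ValueError(f"unknown coil_profile {coil_profile!r}")
    rng = np.random.default_rng([int(seed), _STREAM_B0])
    sd_map = mean_intensity / tsnr_map
    noise = rng.standard_normal((*shape, n_volumes))
    return mean_intensity + sd_map[..., None] * noise
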