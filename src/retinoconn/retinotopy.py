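"""Phase-encoded retinotopy analysis.

Recovers eccentricity / polar-angle phase maps from periodic-stimulation BOLD
runs, computes visual field sign, and derives the six V1 and six V2
retinotopic segments.

Phase convention
----------------
A response ``A * cos(2*pi*f*t - phi)`` at the stimulus frequency ``f`` has
phase ``+phi``; :func:`fourier_phase` returns the complex coefficient
``A * exp(1j*phi)`` with time referenced to stimulus onset, so discarding
initial samples does not shift phases.  Opposite-direction runs are combined
by conjugating the reversed-run coefficient and averaging complex values,
which cancels the common hemodynamic delay.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .datatypes import AREA_V1, AREA_V2, BoldRun, RetinoPatch

logger = logging.getLogger(__name__)

#: default high-pass cutoffs (Hz) per mapping dimension
DEFAULT_HIGHPASS_HZ = {"polar": 1.0 / 120.0, "eccentricity": 1.0 / 72.0}


@dataclass
class PhaseMap:
    """Per-vertex phase lag and response amplitude at the stimulus frequency."""

    phase: np.ndarray       # radians in [0, 2*pi)
    amplitude: np.ndarray   # >= 0, signal units
    dimension: str
    valid: np.ndarray | None = None  # False where phase is undefined

    def __post_init__(self) -> None:
        self.phase = np.mod(np.asarray(self.phase, dtype=float), 2 * np.pi)
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        if self.valid is None:
            self.valid = np.ones(self.phase.shape, dtype=bool)


@dataclass
class FieldSignMap:
    """Per-vertex visual field sign in {-1, 0, +1}."""

    sign: np.ndarray

    def __post_init__(self) -> None:
        self.sign = np.asarray(self.sign, dtype=int)
        if not set(np.unique(self.sign)) <= {-1, 0, 1}:
            raise ValueError("field sign values must be in {-1, 0, +1}")


@dataclass
class SegmentMap:
    """Per-vertex retinotopic segment id: 0 unassigned, 1-6 V1, 7-12 V2."""

    segment: np.ndarray

    def __post_init__(self) -> None:
        self.segment = np.asarray(self.segment, dtype=int)


def discard_initial_quarter_cycle(run: BoldRun) -> BoldRun:
    """Drop the first quarter stimulus cycle from a run.

    Removes ``round(0.25 * cycle_period_s / tr_s)`` samples and reduces the
    cycle count by 0.25; the sample clock origin is advanced so phases remain
    referenced to stimulus onset.
    """
    n_drop = int(round(0.25 * run.cycle_period_s / run.tr_s))
    samples_per_cycle = run.cycle_period_s / run.tr_s
    if run.n_samples - n_drop < samples_per_cycle:
        raise ValueError("run too short: less than one full cycle would remain")
    return BoldRun(
        series=run.series[:, n_drop:],
        tr_s=run.tr_s,
        cycle_period_s=run.cycle_period_s,
        n_cycles=run.n_cycles - 0.25,
        direction=run.direction,
        dimension=run.dimension,
        t0_s=run.t0_s + n_drop * run.tr_s,
    )


def highpass_filter(run: BoldRun, cutoff_hz: float | None = None) -> BoldRun:
    """Remove slow drift below ``cutoff_hz`` by discrete-cosine regression.

    A DCT basis restricted to frequencies at or below the cutoff (plus the
    constant term) is regressed out of every vertex time series.  The cutoff
    must lie below the stimulus frequency; defaults are 1/120 Hz for polar and
    1/72 Hz for eccentricity runs.
    """
    if cutoff_hz is None:
        cutoff_hz = DEFAULT_HIGHPASS_HZ[run.dimension]
    if cutoff_hz >= run.stimulus_frequency_hz:
        raise ValueError(
            f"cutoff {cutoff_hz:g} Hz is at or above the stimulus frequency "
            f"{run.stimulus_frequency_hz:g} Hz and would remove the response"
        )
    n = run.n_samples
    duration = n * run.tr_s
    # DCT-II regressor k has frequency k / (2 * duration)
    k_max = int(np.floor(2.0 * duration * cutoff_hz))
    t = np.arange(n)
    basis = [np.ones(n)]
    for k in range(1, k_max + 1):
        basis.append(np.cos(np.pi * k * (2 * t + 1) / (2 * n)))
    x_drift = np.column_stack(basis)
    # fit drift jointly with stimulus-frequency regressors and subtract only
    # the drift part, so the response component is preserved exactly even
    # though the finite drift basis is not orthogonal to it
    omega = 2 * np.pi * run.stimulus_frequency_hz * run.times_s
    x = np.column_stack([x_drift, np.cos(omega), np.sin(omega)])
    beta, *_ = np.linalg.lstsq(x, run.series.T, rcond=None)
    filtered = run.series - (x_drift @ beta[:x_drift.shape[1]]).T
    return BoldRun(
        series=filtered,
        tr_s=run.tr_s,
        cycle_period_s=run.cycle_period_s,
        n_cycles=run.n_cycles,
        direction=run.direction,
        dimension=run.dimension,
        t0_s=run.t0_s,
    )


def fourier_phase(run: BoldRun) -> np.ndarray:
    """Complex Fourier coefficient at the stimulus frequency, per vertex.

    Returns ``(2/T) * sum_t x_t * exp(+1j * 2*pi*f*t)`` with ``t`` the
    absolute sample times, which equals ``A * exp(1j*phi)`` for a response
    ``A*cos(2*pi*f*t - phi)`` over an integer number of cycles.
    """
    if abs(run.n_cycles - round(run.n_cycles)) > 1e-6:
        warnings.warn(
            f"non-integer cycle count {run.n_cycles}: spectral leakage expected",
            stacklevel=2,
        )
    t = run.times_s
    f = run.stimulus_frequency_hz
    carrier = np.exp(1j * 2 * np.pi * f * t)
    return (2.0 / run.n_samples) * (run.series @ carrier)


def combine_opposite_runs(
    fwd_coeff: np.ndarray, rev_coeff: np.ndarray, dimension: str = "eccentricity"
) -> PhaseMap:
    """Average opposite-direction coefficients to cancel hemodynamic delay.

    The reversed-run coefficient is conjugated, then the complex values are
    averaged: for forward phase ``phi + delta`` and reversed phase
    ``-phi + delta`` the combination has phase ``phi`` for any ``delta``.
    Vertices with zero amplitude in both runs are flagged invalid.
    """
    fwd_coeff = np.asarray(fwd_coeff, dtype=complex)
    rev_coeff = np.asarray(rev_coeff, dtype=complex)
    combined = 0.5 * (fwd_coeff + np.conj(rev_coeff))
    valid = ~((np.abs(fwd_coeff) == 0) & (np.abs(rev_coeff) == 0))
    if np.any(~valid):
        logger.warning("combine_opposite_runs: %d vertices with zero amplitude",
                       int(np.sum(~valid)))
    return PhaseMap(
        phase=np.angle(combined),
        amplitude=np.abs(combined),
        dimension=dimension,
        valid=valid,
    )


def estimate_phase_map(
    fwd: BoldRun,
    rev: BoldRun,
    cutoff_hz: float | None = None,
    discard_quarter: bool = True,
) -> PhaseMap:
    """Full per-dimension phase pipeline: discard, high-pass, Fourier, combine."""
    runs = []
    for run in (fwd, rev):
        if discard_quarter:
            run = discard_initial_quarter_cycle(run)
        run = highpass_filter(run, cutoff_hz)
        runs.append(run)
    if runs[0].direction != +1 or runs[1].direction != -1:
        raise ValueError("expected a (+1, -1) direction pair in that order")
    return combine_opposite_runs(
        fourier_phase(runs[0]), fourier_phase(runs[1]), dimension=fwd.dimension
    )


def field_sign(
    patch: RetinoPatch,
    ecc_map: PhaseMap,
    pol_map: PhaseMap,
    amplitude_threshold: float = 0.0,
) -> FieldSignMap:
    """Visual field sign: orientation of the (eccentricity, polar) mapping.

    Per triangle, the in-plane gradients of the two phase maps are computed by
    linear interpolation; the sign of the normal component of
    ``grad(ecc) x grad(pol)`` distinguishes mirror (-1) from non-mirror (+1)
    representations.  Triangle signs are area-weighted onto vertices.  The
    sign is 0 where the response amplitude falls below ``amplitude_threshold``
    or the phase is flagged invalid.
    """
    coords = patch.vertex_coords
    acc = np.zeros(patch.n_vertices)
    for tri in patch.faces:
        p0, p1, p2 = coords[tri]
        e1, e2 = p1 - p0, p2 - p0
        normal = np.cross(e1, e2)
        area2 = np.linalg.norm(normal)
        if area2 < 1e-12:
            logger.info("field_sign: skipping degenerate triangle %s", tri)
            continue
        n_hat = normal / area2
        # local orthonormal frame in the triangle plane
        u = e1 / np.linalg.norm(e1)
        v = np.cross(n_hat, u)
        a = np.array([[e1 @ u, e1 @ v], [e2 @ u, e2 @ v]])
        grads = []
        for pm in (ecc_map, pol_map):
            d = np.array([pm.phase[tri[1]] - pm.phase[tri[0]],
                          pm.phase[tri[2]] - pm.phase[tri[0]]])
            grads.append(np.linalg.solve(a, d))
        cross_z = grads[0][0] * grads[1][1] - grads[0][1] * grads[1][0]
        # orient by the face normal's dominant axis so winding is consistent
        orient = np.sign(n_hat[np.argmax(np.abs(n_hat))])
        acc[tri] += 0.5 * area2 * cross_z * orient
    sign = np.sign(acc).astype(int)
    low = (ecc_map.amplitude < amplitude_threshold) | \
          (pol_map.amplitude < amplitude_threshold) | \
          ~ecc_map.valid | ~pol_map.valid
    sign[low] = 0
    return FieldSignMap(sign=sign)


def assign_segments(
    ecc_values: np.ndarray,
    pol_values: np.ndarray,
    area_label: np.ndarray,
) -> np.ndarray:
    """Bin per-vertex (ecc, pol) values into the six segments of each area.

    Within each area the values are min-max scaled to [0, 1]; the polar axis
    is split into two bins at 0.5 and the eccentricity axis into three bins at
    1/3 and 2/3 (half-open bins, maximum value assigned to the last bin).
    Segment id = 1 + polar_bin*3 + ecc_bin, plus 6 for V2.
    """
    ecc_values = np.asarray(ecc_values, dtype=float)
    pol_values = np.asarray(pol_values, dtype=float)
    area_label = np.asarray(area_label, dtype=int)
    segment = np.zeros(area_label.shape, dtype=int)
    for area, offset in ((AREA_V1, 0), (AREA_V2, 6)):
        mask = area_label == area
        if not np.any(mask):
            continue
        bins = []
        for values, n_bins in ((pol_values, 2), (ecc_values, 3)):
            v = values[mask]
            vrange = v.max() - v.min()
            if vrange == 0:
                raise ValueError(
                    f"constant phase over area {area}: cannot scale to (0, 1)"
                )
            scaled = (v - v.min()) / vrange
            bins.append(np.minimum((scaled * n_bins).astype(int), n_bins - 1))
        segment[mask] = 1 + bins[0] * 3 + bins[1] + offset
    return segment


def segment_v1_v2(
    ecc_map: PhaseMap, pol_map: PhaseMap, area_label: np.ndarray
) -> SegmentMap:
    """Derive the six V1 and six V2 retinotopic segments from phase maps."""
    return SegmentMap(
        segment=assign_segments(ecc_map.phase, pol_map.phase, area_label)
    )
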