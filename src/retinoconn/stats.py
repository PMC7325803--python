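"""Inference on retinotopic vs non-retinotopic connectivity.

Implements the restricted (within-hemisphere sign-flip) exhaustive
permutation t-test on the retinotopic-minus-non-retinotopic connectivity
difference, element-wise ICC and coefficient-of-variation reliability
matrices, the 2x2 repeated-measures ANOVA on absolute streamline counts,
and the paired t-test on motion-parameter standard deviations.

Zero-variance t statistics are represented by a signed-infinity sentinel
(documented contract) so exhaustive permutation enumeration never aborts;
permutation values are then compared by value, with ties counting toward
the p-value (p uses ``>=``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass
class HemispherePair:
    """Total retinotopic / non-retinotopic strength for one hemisphere."""

    retinotopic: float
    nonretinotopic: float
    hemisphere_id: str = ""


@dataclass
class PermutationTestResult:
    """Observed t, exhaustive sign-flip t distribution, one-tailed p."""

    t_obs: float
    t_perm: np.ndarray
    p: float
    n_hemispheres: int

    @property
    def n_permutations(self) -> int:
        return len(self.t_perm)


@dataclass
class ReliabilityMatrices:
    """Element-wise ICC and CoV with NaN-aware summaries."""

    icc: np.ndarray
    cov: np.ndarray
    icc_form: str = "ICC(2,1)"
    cov_aggregation: str = "across_measurements"

    def _summary(self, m: np.ndarray) -> dict[str, tuple[float, float]]:
        diag = np.eye(6, dtype=bool)
        out = {}
        for name, mask in (("all", np.ones((6, 6), bool)),
                           ("retinotopic", diag),
                           ("nonretinotopic", ~diag)):
            vals = m[mask]
            out[name] = (float(np.nanmean(vals)), float(np.nanstd(vals)))
        return out

    @property
    def icc_summary(self) -> dict[str, tuple[float, float]]:
        return self._summary(self.icc)

    @property
    def cov_summary(self) -> dict[str, tuple[float, float]]:
        return self._summary(self.cov)


@dataclass
class AnovaResult:
    """2x2 within-subject ANOVA: connection type x coil."""

    F_type: float
    F_coil: float
    F_interaction: float
    p_type: float
    p_coil: float
    p_interaction: float
    dfs: dict[str, tuple[int, int]]


def _pairs_to_diffs(pairs) -> np.ndarray:
    if isinstance(pairs, np.ndarray):
        return np.asarray(pairs, dtype=float)
    return np.array([p.retinotopic - p.nonretinotopic for p in pairs])


def _t_from_diffs(d: np.ndarray) -> float:
    """One-sample t on differences with signed-infinity zero-variance sentinel."""
    n = len(d)
    sd = d.std(ddof=1)
    m = d.mean()
    if sd == 0:
        return 0.0 if m == 0 else float(np.sign(m)) * np.inf
    return float(m / (sd / np.sqrt(n)))


def paired_one_tailed_t(pairs) -> float:
    """Paired t over hemispheres on retinotopic - non-retinotopic differences.

    ``pairs`` is a list of :class:`HemispherePair` or an array of differences.
    All-equal nonzero differences yield the +/-inf sentinel.
    """
    d = _pairs_to_diffs(pairs)
    if len(d) < 2:
        raise ValueError("need at least two hemispheres")
    return _t_from_diffs(d)


def restricted_permutation_test(pairs) -> PermutationTestResult:
    """Exhaustive within-hemisphere swap (sign-flip) permutation t-test.

    Each hemisphere's retinotopic/non-retinotopic pair is independently kept
    or swapped, giving 2^H assignments (the identity included); the one-tailed
    p-value is the proportion of permutation t values that exceed or equal the
    observed t.
    """
    d = _pairs_to_diffs(pairs)
    h = len(d)
    if h < 2:
        raise ValueError("need at least two hemispheres")
    if h > 20:
        raise ValueError("exhaustive enumeration limited to H <= 20")
    if np.all(d == 0):
        raise ValueError("degenerate data: all differences are zero")
    n_perm = 2 ** h
    bits = (np.arange(n_perm)[:, None] >> np.arange(h)) & 1
    signs = 1 - 2 * bits  # row 0 = identity assignment
    flipped = signs * d
    means = flipped.mean(axis=1)
    sds = flipped.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_perm = means / (sds / np.sqrt(h))
    zero = sds == 0
    t_perm[zero] = np.sign(means[zero]) * np.inf
    t_obs = t_perm[0]
    p = float(np.count_nonzero(t_perm >= t_obs)) / n_perm
    return PermutationTestResult(
        t_obs=float(t_obs), t_perm=t_perm, p=p, n_hemispheres=h
    )


def _icc_2_1(values: np.ndarray) -> float:
    """Two-way random, single-measure, absolute-agreement ICC for (n, k) data."""
    n, k = values.shape
    grand = values.mean()
    row_means = values.mean(axis=1)
    col_means = values.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((values - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        return np.nan
    return float((msr - mse) / denom)


def icc_matrix(measA: np.ndarray, measB: np.ndarray) -> np.ndarray:
    """Element-wise ICC(2,1) between two measurements across hemispheres.

    ``measA``/``measB`` are (H, 6, 6) stacks.  Cells with zero
    between-hemisphere variance (or all values identical) are undefined (NaN).
    """
    a = np.asarray(measA, dtype=float)
    b = np.asarray(measB, dtype=float)
    if a.shape != b.shape or a.ndim != 3:
        raise ValueError("expect matching (H, 6, 6) stacks")
    if a.shape[0] < 3:
        raise ValueError("need at least three hemispheres")
    out = np.full(a.shape[1:], np.nan)
    for i in range(a.shape[1]):
        for j in range(a.shape[2]):
            vals = np.column_stack([a[:, i, j], b[:, i, j]])
            if np.ptp(vals) == 0 or np.ptp(vals.mean(axis=1)) == 0:
                continue  # undefined, left NaN
            out[i, j] = _icc_2_1(vals)
    return out


def cov_matrix(
    measA: np.ndarray,
    measB: np.ndarray,
    aggregation: str = "across_measurements",
) -> np.ndarray:
    """Element-wise coefficient of variation between two measurements.

    ``across_measurements`` (default): per hemisphere-cell, the sample SD of
    the two measurements divided by their mean, averaged over hemispheres.
    ``across_hemispheres``: per cell and measurement, SD across hemispheres
    divided by the mean across hemispheres, averaged over the two
    measurements.  Cells with non-positive means are undefined (NaN).
    """
    a = np.asarray(measA, dtype=float)
    b = np.asarray(measB, dtype=float)
    if a.shape != b.shape or a.ndim != 3:
        raise ValueError("expect matching (H, 6, 6) stacks")
    if aggregation == "across_measurements":
        pair = np.stack([a, b])                    # (2, H, 6, 6)
        mean = pair.mean(axis=0)
        sd = pair.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            cv = np.where(mean > 0, sd / mean, np.nan)
        return np.nanmean(cv, axis=0)
    if aggregation == "across_hemispheres":
        out = []
        for m in (a, b):
            mean = m.mean(axis=0)
            sd = m.std(axis=0, ddof=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                out.append(np.where(mean > 0, sd / mean, np.nan))
        return np.nanmean(np.stack(out), axis=0)
    raise ValueError(f"unknown aggregation {aggregation!r}")


def reliability(
    measA: np.ndarray,
    measB: np.ndarray,
    cov_aggregation: str = "across_measurements",
) -> ReliabilityMatrices:
    """ICC and CoV reliability matrices between two measurement stacks."""
    return ReliabilityMatrices(
        icc=icc_matrix(measA, measB),
        cov=cov_matrix(measA, measB, aggregation=cov_aggregation),
        cov_aggregation=cov_aggregation,
    )


def _f_and_p(ms_effect: float, ms_error: float, df_err: int) -> tuple[float, float]:
    if ms_error == 0:
        if ms_effect == 0:
            return 0.0, 1.0
        return float(np.inf), 0.0
    f = ms_effect / ms_error
    return float(f), float(sps.f.sf(f, 1, df_err))


def rm_anova_2x2(counts: np.ndarray) -> AnovaResult:
    """2x2 repeated-measures ANOVA (connection type x coil) on counts.

    ``counts`` has shape (H, 2, 2): hemisphere x type {retinotopic,
    non-retinotopic} x coil.  Each effect is tested against its own
    effect-by-hemisphere interaction with df = (1, H-1).
    """
    y = np.asarray(counts, dtype=float)
    if y.ndim != 3 or y.shape[1:] != (2, 2):
        raise ValueError("counts must have shape (H, 2, 2)")
    if np.any(np.isnan(y)):
        raise ValueError("missing cells are not supported")
    h = y.shape[0]
    if h < 3:
        raise ValueError("need at least three hemispheres")
    grand = y.mean()
    m_s = y.mean(axis=(1, 2))            # subject
    m_a = y.mean(axis=(0, 2))            # type
    m_b = y.mean(axis=(0, 1))            # coil
    m_sa = y.mean(axis=2)                # (H, 2)
    m_sb = y.mean(axis=1)                # (H, 2)
    m_ab = y.mean(axis=0)                # (2, 2)

    ss_a = 2 * h * np.sum((m_a - grand) ** 2)
    ss_b = 2 * h * np.sum((m_b - grand) ** 2)
    ss_ab = h * np.sum((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2)
    ss_as = 2 * np.sum((m_sa - m_s[:, None] - m_a[None, :] + grand) ** 2)
    ss_bs = 2 * np.sum((m_sb - m_s[:, None] - m_b[None, :] + grand) ** 2)
    resid = (
        y
        - m_sa[:, :, None] - m_sb[:, None, :] - m_ab[None, :, :]
        + m_s[:, None, None] + m_a[None, :, None] + m_b[None, None, :]
        - grand
    )
    ss_abs = np.sum(resid ** 2)

    df_err = h - 1
    f_a, p_a = _f_and_p(ss_a, ss_as / df_err, df_err)
    f_b, p_b = _f_and_p(ss_b, ss_bs / df_err, df_err)
    f_ab, p_ab = _f_and_p(ss_ab, ss_abs / df_err, df_err)
    return AnovaResult(
        F_type=f_a, F_coil=f_b, F_interaction=f_ab,
        p_type=p_a, p_coil=p_b, p_interaction=p_ab,
        dfs={"type": (1, df_err), "coil": (1, df_err),
             "interaction": (1, df_err)},
    )


MOTION_PARAMETERS = ("trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z")


def motion_sd_paired_test(
    sdA: np.ndarray, sdB: np.ndarray
) -> dict[str, tuple[float, float]]:
    """Two-tailed paired t per motion parameter on per-participant SDs.

    ``sdA``/``sdB`` are (n_participants, 6) arrays (3 translations then 3
    rotations).  Returns ``{parameter: (t, p)}`` with the usual signed-infinity
    sentinel for zero-variance differences.
    """
    a = np.asarray(sdA, dtype=float)
    b = np.asarray(sdB, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 6:
        raise ValueError("expect matching (n_participants, 6) arrays")
    if a.shape[0] < 2:
        raise ValueError("need at least two participants")
    out = {}
    for k, name in enumerate(MOTION_PARAMETERS):
        d = a[:, k] - b[:, k]
        t = _t_from_diffs(d)
        if np.isinf(t):
            p = 0.0
        elif t == 0 and d.std(ddof=1) == 0:
            p = 1.0
        else:
            p = float(2 * sps.t.sf(abs(t), len(d) - 1))
        out[name] = (t, p)
    return out
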