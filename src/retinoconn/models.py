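"""Model objects over the inferential layer.

Thin statsmodels-style wrappers: a model is constructed from data, ``fit()``
returns a results object carrying estimates, the permutation distribution or
reliability matrices, and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .connectivity import ConnectivityMatrix, partition_connectivity
from .stats import (
    AnovaResult,
    HemispherePair,
    PermutationTestResult,
    ReliabilityMatrices,
    reliability,
    restricted_permutation_test,
    rm_anova_2x2,
)


class RetinotopicConnectivity:
    """Test whether retinotopic exceeds non-retinotopic V1-V2 connectivity.

    Built from one connectivity matrix per hemisphere; ``fit()`` partitions
    each matrix into its diagonal/off-diagonal percentage shares and runs the
    exhaustive within-hemisphere sign-flip permutation t-test.

    Parameters
    ----------
    matrices : sequence of ConnectivityMatrix or (H, 6, 6) count array
    """

    def __init__(self, matrices):
        self.matrices = [
            m if isinstance(m, ConnectivityMatrix) else ConnectivityMatrix(m)
            for m in matrices
        ]
        if len(self.matrices) < 2:
            raise ValueError("need at least two hemispheres")

    @classmethod
    def from_counts(cls, counts: np.ndarray) -> "RetinotopicConnectivity":
        return cls(list(np.asarray(counts, dtype=int)))

    def fit(self, alpha: float = 0.05) -> "RetinotopicConnectivityResults":
        pairs = []
        for m in self.matrices:
            part = partition_connectivity(m)
            pairs.append(HemispherePair(
                retinotopic=part.retinotopic_pct,
                nonretinotopic=part.nonretinotopic_pct,
                hemisphere_id=m.hemisphere_id,
            ))
        perm = restricted_permutation_test(pairs)
        return RetinotopicConnectivityResults(
            model=self, pairs=pairs, permutation=perm, alpha=alpha
        )


@dataclass
class RetinotopicConnectivityResults:
    model: RetinotopicConnectivity
    pairs: list[HemispherePair]
    permutation: PermutationTestResult
    alpha: float

    @property
    def retinotopic_pct(self) -> float:
        """Group-mean diagonal (retinotopic) share of total connectivity."""
        return float(np.mean([p.retinotopic for p in self.pairs]))

    @property
    def nonretinotopic_pct(self) -> float:
        return float(np.mean([p.nonretinotopic for p in self.pairs]))

    @property
    def t_obs(self) -> float:
        return self.permutation.t_obs

    @property
    def pvalue(self) -> float:
        return self.permutation.p

    @property
    def reject(self) -> bool:
        return self.pvalue <= self.alpha

    def summary(self) -> str:
        h = self.permutation.n_hemispheres
        lines = [
            "Retinotopic V1-V2 connectivity, restricted permutation t-test",
            "=" * 62,
            f"hemispheres:            {h}",
            f"retinotopic share:      {self.retinotopic_pct:8.2f} %",
            f"non-retinotopic share:  {self.nonretinotopic_pct:8.2f} %",
            f"observed t:             {self.t_obs:8.3f}",
            f"permutations:           {self.permutation.n_permutations}"
            f"  (2^{h}, identity included)",
            f"one-tailed p:           {self.pvalue:8.4f}"
            f"   (min achievable {1.0 / 2 ** h:.4f})",
            f"reject at alpha={self.alpha:g}:   {self.reject}",
        ]
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "hemisphere": [p.hemisphere_id for p in self.pairs],
                "retinotopic_pct": [p.retinotopic for p in self.pairs],
                "nonretinotopic_pct": [p.nonretinotopic for p in self.pairs],
            }
        )


class ReliabilityStudy:
    """Scan-rescan / cross-coil reliability of connectivity matrices.

    Built from two (H, 6, 6) measurement stacks; ``fit()`` computes the
    element-wise ICC(2,1) and coefficient-of-variation matrices.
    """

    def __init__(self, measA: np.ndarray, measB: np.ndarray):
        self.measA = np.asarray(measA, dtype=float)
        self.measB = np.asarray(measB, dtype=float)

    def fit(
        self, cov_aggregation: str = "across_measurements"
    ) -> "ReliabilityResults":
        mats = reliability(self.measA, self.measB,
                           cov_aggregation=cov_aggregation)
        return ReliabilityResults(model=self, matrices=mats)


@dataclass
class ReliabilityResults:
    model: ReliabilityStudy
    matrices: ReliabilityMatrices

    @property
    def icc(self) -> np.ndarray:
        return self.matrices.icc

    @property
    def cov(self) -> np.ndarray:
        return self.matrices.cov

    def summary(self) -> str:
        icc_s = self.matrices.icc_summary
        cov_s = self.matrices.cov_summary
        lines = [
            "Connectivity reliability (element-wise across hemispheres)",
            "=" * 62,
            f"ICC form: {self.matrices.icc_form};  "
            f"CoV aggregation: {self.matrices.cov_aggregation}",
        ]
        for name in ("all", "retinotopic", "nonretinotopic"):
            m, s = icc_s[name]
            cm, cs = cov_s[name]
            lines.append(
                f"{name:>15}:  ICC {m:5.2f} +/- {s:4.2f}   "
                f"CoV {cm:5.2f} +/- {cs:4.2f}"
            )
        return "\n".join(lines)


class ConnectionCountAnova:
    """2x2 within-hemisphere ANOVA on absolute streamline counts.

    ``counts`` has shape (H, 2, 2): hemisphere x connection type
    (retinotopic, non-retinotopic) x coil.
    """

    def __init__(self, counts: np.ndarray):
        self.counts = np.asarray(counts, dtype=float)

    def fit(self) -> "ConnectionCountAnovaResults":
        return ConnectionCountAnovaResults(
            model=self, anova=rm_anova_2x2(self.counts)
        )


@dataclass
class ConnectionCountAnovaResults:
    model: ConnectionCountAnova
    anova: AnovaResult

    def summary(self) -> str:
        a = self.anova
        rows = [
            ("type", a.F_type, a.p_type, a.dfs["type"]),
            ("coil", a.F_coil, a.p_coil, a.dfs["coil"]),
            ("type x coil", a.F_interaction, a.p_interaction,
             a.dfs["interaction"]),
        ]
        lines = [
            "Repeated-measures ANOVA on absolute streamline counts",
            "=" * 62,
            f"{'effect':>12}  {'df':>8}  {'F':>10}  {'p':>10}",
        ]
        for name, f, p, df in rows:
            lines.append(f"{name:>12}  {df[0]:>3},{df[1]:>4}  {f:>10.3f}  "
                         f"{p:>10.3g}")
        return "\n".join(lines)
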