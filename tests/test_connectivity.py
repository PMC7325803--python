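"""Endpoint assignment, retention rules, matrices, and U-shape filtering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import retinoconn as rc
from retinoconn.connectivity import turning_angle_deg
from retinoconn.datatypes import CSF_CODE, StreamlineSet, V1_CODES, V2_CODES


def brute_force_connectivity(tractogram, labels):
    """Naive per-streamline, per-point reference implementation."""
    inv = np.linalg.inv(labels.affine)
    shape = labels.grid.shape

    def code_of(pt):
        v = inv[:3, :3] @ pt + inv[:3, 3]
        ijk = tuple(int(np.floor(c + 0.5)) for c in v)
        for d in range(3):
            if ijk[d] < 0 or ijk[d] >= shape[d]:
                return 0
        return int(labels.grid[ijk])

    counts = np.zeros((6, 6), dtype=int)
    for sl in tractogram:
        a, b = code_of(sl[0]), code_of(sl[-1])
        pair = None
        if a in V1_CODES and b in V2_CODES:
            pair = (a - 1, b - 7)
        elif b in V1_CODES and a in V2_CODES:
            pair = (b - 1, a - 7)
        if pair is None:
            continue
        if any(code_of(p) == CSF_CODE for p in sl):
            continue
        counts[pair] += 1
    return counts


def _labels_with_box(csf=False):
    grid = np.zeros((10, 10, 10), dtype=np.int16)
    for k, code in enumerate(range(1, 7)):
        grid[k, 0, 0] = code          # V1 segments along x at y=0
        grid[k, 9, 0] = code + 6      # V2 segments along x at y=9
    if csf:
        grid[:, 4:6, 5] = CSF_CODE
    return rc.SegmentLabelVolume(grid=grid, affine=np.eye(4))


def _line(p, q, n=20):
    return np.linspace(p, q, n)


class TestPrimitives:
    def test_streamline_length_345(self):
        assert rc.streamline_length([(0, 0, 0), (3, 4, 0)]) == 5.0

    def test_degenerate_repeated_point(self):
        assert rc.streamline_length([(1, 1, 1), (1, 1, 1)]) == 0.0

    def test_arc_length_matches_pairwise_sum(self):
        rng = np.random.default_rng(0)
        arc = np.cumsum(rng.normal(size=(100, 3)), axis=0)
        oracle = sum(
            float(np.linalg.norm(arc[i + 1] - arc[i]))
            for i in range(len(arc) - 1)
        )
        assert np.isclose(rc.streamline_length(arc), oracle)

    def test_assign_endpoint_floor_convention(self):
        labels = _labels_with_box()
        labels.grid[2, 3, 2] = 5
        from retinoconn.connectivity import assign_endpoint

        assert assign_endpoint((2.2, 3.0, 1.9), labels) == 5
        assert assign_endpoint((50.0, 0.0, 0.0), labels) == 0

    def test_endpoint_round_trip_on_generated_streamlines(
        self, default_labels
    ):
        cfg = rc.GeneratorConfig(seed=12, n_streamlines=1000,
                                 csf_contaminant_fraction=0.0)
        sset = rc.simulate_streamlines(default_labels, cfg)
        from retinoconn.connectivity import assign_endpoint

        hits = 0
        for sl, (i, j) in zip(sset, sset.true_cell):
            a = assign_endpoint(sl[0], default_labels)
            b = assign_endpoint(sl[-1], default_labels)
            hits += {a, b} == {i, j + 6}
        assert hits == len(sset)

    def test_traverses_csf(self):
        labels = _labels_with_box(csf=True)
        through = _line((1.0, 0.0, 5.0), (8.0, 9.0, 5.0), n=50)
        clear = _line((1.0, 0.0, 0.0), (8.0, 9.0, 0.0), n=50)
        assert rc.connectivity.traverses_csf(through, labels)
        assert not rc.connectivity.traverses_csf(clear, labels)

    def test_contaminant_flag_rate(self, default_labels):
        cfg = rc.GeneratorConfig(seed=13, n_streamlines=400,
                                 csf_contaminant_fraction=0.1)
        sset = rc.simulate_streamlines(default_labels, cfg)
        flagged = np.array([
            rc.connectivity.traverses_csf(sl, default_labels) for sl in sset
        ])
        assert np.array_equal(flagged, sset.csf_tag)
        assert flagged.sum() == round(0.1 * 400)


class TestBuildConnectivity:
    def test_single_cell(self):
        labels = _labels_with_box()
        sls = [_line((0.0, 0.0, 0.0), (0.0, 9.0, 0.0)) for _ in range(5)]
        m = rc.build_connectivity(StreamlineSet(streamlines=sls), labels)
        assert m.counts[0, 0] == 5 and m.total == 5
        assert m.percent[0, 0] == 100.0

    def test_same_area_termination_discarded(self):
        labels = _labels_with_box()
        sl = _line((0.0, 0.0, 0.0), (1.0, 0.0, 0.0))  # V1 seg1 -> V1 seg2
        m = rc.build_connectivity(StreamlineSet(streamlines=[sl]), labels)
        assert m.total == 0 and m.n_discarded_termination == 1

    def test_explicit_table_round_trip(self, default_labels):
        rng = np.random.default_rng(5)
        table = rng.integers(0, 8, size=(6, 6))
        cfg = rc.GeneratorConfig(seed=5, n_streamlines_per_cell=table,
                                 csf_contaminant_fraction=0.0)
        sset = rc.simulate_streamlines(default_labels, cfg)
        m = rc.build_connectivity(sset, default_labels)
        assert np.array_equal(m.counts, table)

    def test_reversal_symmetry(self, default_tractogram, default_labels):
        fwd = rc.build_connectivity(default_tractogram, default_labels)
        rev = rc.build_connectivity(
            StreamlineSet(streamlines=[s[::-1] for s in default_tractogram]),
            default_labels,
        )
        assert np.array_equal(fwd.counts, rev.counts)

    def test_count_conservation_and_percent_sum(
        self, default_tractogram, default_labels
    ):
        m = rc.build_connectivity(default_tractogram, default_labels)
        assert (m.total + m.n_discarded_csf + m.n_discarded_termination
                == len(default_tractogram))
        assert abs(m.percent.sum() - 100.0) < 1e-9

    def test_matches_brute_force_reference(
        self, default_tractogram, default_labels
    ):
        m = rc.build_connectivity(default_tractogram, default_labels)
        oracle = brute_force_connectivity(default_tractogram, default_labels)
        assert np.array_equal(m.counts, oracle)

    def test_zero_retained_percent_flagged(self):
        labels = _labels_with_box()
        sl = _line((0.0, 0.0, 3.0), (0.0, 9.0, 3.0))  # endpoints unlabeled
        m = rc.build_connectivity(StreamlineSet(streamlines=[sl]), labels)
        assert m.total == 0
        with pytest.raises(ValueError):
            _ = m.percent


class TestPartition:
    def test_uniform_matrix(self):
        m = rc.ConnectivityMatrix(np.ones((6, 6), dtype=int))
        part = rc.partition_connectivity(m)
        assert np.isclose(part.retinotopic_pct, 100.0 * 6 / 36)

    def test_diagonal_only(self):
        m = rc.ConnectivityMatrix(np.diag([3, 1, 4, 1, 5, 9]))
        part = rc.partition_connectivity(m)
        assert part.retinotopic_pct == 100.0 and part.nonretinotopic_pct == 0.0

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            rc.partition_connectivity(
                rc.ConnectivityMatrix(np.zeros((6, 6), dtype=int))
            )

    def test_bias_recovery_closed_form(self, default_labels):
        cfg = rc.GeneratorConfig(seed=21, n_streamlines=2000,
                                 csf_contaminant_fraction=0.0)
        sset = rc.simulate_streamlines(default_labels, cfg)
        part = rc.partition_connectivity(
            rc.build_connectivity(sset, default_labels)
        )
        p = cfg.retino_bias + (1 - cfg.retino_bias) / 6
        tol = 3 * 100 * np.sqrt(p * (1 - p) / cfg.n_streamlines)
        assert abs(part.retinotopic_pct - 100 * p) < tol


class TestProximity:
    def test_mean_reciprocal_examples(self):
        labels = _labels_with_box()
        sls = [
            np.linspace((0, 0, 0), (0, 9, 0), 30),
        ]
        # hand-build two streamlines with controlled lengths in one cell is
        # awkward geometrically; check the arithmetic directly instead
        lengths = np.array([10.0, 20.0])
        assert np.isclose(np.mean(1.0 / lengths), 0.075)
        assert np.isclose(1.0 / 16.0, 0.0625)
        prox = rc.proximity_matrix(StreamlineSet(streamlines=sls), labels)
        assert prox.defined_mask[0, 0]
        assert np.isclose(prox.mean_recip_len[0, 0], 1.0 / 9.0)
        assert not prox.defined_mask[1, 1]

    def test_diagonal_proximity_exceeds_off_diagonal(
        self, default_tractogram, default_labels
    ):
        prox = rc.proximity_matrix(default_tractogram, default_labels)
        diag = np.eye(6, dtype=bool)
        d = np.nanmean(prox.mean_recip_len[diag & prox.defined_mask])
        o = np.nanmean(prox.mean_recip_len[~diag & prox.defined_mask])
        assert d > o  # shorter retinotopic fibers -> larger reciprocals


class TestGroupAverage:
    def test_identity_and_arithmetic(self):
        m = np.arange(36.0).reshape(6, 6)
        mean, n = rc.group_average([m])
        assert np.array_equal(mean, m)
        mean, _ = rc.group_average([np.full((6, 6), 10.0),
                                    np.full((6, 6), 20.0)])
        assert np.all(mean == 15.0)

    def test_order_invariance(self):
        rng = np.random.default_rng(3)
        mats = [rng.normal(size=(6, 6)) for _ in range(5)]
        a, _ = rc.group_average(mats)
        b, _ = rc.group_average(mats[::-1])
        assert np.allclose(a, b)

    def test_nan_cells_excluded_pairwise(self):
        m1 = np.full((6, 6), 2.0)
        m2 = np.full((6, 6), 4.0)
        m2[0, 0] = np.nan
        mean, n = rc.group_average([m1, m2])
        assert mean[0, 0] == 2.0 and n[0, 0] == 1
        assert mean[1, 1] == 3.0 and n[1, 1] == 2

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rc.group_average([])


class TestUShapeFilter:
    def test_straight_line_rejected(self):
        sl = _line((0.0, 0.0, 0.0), (10.0, 0.0, 0.0), n=50)
        out = rc.filter_u_shaped(StreamlineSet(streamlines=[sl]))
        assert len(out) == 0

    def test_semicircle_retained(self):
        t = np.linspace(0, np.pi, 100)
        arc = np.column_stack([5 * np.cos(t), 5 * np.sin(t), np.zeros_like(t)])
        out = rc.filter_u_shaped(StreamlineSet(streamlines=[arc]))
        assert len(out) == 1  # turning 180 deg >= 90, length ~15.7 <= 25

    def test_long_streamline_rejected(self):
        t = np.linspace(0, np.pi, 200)
        arc = np.column_stack([20 * np.cos(t), 20 * np.sin(t),
                               np.zeros_like(t)])
        out = rc.filter_u_shaped(StreamlineSet(streamlines=[arc]))
        assert len(out) == 0  # turning passes but length ~63 mm > 25

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 10_000))
    def test_turning_angle_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        pts = np.cumsum(rng.normal(size=(12, 3)), axis=0)
        total = 0.0
        for i in range(1, len(pts) - 1):
            u = pts[i] - pts[i - 1]
            v = pts[i + 1] - pts[i]
            cosang = u @ v / (np.linalg.norm(u) * np.linalg.norm(v))
            total += np.degrees(np.arccos(np.clip(cosang, -1, 1)))
        assert np.isclose(turning_angle_deg(pts), total, atol=1e-9)
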