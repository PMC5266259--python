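"""Gating, arcsinh transform and replicate pooling."""

import numpy as np
import pytest
import yaml

from flowident import (
    EventMatrix,
    PolygonGate,
    apply_gate,
    cell_count,
    default_gate,
    load_gates,
    pool_replicates,
    transform_arcsinh,
)


def _events(xy: np.ndarray, channels=("FL1-H", "FL3-H")) -> EventMatrix:
    return EventMatrix(list(channels), np.asarray(xy, dtype=float))


def _identity_rect(lo, hi) -> PolygonGate:
    return PolygonGate(
        "FL1-H", "FL3-H",
        np.array([[lo, lo], [hi, lo], [hi, hi], [lo, hi]]),
        transform="identity",
    )


class TestArcsinh:
    def test_zero_maps_to_zero(self):
        ev = transform_arcsinh(_events([[0.0, 1.0]]), ["FL1-H"])
        assert ev.values[0, 0] == 0.0

    def test_closed_form_value(self):
        # arcsinh(10000) = ln(10000 + sqrt(10000^2 + 1))
        ev = transform_arcsinh(_events([[10_000.0, 1.0]]), ["FL1-H"])
        assert ev.values[0, 0] == pytest.approx(np.log(10_000 + np.sqrt(1e8 + 1)))
        assert ev.values[0, 0] == pytest.approx(9.9035, abs=1e-4)

    def test_other_channels_untouched(self):
        ev = transform_arcsinh(_events([[5.0, 7.0]]), ["FL1-H"])
        assert ev.values[0, 1] == 7.0

    def test_double_transform_refused(self):
        once = transform_arcsinh(_events([[1.0, 2.0]]), ["FL1-H"])
        with pytest.raises(ValueError, match="already"):
            transform_arcsinh(once, ["FL1-H"])

    def test_missing_channel(self):
        with pytest.raises(KeyError, match="FL9-H"):
            transform_arcsinh(_events([[1.0, 2.0]]), ["FL9-H"])


class TestPolygonGate:
    def test_needs_three_vertices(self):
        with pytest.raises(ValueError, match="3 vertices"):
            PolygonGate("A", "B", [[0, 0], [1, 1]])

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError, match="zero area|simple"):
            PolygonGate("A", "B", [[0, 0], [1, 1], [2, 2]])

    def test_self_intersecting_rejected(self):
        with pytest.raises(ValueError, match="simple"):
            PolygonGate("A", "B", [[0, 0], [1, 1], [1, 0], [0, 1]])

    def test_same_channel_rejected(self):
        with pytest.raises(ValueError, match="differ"):
            PolygonGate("A", "A", [[0, 0], [1, 0], [0, 1]])


class TestApplyGate:
    def test_all_inside(self):
        rng = np.random.default_rng(0)
        ev = _events(rng.uniform(1, 9, (500, 2)))
        inside, outside = apply_gate(ev, _identity_rect(0, 10))
        assert inside.n_events == 500 and outside.n_events == 0

    def test_all_outside(self):
        rng = np.random.default_rng(0)
        ev = _events(rng.uniform(1, 9, (500, 2)))
        inside, _ = apply_gate(ev, _identity_rect(100, 200))
        assert inside.n_events == 0

    def test_partition_is_exact_and_ordered(self):
        rng = np.random.default_rng(1)
        ev = _events(rng.uniform(0, 10, (1000, 2)))
        gate = _identity_rect(2, 7)
        inside, outside = apply_gate(ev, gate)
        assert inside.n_events + outside.n_events == 1000
        # multiset equality: sorting the union of parts recovers the input
        union = np.vstack([inside.values, outside.values])
        assert np.array_equal(
            union[np.lexsort(union.T)], ev.values[np.lexsort(ev.values.T)]
        )
        # order preserved within each part
        mask = (
            (ev.values[:, 0] >= 2) & (ev.values[:, 0] <= 7)
            & (ev.values[:, 1] >= 2) & (ev.values[:, 1] <= 7)
        )
        assert np.array_equal(inside.values, ev.values[mask])

    def test_boundary_counts_as_inside(self):
        ev = _events([[2.0, 5.0], [2.0, 2.0], [7.0, 7.0], [5.0, 7.0]])
        inside, outside = apply_gate(ev, _identity_rect(2, 7))
        assert inside.n_events == 4 and outside.n_events == 0

    def test_arcsinh_gate_returns_raw_values(self):
        # default gate thresholds at arcsinh(x) = 1, i.e. raw x = sinh(1)
        ev = _events([[1000.0, 1000.0], [0.1, 0.1]])
        inside, outside = apply_gate(ev, default_gate())
        assert inside.n_events == 1 and outside.n_events == 1
        assert inside.values[0, 0] == 1000.0  # untransformed

    def test_deterministic(self):
        rng = np.random.default_rng(2)
        ev = _events(rng.uniform(0, 10, (300, 2)))
        gate = _identity_rect(1, 8)
        a, _ = apply_gate(ev, gate)
        b, _ = apply_gate(ev, gate)
        assert np.array_equal(a.values, b.values)


def _ray_cast(point, vertices) -> bool:
    """Brute-force crossing-number point-in-polygon (strict interior)."""
    x, y = point
    inside = False
    n = len(vertices)
    for i in range(n):
        x1, y1 = vertices[i]
        x2, y2 = vertices[(i + 1) % n]
        if (y1 > y) != (y2 > y):
            x_cross = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < x_cross:
                inside = not inside
    return inside


def _random_simple_polygon(rng, n_vertices):
    """Star-shaped polygon: vertices at sorted angles around a center."""
    angles = np.sort(rng.uniform(0, 2 * np.pi, n_vertices))
    radii = rng.uniform(1, 5, n_vertices)
    center = rng.uniform(3, 7, 2)
    return center + np.column_stack([radii * np.cos(angles), radii * np.sin(angles)])


def test_gate_membership_matches_ray_casting_oracle():
    """>= 10,000 random (point, polygon) cases agree with the oracle.

    Random continuous points hit polygon edges with probability zero, so the
    strict-interior oracle and the boundary-inclusive gate coincide a.s.
    """
    rng = np.random.default_rng(42)
    total = 0
    for _ in range(10):
        verts = _random_simple_polygon(rng, int(rng.integers(3, 9)))
        gate = PolygonGate("FL1-H", "FL3-H", verts, transform="identity")
        pts = rng.uniform(-2, 12, (1100, 2))
        inside, _ = apply_gate(_events(pts), gate)
        got = np.zeros(len(pts), dtype=bool)
        inside_set = {tuple(row) for row in inside.values}
        got = np.array([tuple(p) in inside_set for p in pts])
        expected = np.array([_ray_cast(p, verts) for p in pts])
        assert np.array_equal(got, expected)
        total += len(pts)
    assert total >= 10_000


class TestPooling:
    def _uniform_inside(self, n, seed):
        rng = np.random.default_rng(seed)
        # raw values whose arcsinh lies in [2, 8]: inside the default gate
        return _events(np.sinh(rng.uniform(2, 8, (n, 2))))

    def test_additivity(self):
        reps = [self._uniform_inside(6000, 0), self._uniform_inside(6000, 1)]
        sample = pool_replicates(reps, default_gate(), taxon_id="t")
        assert cell_count(sample) == 12_000
        assert sample.meta["replicate_gated_counts"] == (6000, 6000)

    def test_single_replicate_identity(self):
        rep = self._uniform_inside(500, 2)
        sample = pool_replicates([rep], default_gate())
        assert np.array_equal(sample.pooled.values, rep.values)

    def test_low_count_replicate(self):
        reps = [self._uniform_inside(7000, 3), self._uniform_inside(3084, 4)]
        assert cell_count(pool_replicates(reps, default_gate())) == 10_084

    def test_panel_mismatch_lists_channels(self):
        a = self._uniform_inside(10, 5)
        b = EventMatrix(["FL1-H", "FL4-H"], np.ones((5, 2)))
        with pytest.raises(ValueError, match="FL3-H"):
            pool_replicates([a, b], default_gate())

    def test_empty_pool_counts_zero(self):
        rep = _events(np.full((50, 2), 0.01))  # all below the gate
        assert cell_count(pool_replicates([rep], default_gate())) == 0

    def test_count_permutation_invariant(self):
        rep = self._uniform_inside(400, 6)
        sample = pool_replicates([rep], default_gate())
        shuffled = rep.take(np.random.default_rng(7).permutation(400))
        assert cell_count(pool_replicates([shuffled], default_gate())) == cell_count(sample)


def test_load_gates_yaml(tmp_path):
    cfg = {
        "default": {
            "channel_x": "FL1-H",
            "channel_y": "FL3-H",
            "transform": "arcsinh",
            "vertices": [[1, 1], [9, 1], [9, 9], [1, 9]],
        }
    }
    path = tmp_path / "gates.yaml"
    path.write_text(yaml.safe_dump(cfg))
    gates = load_gates(path)
    assert gates["default"].channel_x == "FL1-H"
    assert gates["default"].vertices.shape == (4, 2)
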