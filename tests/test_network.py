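"""Geometry, topology and mechanics of the vertex-model cell network."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from shapely.geometry import Polygon

from rootmorph.errors import DegenerateGeometry, DivisionRetry
from rootmorph.network import (CellNetwork, MechParams, elastic_wall_force,
                               initial_network, pressure_magnitude)

from conftest import square_pair


# ----------------------------------------------------------- geometry oracles

def test_cell_area_matches_shapely(net20):
    for cid in net20.cell_ids():
        poly = Polygon(net20.cell_polygon(cid))
        assert net20.cell_area(cid) == pytest.approx(poly.area, rel=1e-12)


def test_cell_centroid_matches_shapely(net20):
    for cid in net20.cell_ids():
        poly = Polygon(net20.cell_polygon(cid))
        c = net20.cell_centroid(cid)
        assert c[0] == pytest.approx(poly.centroid.x, abs=1e-12)
        assert c[1] == pytest.approx(poly.centroid.y, abs=1e-12)


def test_degenerate_polygon_rejected():
    net = CellNetwork()
    a = net.add_vertex(0, 0)
    b = net.add_vertex(1, 0)
    c = net.add_vertex(2, 0)  # collinear: zero area
    net.add_cell([a, b, c])
    with pytest.raises(DegenerateGeometry):
        net.cell_area(0)


def test_wall_bookkeeping_square_pair():
    net = square_pair()
    walls = net.walls
    assert len(walls) == 7
    shared = [w for w in walls.values() if len(w.cells) == 2]
    assert len(shared) == 1 and set(shared[0].cells) == {0, 1}
    assert sum(w.is_boundary for w in walls.values()) == 6
    assert net.neighbors(0) == {1}
    assert net.adjacency_edges() == [(0, 1)]


def test_marginality_square_pair_and_tissue(net20):
    net = square_pair()
    assert net.is_marginal(0) and net.is_marginal(1)
    # a 20-cell disk has at least one interior (non-marginal) cell
    marginal = [net20.is_marginal(c) for c in net20.cell_ids()]
    assert any(marginal) and not all(marginal)


def test_largest_cell_tie_prefers_smallest_id():
    net = square_pair()  # both cells have area exactly 1
    assert net.largest_cell() == 0


# ------------------------------------------------------------------- division

def test_division_preserves_total_area(net20):
    total = sum(net20.cell_area(c) for c in net20.cell_ids())
    mother = net20.largest_cell()
    ida, idb = net20.divide_cell(mother, angle=0.3)
    after = sum(net20.cell_area(c) for c in net20.cell_ids())
    assert after == pytest.approx(total, abs=1e-10)
    assert mother not in net20.cell_ids()
    assert {ida, idb} <= set(net20.cell_ids())


def test_division_daughters_share_new_wall(net20):
    ida, idb = net20.divide_cell(net20.largest_cell(), angle=1.1)
    assert idb in net20.neighbors(ida)
    net20.validate()


def test_division_passes_through_centroid(net20):
    mother = net20.largest_cell()
    cen = net20.cell_centroid(mother)
    before = set(net20.vertices)
    ida, idb = net20.divide_cell(mother, angle=0.7)
    new_vs = [v for v in net20.vertices if v not in before]
    assert len(new_vs) == 2
    p, q = (net20.vertices[v] for v in new_vs)
    # centroid lies on the segment p-q
    cross = (q[0] - p[0]) * (cen[1] - p[1]) - (q[1] - p[1]) * (cen[0] - p[0])
    assert abs(cross) < 1e-9 * np.hypot(*(q - p))


def test_division_vertex_graze_raises_retry():
    net = square_pair()
    # the diagonal through the unit square's centroid at 45 degrees passes
    # exactly through two of its corners
    with pytest.raises(DivisionRetry):
        net.divide_cell(0, angle=math.pi / 4)


def test_division_updates_neighbor_cycles():
    net = square_pair()
    ida, idb = net.divide_cell(0, angle=math.pi / 2)
    net.validate()
    # cell 1's cycle gained the new vertex on the shared wall only if the cut
    # hit that wall; either way the network stays consistent and the
    # daughters tile the old square
    assert net.cell_area(ida) + net.cell_area(idb) == pytest.approx(1.0)


@given(st.integers(0, 10**6))
def test_division_at_random_angles_keeps_area_and_validity(angle_seed):
    rng = np.random.default_rng(angle_seed)
    net = initial_network(6, seed=3)
    total = sum(net.cell_area(c) for c in net.cell_ids())
    for _ in range(3):
        mother = net.largest_cell()
        for _ in range(100):
            try:
                net.divide_cell(mother, rng.uniform(0, math.pi))
                break
            except DivisionRetry:
                continue
    net.validate()
    assert sum(net.cell_area(c) for c in net.cell_ids()) == pytest.approx(
        total, abs=1e-9)
    assert net.n_cells == 9


# ------------------------------------------------------------------ mechanics

def test_elastic_force_zero_at_rest_length(mech):
    a = np.zeros(2)
    b = np.array([mech.l_0, 0.0])
    assert np.allclose(elastic_wall_force(a, b, mech), 0.0)


def test_elastic_force_direction_and_magnitude(mech):
    a = np.zeros(2)
    b = np.array([2 * mech.l_0, 0.0])   # stretched: pulls a toward b
    f = elastic_wall_force(a, b, mech)
    assert f[0] == pytest.approx(mech.k_S * mech.l_0) and f[1] == 0.0
    b = np.array([0.5 * mech.l_0, 0.0])  # compressed: pushes a away
    f = elastic_wall_force(a, b, mech)
    assert f[0] == pytest.approx(-mech.k_S * 0.5 * mech.l_0)


def test_pressure_magnitude_inverse_area(mech):
    assert pressure_magnitude(2.0, mech) == pytest.approx(mech.k_P / 2.0)
    assert pressure_magnitude(0.5, mech) == pytest.approx(2.0 * mech.k_P)


def test_vertex_force_matches_finite_difference(hexagon, mech):
    """-dE/dx for the elastic part + analytic pressure: cross-check the
    elastic contribution of vertex_force against a numerical gradient of
    the spring energy."""
    vid = next(iter(hexagon.vertices))
    f = hexagon.vertex_force(vid, mech)

    def elastic_energy():
        return sum(0.5 * mech.k_S * (hexagon.wall_length(w) - mech.l_0) ** 2
                   for w in hexagon.walls)

    h = 1e-7
    grad = np.zeros(2)
    for k in range(2):
        orig = hexagon.vertices[vid][k]
        hexagon.vertices[vid][k] = orig + h
        hexagon._invalidate()
        ep = elastic_energy()
        hexagon.vertices[vid][k] = orig - h
        hexagon._invalidate()
        em = elastic_energy()
        hexagon.vertices[vid][k] = orig
        hexagon._invalidate()
        grad[k] = (ep - em) / (2 * h)
    # elastic part of f equals -grad; the remainder is the pressure of the
    # two adjacent walls, each of magnitude k_P/V
    pressure_part = f + grad
    area = hexagon.cell_area(0)
    assert np.linalg.norm(pressure_part) <= (
        2 * pressure_magnitude(area, mech) + 1e-5)
    assert np.linalg.norm(pressure_part) > 0.1 * pressure_magnitude(area, mech)


def test_relaxation_stopping_rule(net20, mech):
    """After a converged relaxation every vertex moves less than relax_tol
    per step under the drift-corrected force (the rigid translation and
    rotation components change no length or area and are projected out)."""
    net20.relax(mech)
    assert net20.last_relax.converged
    drift = net20.rigid_drift_forces(mech)
    for v in net20.vertices:
        f = net20.vertex_force(v, mech) - drift[v]
        step = np.linalg.norm(mech.k_T * f) * mech.relax_dt
        assert step < mech.relax_tol * 1.5


def test_relaxation_keeps_areas_positive_and_reduces_spread(mech):
    net = initial_network(12, seed=5, mech=mech)
    areas = [net.cell_area(c) for c in net.cell_ids()]
    assert min(areas) > 0
    # turgor ~ 1/V equalizes cell sizes: relaxed spread is modest
    assert max(areas) / min(areas) < 10


def test_relax_is_idempotent_at_equilibrium(net20, mech):
    net20.relax(mech)
    pos = {v: p.copy() for v, p in net20.vertices.items()}
    net20.relax(mech)
    for v, p in net20.vertices.items():
        assert np.allclose(p, pos[v], atol=5 * mech.relax_tol)


def test_mech_params_validation():
    with pytest.raises(ValueError):
        MechParams(k_S=-1.0)
    with pytest.raises(ValueError):
        MechParams(relax_dt=0.0)


# -------------------------------------------------------------- serialization

def test_json_round_trip(net20):
    text = net20.to_json()
    back = CellNetwork.from_json(text)
    assert back.cell_ids() == net20.cell_ids()
    assert set(back.vertices) == set(net20.vertices)
    for v in net20.vertices:
        assert np.allclose(back.vertices[v], net20.vertices[v])
    assert back.cells == net20.cells
    assert back.to_json() == text


def test_initial_network_deterministic(mech):
    a = initial_network(15, seed=42, mech=mech)
    b = initial_network(15, seed=42, mech=mech)
    assert a.to_json() == b.to_json()
    c = initial_network(15, seed=43, mech=mech)
    assert a.to_json() != c.to_json()


def test_initial_network_structure(net20):
    assert net20.n_cells == 20
    net20.validate()
    # Euler characteristic for a disk-like planar subdivision:
    # V - E + F = 2 with the outer face included
    V, E, F = net20.n_vertices, len(net20.walls), net20.n_cells + 1
    assert V - E + F == 2
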