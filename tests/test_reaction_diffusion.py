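"""Activator-inhibitor kinetics, diffusion, and linear stability."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from rootmorph.errors import NoPositiveEquilibrium
from rootmorph.network import CellNetwork, initial_network
from rootmorph.reaction_diffusion import (RDParams, RDState, equilibrium_state,
                                          mode_growth_rate, perturb_equilibrium,
                                          phi, psi, rd_run, rd_step,
                                          turing_unstable)


def interior_state(network, params, value_u=None, value_v=None):
    eq = equilibrium_state(params)
    ids = np.array(network.cell_ids(), np.int64)
    u = np.full(len(ids), eq.u_0 if value_u is None else value_u)
    v = np.full(len(ids), eq.v_0 if value_v is None else value_v)
    return RDState(ids, u, v)


def reference_rd_step(state, network, params):
    """Pure-numpy oracle for one Euler step (mirrors the model equations
    directly, independent of the compiled kernel)."""
    ids = list(state.cell_ids)
    index = {c: i for i, c in enumerate(ids)}
    u, v = state.u.copy(), state.v.copy()
    lap_u = np.zeros_like(u)
    lap_v = np.zeros_like(v)
    for a, b in network.adjacency_edges():
        i, j = index[a], index[b]
        lap_u[i] += u[j] - u[i]
        lap_u[j] += u[i] - u[j]
        lap_v[i] += v[j] - v[i]
        lap_v[j] += v[i] - v[j]
    du = np.empty_like(u)
    dv = np.empty_like(v)
    for k, cid in enumerate(ids):
        du[k] = (phi(params.eps + params.alpha_s * u[k] - params.beta * v[k],
                     params)
                 - (params.alpha_d + psi(cid, network, params)) * u[k]
                 + params.D_u * lap_u[k])
        dv[k] = (params.gamma * u[k] - params.delta * v[k]
                 + params.D_v * lap_v[k])
    u2 = np.clip(u + params.dt * du, 0.0, params.u_max)
    v2 = np.clip(v + params.dt * dv, 0.0, None)
    return RDState(state.cell_ids.copy(), u2, v2)


# ---------------------------------------------------------------- equilibrium

def test_equilibrium_formula_and_value():
    p = RDParams(alpha_s=1.8)
    eq = equilibrium_state(p)
    den = p.beta * p.gamma - (p.alpha_s - p.alpha_d) * p.delta
    assert eq.u_0 == pytest.approx(p.delta * p.eps / den)
    assert eq.v_0 == pytest.approx(p.gamma * p.eps / den)
    assert eq.u_0 == pytest.approx(5.0)


def test_no_positive_equilibrium_raises():
    with pytest.raises(NoPositiveEquilibrium):
        equilibrium_state(RDParams(alpha_s=2.0))  # denominator exactly 0
    with pytest.raises(NoPositiveEquilibrium):
        equilibrium_state(RDParams(alpha_s=2.5))


@given(st.floats(1.05, 1.95))
def test_equilibrium_is_fixed_point_of_unclamped_kinetics(alpha_s):
    p = RDParams(alpha_s=alpha_s)
    eq = equilibrium_state(p)
    du = (p.eps + p.alpha_s * eq.u_0 - p.beta * eq.v_0) - p.alpha_d * eq.u_0
    dv = p.gamma * eq.u_0 - p.delta * eq.v_0
    assert du == pytest.approx(0.0, abs=1e-12)
    assert dv == pytest.approx(0.0, abs=1e-12)


def test_phi_clamps():
    p = RDParams()
    assert phi(-1.0, p) == 0.0
    assert phi(3.0, p) == 3.0
    assert phi(1e9, p) == p.alpha_d * p.u_max


def test_psi_marginal_only(net20):
    p = RDParams(alpha_m=1.0)
    vals = {c: psi(c, net20, p) for c in net20.cell_ids()}
    for c, val in vals.items():
        assert val == (1.0 if net20.is_marginal(c) else 0.0)


# ----------------------------------------------------------------- integrator

def test_homogeneous_equilibrium_invariant_without_marginal_decay(net20):
    p = RDParams(alpha_s=1.8, alpha_m=0.0)
    s0 = interior_state(net20, p)
    s1 = rd_step(s0, net20, p)
    assert np.array_equal(s1.u, s0.u)
    assert np.array_equal(s1.v, s0.v)


def test_single_cell_euler_step_by_hand(hexagon):
    p = RDParams(alpha_s=1.8, alpha_m=1.0)
    s0 = RDState(np.array([0]), np.array([2.0]), np.array([1.5]))
    s1 = rd_step(s0, hexagon, p)
    # one marginal cell, no neighbours: du = phi(eps + a_s u - b v)
    # - (a_d + a_m) u, dv = g u - d v
    du = phi(1.0 + 1.8 * 2.0 - 1.5, p) - (1.0 + 1.0) * 2.0
    dv = 1.0 * 2.0 - 1.0 * 1.5
    assert s1.u[0] == pytest.approx(2.0 + p.dt * du, abs=1e-14)
    assert s1.v[0] == pytest.approx(1.5 + p.dt * dv, abs=1e-14)


def test_kernel_matches_numpy_reference(net20, rng):
    p = RDParams(alpha_s=1.6, alpha_m=1.0)
    ids = np.array(net20.cell_ids(), np.int64)
    s = RDState(ids, rng.uniform(0, 8, len(ids)), rng.uniform(0, 3, len(ids)))
    got = rd_step(s, net20, p)
    want = reference_rd_step(s, net20, p)
    np.testing.assert_allclose(got.u, want.u, rtol=0, atol=1e-13)
    np.testing.assert_allclose(got.v, want.v, rtol=0, atol=1e-13)
    # and across many steps the trajectories stay identical
    got_n, want_n = s, s
    for _ in range(50):
        want_n = reference_rd_step(want_n, net20, p)
    from rootmorph.reaction_diffusion import _integrate
    got_n = _integrate(s, net20, p, 50)
    np.testing.assert_allclose(got_n.u, want_n.u, rtol=0, atol=1e-10)


def test_pure_diffusion_conserves_mass(net20, rng):
    # alpha_s = alpha_d with eps = beta = 0 makes phi(x) = alpha_d*u on
    # 0 <= u <= u_max, so the reaction terms cancel exactly and only
    # diffusion remains; likewise gamma = delta = 0 for v
    p = RDParams(alpha_s=1.0, alpha_d=1.0, alpha_m=0.0, beta=0.0, gamma=0.0,
                 delta=0.0, eps=0.0)
    ids = np.array(net20.cell_ids(), np.int64)
    s = RDState(ids, rng.uniform(1, 9, len(ids)), rng.uniform(1, 3, len(ids)))
    total_u, total_v = s.u.sum(), s.v.sum()
    out = rd_run(s, net20, p)
    assert out.u.sum() == pytest.approx(total_u, abs=1e-9)
    assert out.v.sum() == pytest.approx(total_v, abs=1e-9)
    # diffusion contracts toward the mean
    assert out.u.std() < s.u.std()


def test_rd_run_step_count_and_immutability(net20):
    p = RDParams()
    s = perturb_equilibrium(net20, p, 0.01, 3)
    u_before = s.u.copy()
    one = rd_step(s, net20, p)
    assert np.array_equal(s.u, u_before), "input state must not be mutated"
    assert p.n_steps == 2500
    two = rd_run(s, net20, p)
    assert not np.array_equal(one.u, two.u)


def test_rd_misaligned_state_rejected(net20):
    p = RDParams()
    bad = RDState(np.array([999]), np.array([1.0]), np.array([1.0]))
    with pytest.raises(ValueError):
        rd_step(bad, net20, p)


# --------------------------------------------------------------------- states

def test_perturb_equilibrium_bounds_and_determinism(net20):
    p = RDParams()
    eq = equilibrium_state(p)
    s = perturb_equilibrium(net20, p, 0.01, 99)
    assert np.all(np.abs(s.u / eq.u_0 - 1) <= 0.01 + 1e-12)
    assert np.all(np.abs(s.v / eq.v_0 - 1) <= 0.01 + 1e-12)
    s2 = perturb_equilibrium(net20, p, 0.01, 99)
    assert np.array_equal(s.u, s2.u)


def test_replace_cell_inherits_and_sorts():
    s = RDState(np.array([2, 5, 9]), np.array([1.0, 2.0, 3.0]),
                np.array([0.1, 0.2, 0.3]))
    out = s.replace_cell(5, (11, 10))
    assert list(out.cell_ids) == [2, 9, 10, 11]
    m = out.value_map()
    assert m[10] == (2.0, 0.2) and m[11] == (2.0, 0.2)
    with pytest.raises(KeyError):
        s.replace_cell(4, (20, 21))


# ----------------------------------------------------- linear stability oracle

def ring_network(n):
    """A ring of n quadrilateral cells around an annulus (each cell has
    exactly two neighbours), so the adjacency graph is the cycle C_n with
    known Laplacian eigenvalues 2 - 2 cos(2 pi k / n)."""
    net = CellNetwork()
    inner, outer = [], []
    for k in range(n):
        a = 2 * np.pi * k / n
        inner.append(net.add_vertex(np.cos(a), np.sin(a)))
        outer.append(net.add_vertex(2 * np.cos(a), 2 * np.sin(a)))
    for k in range(n):
        j = (k + 1) % n
        net.add_cell([inner[k], inner[j], outer[j], outer[k]])
    return net


def full_system_growth_rate(params, n):
    """Eigenvalue oracle: largest real part of the (2n x 2n) linearization
    of the full RD system on the cycle graph C_n."""
    L = 2 * np.eye(n)
    for k in range(n):
        L[k, (k + 1) % n] -= 1
        L[k, (k - 1) % n] -= 1
    fu = params.alpha_s - params.alpha_d
    A = np.block([[fu * np.eye(n) - params.D_u * L, -params.beta * np.eye(n)],
                  [params.gamma * np.eye(n),
                   -params.delta * np.eye(n) - params.D_v * L]])
    return float(np.linalg.eigvals(A).real.max())


@pytest.mark.parametrize("n", [4, 7, 12])
def test_mode_growth_rate_matches_eigen_oracle(n):
    for d_u, d_v in [(0.1, 2.0), (0.25, 0.5), (0.05, 4.0)]:
        p = RDParams(alpha_s=1.8, D_u=d_u, D_v=d_v)
        lams = [2 - 2 * np.cos(2 * np.pi * k / n) for k in range(n)]
        per_mode = max(mode_growth_rate(p, l) for l in lams)
        assert per_mode == pytest.approx(full_system_growth_rate(p, n),
                                         abs=1e-10)


def test_turing_window_default_unstable_printed_pair_stable():
    n = 40
    lams = [2 - 2 * np.cos(2 * np.pi * k / n) for k in range(n)]
    # the calibrated default diffusion pair destabilises short modes
    assert turing_unstable(RDParams(), lams)
    # a ratio D_v/D_u = 2 keeps every mode stable at these kinetics
    assert not turing_unstable(RDParams(D_u=0.25, D_v=0.5), lams)
    # without any diffusion contrast there is never an instability
    assert not turing_unstable(RDParams(D_u=1.0, D_v=1.0), lams)


def test_instability_grows_on_ring_network():
    """The sign predicted by the dispersion relation shows up in the actual
    nonlinear integrator: perturbations grow for the unstable pair and decay
    for the stable one (marginal decay off to keep the ring homogeneous)."""
    net = ring_network(16)
    for d_u, d_v, grows in [(0.1, 2.0, True), (0.25, 0.5, False)]:
        p = RDParams(alpha_s=1.8, alpha_m=0.0, D_u=d_u, D_v=d_v)
        p = p.with_u_max_factor(10.0)
        s = perturb_equilibrium(net, p, 0.01, 5)
        eq = equilibrium_state(p)
        dev0 = np.abs(s.u - eq.u_0).max()
        out = rd_run(s, net, p)
        dev1 = np.abs(out.u - eq.u_0).max()
        if grows:
            assert dev1 > 10 * dev0
        else:
            assert dev1 < dev0
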