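"""Activator-inhibitor dynamics on a cell network.

Each cell i carries an activator concentration u_i and an inhibitor
concentration v_i.  The activator induces itself (strength ``alpha_s``) and
its inhibitor (``gamma``); the inhibitor represses activator synthesis
(``beta``); both decay (``alpha_d``, ``delta``); a basal synthesis ``eps``
keeps the system away from the origin; both species diffuse to wall-sharing
neighbour cells (coefficients ``D_u`` < ``D_v``).  Activator synthesis is a
piecewise-linear function clamped between 0 and ``alpha_d * u_max``, which
bounds u in [0, u_max]; marginal (boundary) cells receive an extra activator
decay ``alpha_m``, which suppresses (or, if negative, favours) spots at the
tissue edge.

The homogeneous equilibrium of the unclamped interior kinetics is
``u0 = delta*eps / (beta*gamma - (alpha_s - alpha_d)*delta)`` and
``v0 = gamma*eps / (beta*gamma - (alpha_s - alpha_d)*delta)``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from ._kernels import rd_kernel
from .errors import NoPositiveEquilibrium
from .network import CellNetwork

__all__ = [
    "RDParams", "RDState", "EquilibriumState",
    "equilibrium_state", "phi", "psi",
    "mode_growth_rate", "turing_unstable",
    "rd_step", "rd_run", "perturb_equilibrium",
]


@dataclass(frozen=True)
class RDParams:
    """Kinetic and numerical constants of the activator-inhibitor system.

    Defaults fix the decay/repression/basal rates at 1.0; ``alpha_s``
    (activator self-induction), ``gamma`` (inhibitor induction),
    ``alpha_m`` (marginal extra decay) and the saturation ``u_max`` are the
    knobs that move the system between patterning regimes.

    The default diffusion pair (D_u = 0.1, D_v = 2.0) is a calibration, not
    a free styling choice: lateral inhibition on the cell-adjacency graph
    destabilises the homogeneous state only when
    ``D_v*(alpha_s - alpha_d) + D_u*(-delta) > 2*sqrt(D_u*D_v*det(J))``,
    which at the kinetic defaults requires roughly D_v/D_u > 5 — and the
    explicit Euler step (dt = 0.02) additionally caps D_v below about 8 on
    networks with vertex degrees up to ~6.  The chosen pair sits inside
    that window and places the fastest-growing wavelength at a few cell
    diameters, so tissues of a few hundred to a thousand cells carry one to
    a handful of activator regions.  See docs/methods.md for the full
    derivation.  ``u_max`` may be given directly or
    derived from the equilibrium via :meth:`with_u_max_factor`.  Integration
    is forward Euler with step ``dt`` for total time ``Td`` per run.
    """

    alpha_s: float = 1.8
    alpha_d: float = 1.0
    alpha_m: float = 1.0
    beta: float = 1.0
    gamma: float = 1.0
    delta: float = 1.0
    eps: float = 1.0
    D_u: float = 0.1
    D_v: float = 2.0
    u_max: float = 50.0
    dt: float = 0.02
    Td: float = 50.0

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.Td < self.dt:
            raise ValueError("need dt > 0 and Td >= dt")
        if self.D_u < 0 or self.D_v < 0:
            raise ValueError("diffusion coefficients must be non-negative")

    @property
    def n_steps(self) -> int:
        return round(self.Td / self.dt)

    def with_u_max_factor(self, factor: float) -> "RDParams":
        """Return a copy whose saturation is ``factor * u0`` (factor > 1)."""
        if factor <= 1:
            raise ValueError("u_max must exceed u0")
        eq = equilibrium_state(self)
        return replace(self, u_max=factor * eq.u_0)


@dataclass(frozen=True)
class EquilibriumState:
    u_0: float
    v_0: float


@dataclass
class RDState:
    """Per-cell activator/inhibitor concentrations, aligned to sorted cell
    ids of a :class:`CellNetwork`."""

    cell_ids: np.ndarray        # sorted int ids
    u: np.ndarray
    v: np.ndarray

    def __post_init__(self) -> None:
        self.cell_ids = np.asarray(self.cell_ids, np.int64)
        self.u = np.asarray(self.u, float)
        self.v = np.asarray(self.v, float)
        if not (len(self.cell_ids) == len(self.u) == len(self.v)):
            raise ValueError("cell_ids, u, v must have equal length")

    def copy(self) -> "RDState":
        return RDState(self.cell_ids.copy(), self.u.copy(), self.v.copy())

    def value_map(self) -> dict[int, tuple[float, float]]:
        return {int(c): (float(a), float(b))
                for c, a, b in zip(self.cell_ids, self.u, self.v)}

    def replace_cell(self, old_id: int, new_ids: tuple[int, int]) -> "RDState":
        """Daughters inherit the mother's concentrations unchanged."""
        idx = np.flatnonzero(self.cell_ids == old_id)
        if idx.size != 1:
            raise KeyError(f"cell {old_id} not in state")
        i = idx[0]
        ids = np.concatenate([np.delete(self.cell_ids, i),
                              np.array(new_ids, np.int64)])
        u = np.concatenate([np.delete(self.u, i), [self.u[i]] * 2])
        v = np.concatenate([np.delete(self.v, i), [self.v[i]] * 2])
        order = np.argsort(ids)
        return RDState(ids[order], u[order], v[order])


def equilibrium_state(params: RDParams) -> EquilibriumState:
    """Homogeneous interior equilibrium (u0, v0); raises
    :class:`NoPositiveEquilibrium` when the denominator
    ``beta*gamma - (alpha_s - alpha_d)*delta`` is not positive."""
    den = params.beta * params.gamma - (params.alpha_s - params.alpha_d) * params.delta
    if den <= 0:
        raise NoPositiveEquilibrium(
            f"beta*gamma - (alpha_s - alpha_d)*delta = {den} <= 0")
    return EquilibriumState(params.delta * params.eps / den,
                            params.gamma * params.eps / den)


def mode_growth_rate(params: RDParams, lam: float) -> float:
    """Largest real eigenvalue of the linearized reaction-diffusion operator
    restricted to a graph-Laplacian eigenmode with eigenvalue ``lam``.

    Around the interior equilibrium (phi unclamped, psi = 0) the Jacobian of
    the reaction part is ``[[alpha_s - alpha_d, -beta], [gamma, -delta]]``;
    diffusion subtracts ``diag(D_u, D_v) * lam`` mode by mode.
    """
    if lam < 0:
        raise ValueError("graph Laplacian eigenvalues are non-negative")
    J = np.array([[params.alpha_s - params.alpha_d - params.D_u * lam,
                   -params.beta],
                  [params.gamma, -params.delta - params.D_v * lam]])
    return float(np.linalg.eigvals(J).real.max())


def turing_unstable(params: RDParams, laplacian_eigenvalues) -> bool:
    """True when the homogeneous equilibrium is stable to uniform
    perturbations but some non-uniform Laplacian mode grows."""
    lams = np.asarray(laplacian_eigenvalues, float)
    if mode_growth_rate(params, 0.0) >= 0:
        return False
    return any(mode_growth_rate(params, l) > 0 for l in lams if l > 1e-12)


def phi(x: float, params: RDParams) -> float:
    """Clamped activator synthesis: x limited to [0, alpha_d * u_max]."""
    hi = params.alpha_d * params.u_max
    return 0.0 if x < 0 else (hi if x > hi else x)


def psi(cell_id: int, network: CellNetwork, params: RDParams) -> float:
    """Extra activator decay: ``alpha_m`` in marginal cells, 0 elsewhere."""
    return params.alpha_m if network.is_marginal(cell_id) else 0.0


def _check_aligned(state: RDState, network: CellNetwork) -> None:
    ids = np.array(network.cell_ids(), np.int64)
    if len(ids) != len(state.cell_ids) or np.any(ids != state.cell_ids):
        raise ValueError("RD state is not aligned to the network's cells")


def _edges_and_psi(network: CellNetwork, params: RDParams):
    ids = network.cell_ids()
    index = {c: i for i, c in enumerate(ids)}
    pairs = network.adjacency_edges()
    e1 = np.array([index[a] for a, b in pairs], np.int64)
    e2 = np.array([index[b] for a, b in pairs], np.int64)
    psi_arr = np.array([params.alpha_m if network.is_marginal(c) else 0.0
                        for c in ids])
    return e1, e2, psi_arr


def _integrate(state: RDState, network: CellNetwork, params: RDParams,
               n_steps: int) -> RDState:
    _check_aligned(state, network)
    out = state.copy()
    e1, e2, psi_arr = _edges_and_psi(network, params)
    rd_kernel(out.u, out.v, e1, e2, psi_arr,
              params.alpha_s, params.alpha_d, params.beta, params.gamma,
              params.delta, params.eps, params.D_u, params.D_v,
              params.u_max, params.dt, n_steps)
    return out


def rd_step(state: RDState, network: CellNetwork, params: RDParams) -> RDState:
    """One forward-Euler update of every cell's (u, v), with u clipped to
    [0, u_max] and v to [0, inf) afterwards."""
    return _integrate(state, network, params, 1)


def rd_run(state: RDState, network: CellNetwork, params: RDParams) -> RDState:
    """Apply exactly ``round(Td/dt)`` Euler steps (2500 at the default
    Td = 50, dt = 0.02) — the fixed-step realisation of integrating to an
    almost steady state."""
    return _integrate(state, network, params, params.n_steps)


def perturb_equilibrium(network: CellNetwork, params: RDParams,
                        fraction: float,
                        seed_or_rng) -> RDState:
    """Initial condition: the homogeneous equilibrium with an independent
    uniform relative fluctuation of +/- ``fraction`` on every u_i and v_i."""
    if not 0 <= fraction < 1:
        raise ValueError("fraction must be in [0, 1)")
    rng = (seed_or_rng if isinstance(seed_or_rng, np.random.Generator)
           else np.random.default_rng(seed_or_rng))
    eq = equilibrium_state(params)
    ids = np.array(network.cell_ids(), np.int64)
    n = len(ids)
    u = eq.u_0 * (1 + fraction * rng.uniform(-1, 1, n))
    v = eq.v_0 * (1 + fraction * rng.uniform(-1, 1, n))
    return RDState(ids, u, v)
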