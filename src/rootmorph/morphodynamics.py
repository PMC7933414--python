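"""Growth orchestration: repeated division -> relaxation -> reaction cycles.

A simulation starts from a small relaxed tissue with the activator/inhibitor
field at its homogeneous equilibrium plus a small random fluctuation, then
repeats the three-step cycle — divide the largest cell along a random line
through its centroid, relax the vertex mechanics to equilibrium, integrate
the reaction-diffusion dynamics for one division interval — until the target
cell count is reached.  One division happens per cycle (the division clock T
and the reaction-diffusion time Td per cycle are both 50 time units).

Replicate sweeps rerun the whole pipeline with independent seeds (fresh
initial geometry, fluctuation, and division angles per replicate) and
collect the classified final patterns.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import DivisionRetry
from .network import CellNetwork, MechParams, initial_network
from .pattern_classify import PatternSummary, classify
from .reaction_diffusion import (RDParams, RDState, equilibrium_state,
                                 perturb_equilibrium, rd_run)

__all__ = ["SimulationConfig", "SimulationResult", "SweepResult",
           "run_simulation", "run_replicates", "run_grid", "grid_summary"]

logger = logging.getLogger(__name__)

_MAX_ANGLE_RETRIES = 100


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one growth simulation.

    ``u_max_factor`` sets the activator saturation as a multiple of the
    homogeneous equilibrium u0 (10 for the high-saturation "spotted" regime,
    1.1 for the low-saturation "reverse-spotted" regime); it overrides
    ``rd.u_max`` at run time so that sweeps over alpha_s / gamma keep the
    saturation tied to the regime rather than to an absolute number.
    """

    mech: MechParams = MechParams()
    rd: RDParams = RDParams()
    n_start: int = 10
    n_end: int = 1000
    fluctuation: float = 0.01
    seed: int = 0
    u_max_factor: float | None = 10.0
    snapshot_cells: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.n_start < 1 or self.n_end < self.n_start:
            raise ValueError("need 1 <= n_start <= n_end")
        if not 0 <= self.fluctuation < 1:
            raise ValueError("fluctuation must be in [0, 1)")

    def resolved_rd(self) -> RDParams:
        if self.u_max_factor is None:
            return self.rd
        return self.rd.with_u_max_factor(self.u_max_factor)


@dataclass
class SimulationResult:
    network: CellNetwork
    state: RDState
    config: SimulationConfig
    snapshots: dict[int, tuple[CellNetwork, RDState]] = field(default_factory=dict)

    def summary(self) -> PatternSummary:
        eq = equilibrium_state(self.config.resolved_rd())
        return classify(self.network, self.state, eq.u_0)


@dataclass
class SweepResult:
    """Replicate set at one grid point (alpha_s, gamma, u_max_factor)."""

    alpha_s: float
    gamma: float
    u_max_factor: float
    seeds: list[int]
    results: list[SimulationResult]
    summaries: list[PatternSummary]


def run_simulation(config: SimulationConfig) -> SimulationResult:
    """Run one growth simulation; fully deterministic for a fixed config.

    The RNG stream order is fixed — initial network geometry, then the
    initial fluctuation, then one angle draw per division (plus redraws when
    a cut grazes a vertex) — so identical configs give bit-identical output.
    """
    rd_params = config.resolved_rd()
    rng = np.random.default_rng(config.seed)
    net_seed = int(rng.integers(2**31))
    net = initial_network(config.n_start, net_seed, config.mech)
    state = perturb_equilibrium(net, rd_params, config.fluctuation, rng)
    result = SimulationResult(net, state, config)
    _maybe_snapshot(result, net, state, config)
    cycle = 0
    while net.n_cells < config.n_end:
        cycle += 1
        state = _one_cycle(net, state, config, rd_params, rng)
        _maybe_snapshot(result, net, state, config)
        if cycle % 100 == 0:
            logger.info("cycle %d: %d cells, relax %s",
                        cycle, net.n_cells, net.last_relax)
    result.state = state
    return result


def _one_cycle(net: CellNetwork, state: RDState, config: SimulationConfig,
               rd_params: RDParams, rng: np.random.Generator) -> RDState:
    mother = net.largest_cell()
    for attempt in range(_MAX_ANGLE_RETRIES):
        angle = rng.uniform(0.0, math.pi)
        try:
            daughters = net.divide_cell(mother, angle)
            break
        except DivisionRetry:
            continue
    else:
        raise DivisionRetry(
            f"cell {mother} admits no centroid cut after "
            f"{_MAX_ANGLE_RETRIES} angles")
    state = state.replace_cell(mother, daughters)
    net.relax(config.mech)
    if not net.last_relax.converged:
        logger.warning("relaxation hit iteration cap at %d cells",
                       net.n_cells)
    return rd_run(state, net, rd_params)


def _maybe_snapshot(result: SimulationResult, net: CellNetwork,
                    state: RDState, config: SimulationConfig) -> None:
    if net.n_cells in config.snapshot_cells:
        result.snapshots[net.n_cells] = (
            CellNetwork.from_json(net.to_json()), state.copy())


def run_replicates(config: SimulationConfig, n_rep: int,
                   base_seed: int | None = None) -> SweepResult:
    """``n_rep`` independent simulations with seeds base_seed + k; every
    replicate redraws its initial geometry, fluctuation, and angles."""
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    base = config.seed if base_seed is None else base_seed
    seeds = [base + k for k in range(n_rep)]
    results = [run_simulation(replace(config, seed=s)) for s in seeds]
    return SweepResult(
        alpha_s=config.rd.alpha_s, gamma=config.rd.gamma,
        u_max_factor=(config.u_max_factor if config.u_max_factor is not None
                      else config.rd.u_max),
        seeds=seeds, results=results,
        summaries=[r.summary() for r in results])


def run_grid(alpha_s_values, gamma_values, u_max_factors,
             config: SimulationConfig, n_rep: int) -> list[SweepResult]:
    """Cartesian sweep over (alpha_s, gamma, u_max_factor) with ``n_rep``
    replicates at each grid point."""
    alpha_s_values = list(alpha_s_values)
    gamma_values = list(gamma_values)
    u_max_factors = list(u_max_factors)
    if not (alpha_s_values and gamma_values and u_max_factors):
        raise ValueError("all grids must be non-empty")
    out = []
    for f in u_max_factors:
        for a in alpha_s_values:
            for g in gamma_values:
                cfg = replace(config,
                              rd=replace(config.rd, alpha_s=a, gamma=g),
                              u_max_factor=f)
                out.append(run_replicates(cfg, n_rep))
    return out


def grid_summary(sweeps: list[SweepResult]):
    """Pattern-class frequency table per grid point (pandas DataFrame)."""
    import pandas as pd

    rows = []
    for s in sweeps:
        for seed, summ in zip(s.seeds, s.summaries):
            rows.append({"alpha_s": s.alpha_s, "gamma": s.gamma,
                         "u_max_factor": s.u_max_factor, "seed": seed,
                         "polarity": summ.polarity,
                         "n_regions": summ.n_regions,
                         "root_label": summ.root_label})
    df = pd.DataFrame(rows)
    return (df.groupby(["alpha_s", "gamma", "u_max_factor", "root_label"])
              .size().rename("count").reset_index())
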