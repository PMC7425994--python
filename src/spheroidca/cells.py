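"""Per-cell state and cell-cycle progression.

Each cell owns a stochastic doubling time tau_i ~ Normal(mu, sigma^2)
(redrawn if non-positive) and progresses through G1 -> S -> G2 -> M via an
intrinsic clock. Under well-oxygenated conditions the phases occupy fixed
fractions Theta of tau_i (11/24, 8/24, 4/24, 1/24, summing to one). Hypoxia
delays the cycle through the G1 Delay Factor (G1DF), a piecewise fit that
doubles the G1 duration below 1 mmHg and relaxes to one above ~10.5 mmHg;
only G1 is oxygen-dependent.

Cells that finish mitosis without free lattice space within the nu-th order
neighbourhood do not divide: in vitro they keep cycling very slowly
(slow-cycling), in vivo they rest in G0 (quiescent). Both resting states
are reported under the common "slow/non-proliferative" (S/N-P) label and
may resume active cycling when treatment frees nearby space.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace

import numpy as np

from .lattice import LatticeGrid, Topology, shell_offsets

__all__ = [
    "Phase",
    "CellState",
    "GrowthMode",
    "CycleParameters",
    "CellAgent",
    "sample_doubling_time",
    "g1_delay_factor",
    "phase_durations",
    "cycle_length",
    "phase_from_clock",
    "advance_cell",
    "divide",
    "update_proliferative_state",
]


class Phase(enum.IntEnum):
    G1 = 0
    S = 1
    G2 = 2
    M = 3
    G0 = 4  # radiosensitivity row for resting (slow/quiescent) cells


class CellState(enum.IntEnum):
    CYCLING = 0
    SLOW_CYCLING = 1  # in-vitro space-restricted cells
    QUIESCENT_G0 = 2  # in-vivo space-restricted cells


class GrowthMode(enum.Enum):
    IN_VITRO = "in_vitro"
    IN_VIVO = "in_vivo"


@dataclass
class CycleParameters:
    """Cell-cycle parameters (hours / dimensionless fractions)."""

    mu: float = 40.0
    sigma: float = 4.0
    theta: tuple[float, float, float, float] = (11 / 24, 8 / 24, 4 / 24, 1 / 24)
    # G1DF fit coefficients for the 1..10.5 mmHg branch
    a1: float = 0.9209
    a2: float = 0.8200
    a3: float = -0.2389
    slow_cycle_factor: float = 0.1  # clock rate of in-vitro slow-cycling cells

    def validate(self) -> list[str]:
        errs = []
        if self.mu <= 0:
            errs.append("cycle.mu must be > 0")
        if self.sigma < 0:
            errs.append("cycle.sigma must be >= 0")
        if abs(sum(self.theta) - 1.0) > 1e-12:
            errs.append("cycle.theta fractions must sum to 1")
        if not 0 <= self.slow_cycle_factor <= 1:
            errs.append("cycle.slow_cycle_factor must be in [0, 1]")
        return errs


@dataclass
class CellAgent:
    """One lattice-resident cell."""

    position: tuple[int, int, int]
    tau: float
    clock: float = 0.0
    state: CellState = CellState.CYCLING
    viable: bool = True
    death_time: float = float("nan")


def sample_doubling_time(params: CycleParameters, rng: np.random.Generator) -> float:
    """Draw tau ~ Normal(mu, sigma^2), redrawn until strictly positive.

    At mu/sigma = 10 the redraw perturbs the stated mean/SD only at the
    ~1e-11 level, so the configured moments are effectively preserved.
    """
    if params.sigma == 0:
        return params.mu
    while True:
        tau = rng.normal(params.mu, params.sigma)
        if tau > 0:
            return float(tau)


def g1_delay_factor(pO2, params: CycleParameters = CycleParameters()):
    """G1 Delay Factor as a function of oxygen partial pressure (mmHg).

    Piecewise: 2 on [0, 1) mmHg, a1 + a2/(a3 + pO2) on [1, 10.5] mmHg and 1
    above. Accepts scalars or arrays; negative oxygen raises.
    """
    p = np.asarray(pO2, dtype=float)
    if np.any(p < 0):
        raise ValueError("pO2 must be non-negative")
    mid = params.a1 + params.a2 / (params.a3 + p)
    out = np.where(p < 1.0, 2.0, np.where(p <= 10.5, mid, 1.0))
    if np.ndim(pO2) == 0:
        return float(out)
    return out


def phase_durations(tau: float, g1df: float, params: CycleParameters = CycleParameters()):
    """Durations (h) of G1, S, G2, M; only G1 is scaled by the G1DF."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    tG1, tS, tG2, tM = (th * tau for th in params.theta)
    return (g1df * tG1, tS, tG2, tM)


def cycle_length(tau, g1df, params: CycleParameters = CycleParameters()):
    """Total cycle length; vectorises over tau/g1df."""
    thG1, thS, thG2, thM = params.theta
    return tau * (thS + thG2 + thM) + g1df * thG1 * tau


def phase_from_clock(clock, tau, g1df, params: CycleParameters = CycleParameters()):
    """Current phase code (0..3) given clock position; vectorised."""
    thG1, thS, thG2, _ = params.theta
    b1 = np.asarray(g1df) * thG1 * np.asarray(tau)
    b2 = b1 + thS * np.asarray(tau)
    b3 = b2 + thG2 * np.asarray(tau)
    c = np.asarray(clock)
    code = (c >= b1).astype(np.int8) + (c >= b2) + (c >= b3)
    return np.minimum(code, 3)


def advance_cell(
    cell: CellAgent,
    dt: float,
    local_pO2: float,
    mode: GrowthMode,
    params: CycleParameters = CycleParameters(),
) -> tuple[CellAgent, bool]:
    """Advance one cell's clock by dt and report division readiness.

    The clock runs at full speed while cycling, at ``slow_cycle_factor``
    speed for in-vitro slow-cycling cells and not at all for in-vivo
    quiescent cells. The G1 duration is re-evaluated from the instantaneous
    oxygen each step. The clock is capped at the (current) cycle length;
    the cell is division-ready once it reaches it.
    """
    if not cell.viable:
        raise ValueError("cannot advance a dying cell")
    if cell.state is CellState.CYCLING:
        rate = 1.0
    elif cell.state is CellState.SLOW_CYCLING:
        rate = params.slow_cycle_factor if mode is GrowthMode.IN_VITRO else 0.0
    else:
        rate = 0.0
    g1df = g1_delay_factor(local_pO2, params)
    total = cycle_length(cell.tau, g1df, params)
    clock = min(cell.clock + rate * dt, total)
    new = replace(cell, clock=clock)
    return new, clock >= total


def divide(
    mother: CellAgent,
    site: tuple[int, int, int],
    grid: LatticeGrid,
    params: CycleParameters,
    rng: np.random.Generator,
) -> CellAgent:
    """Produce a daughter at ``site`` and reset the mother's cycle.

    The daughter starts its first cycle in G1 (clock 0) with a freshly
    sampled doubling time; the mother keeps her own tau and restarts in G1.
    """
    if not grid.is_free(site):
        raise ValueError(f"division site {site} is occupied")
    mother.clock = 0.0
    mother.state = CellState.CYCLING
    return CellAgent(position=tuple(site), tau=sample_doubling_time(params, rng))


def _has_free_within(grid: LatticeGrid, pos, nu: int) -> bool:
    # Chebyshev ball (union of Moore shells 1..nu) — the widest reach a
    # daughter placement can have.
    for order in range(1, nu + 1):
        offs = shell_offsets(Topology.MOORE, order)
        sites = np.asarray(pos)[None, :] + offs
        ok = np.all((sites >= 0) & (sites < np.asarray(grid.dims)[None, :]), axis=1)
        sites = sites[ok]
        if np.any(grid.occupancy[sites[:, 0], sites[:, 1], sites[:, 2]] == -1):
            return True
    return False


def update_proliferative_state(
    cell: CellAgent,
    grid: LatticeGrid,
    nu: int,
    mode: GrowthMode,
    division_ready: bool = False,
) -> CellAgent:
    """Space-driven transitions between cycling and resting states.

    A division-ready cell with no free voxel within order nu becomes
    slow-cycling (in vitro) or quiescent (in vivo); a resting cell with
    free space nearby resumes cycling.
    """
    if not cell.viable:
        raise ValueError("cannot update a dying cell")
    free = _has_free_within(grid, cell.position, nu)
    if division_ready and not free:
        new_state = (
            CellState.SLOW_CYCLING if mode is GrowthMode.IN_VITRO else CellState.QUIESCENT_G0
        )
        return replace(cell, state=new_state)
    if cell.state is not CellState.CYCLING and free:
        return replace(cell, state=CellState.CYCLING)
    return cell
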