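"""Simulation orchestration: grow spheroids, run treatment schedules.

One step of the automaton (cell-clock step ``dt``) performs, in order:
advance cell clocks -> attempt divisions -> fire due schedule events ->
step the drug fields (if any drug is present) -> apply AHAP cytotoxicity
-> process removals -> refresh quasi-steady oxygen (at its cadence or when
occupancy changed) -> record a summary row (at the output cadence).
Drugs are stepped before kill checks so that a dose given this step can
already kill. Events sharing a time execute in schedule order.

All randomness (doubling times, placement topology and site, IR Bernoulli
draws) flows from a single per-run numpy Generator, so a run is
bit-reproducible given its seed; replicate seeds are spawned from the base
seed with ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import ndimage

from . import lattice as lat
from .cells import (
    CellState,
    GrowthMode,
    cycle_length,
    g1_delay_factor,
    phase_from_clock,
    sample_doubling_time,
)
from .config import ScheduleEvent, SimulationConfig
from .drugs import DrugStepper, RemovalPolicy
from .lattice import EMPTY, LatticeGrid, find_division_site
from .oxygen import hypoxic_fraction, scaled_oxygen, solve_oxygen_steady
from .radiation import IRDose, apply_irradiation

__all__ = [
    "CellPopulation",
    "SimulationState",
    "new_state",
    "run_simulation",
    "run_replicates",
    "apply_schedule_event",
    "scale_oxygen_landscape",
    "SUMMARY_COLUMNS",
]

SUMMARY_COLUMNS = [
    "time_h", "n_G1", "n_S", "n_G2", "n_M", "n_SNP", "n_dying",
    "hypoxic_fraction", "hap_mass", "ahap_mass",
]


class CellPopulation:
    """Struct-of-arrays container for every cell ever placed on the lattice.

    Removed cells keep their slot with ``present = False``; vector
    operations mask on ``present``. This keeps grid occupancy indices
    stable without compaction.
    """

    def __init__(self, capacity: int = 1024):
        self._n = 0
        self.pos = np.zeros((capacity, 3), dtype=np.int32)
        self.tau = np.zeros(capacity)
        self.clock = np.zeros(capacity)
        self.state = np.zeros(capacity, dtype=np.int8)
        self.dying = np.zeros(capacity, dtype=bool)
        self.death_time = np.full(capacity, np.nan)
        self.death_cause = np.zeros(capacity, dtype=np.int8)  # 0 none, 1 drug, 2 IR
        self.present = np.zeros(capacity, dtype=bool)

    def __len__(self) -> int:
        return self._n

    def _grow(self):
        cap = len(self.tau)
        new = 2 * cap
        self.pos = np.resize(self.pos, (new, 3))
        for name in ("tau", "clock", "death_time"):
            setattr(self, name, np.resize(getattr(self, name), new))
        for name in ("state", "dying", "death_cause", "present"):
            arr = getattr(self, name)
            out = np.zeros(new, dtype=arr.dtype)
            out[:cap] = arr
            setattr(self, name, out)

    def add(self, site, tau: float) -> int:
        if self._n == len(self.tau):
            self._grow()
        i = self._n
        self.pos[i] = site
        self.tau[i] = tau
        self.clock[i] = 0.0
        self.state[i] = CellState.CYCLING
        self.dying[i] = False
        self.death_time[i] = np.nan
        self.death_cause[i] = 0
        self.present[i] = True
        self._n += 1
        return i

    @property
    def viable(self) -> np.ndarray:
        return self.present[: self._n] & ~self.dying[: self._n]

    def view(self, name: str) -> np.ndarray:
        return getattr(self, name)[: self._n]


@dataclass
class _DoseWindow:
    start: float
    end: float
    magnitude: float


@dataclass
class SimulationState:
    """Full mutable state of one run."""

    config: SimulationConfig
    grid: LatticeGrid
    pop: CellPopulation
    rng: np.random.Generator
    time: float = 0.0
    K: np.ndarray | None = None  # raw oxygen
    khat: np.ndarray | None = None  # scaled oxygen, mmHg
    khat_frozen: bool = False  # synthetic landscapes: never re-solve
    HAP: np.ndarray | None = None
    AHAP: np.ndarray | None = None
    oxygen_scale: float = 1.0
    dose_windows: list = dc_field(default_factory=list)
    event_log: list = dc_field(default_factory=list)
    events_fired: int = 0
    _oxy_dirty: bool = True
    _last_refresh: float = -np.inf
    _occ_version: int = 0
    _stepper: DrugStepper | None = None
    _stepper_version: int = -1

    # -- geometry helpers ---------------------------------------------------

    def occupied(self) -> np.ndarray:
        return self.grid.occupancy != EMPTY

    def consuming(self) -> np.ndarray:
        """Voxels with a viable (oxygen-consuming) cell."""
        mask = np.zeros(self.grid.dims, dtype=bool)
        v = self.pop.viable
        p = self.pop.view("pos")[v]
        mask[p[:, 0], p[:, 1], p[:, 2]] = True
        return mask

    def exterior(self) -> np.ndarray:
        return lat.exterior_mask(self.occupied())

    def pO2_at(self, positions: np.ndarray) -> np.ndarray:
        k = self.khat_effective()
        return k[positions[:, 0], positions[:, 1], positions[:, 2]]

    def khat_effective(self) -> np.ndarray:
        if self.khat is None:
            raise RuntimeError("oxygen field not initialised")
        return self.khat * self.oxygen_scale

    def n_viable(self) -> int:
        return int(np.count_nonzero(self.pop.viable))

    def copy(self) -> "SimulationState":
        cfg = self.config
        self.config = None  # shared, not copied
        try:
            new = copy.deepcopy(self)
        finally:
            self.config = cfg
        new.config = cfg
        return new

    def reseed(self, seed) -> None:
        self.rng = np.random.default_rng(seed)

    # -- summaries ----------------------------------------------------------

    def summary_row(self) -> dict:
        pop, cfg = self.pop, self.config
        v = pop.viable
        cyc = v & (pop.view("state") == CellState.CYCLING)
        snp = v & (pop.view("state") != CellState.CYCLING)
        pos_v = pop.view("pos")[v]
        pO2 = self.pO2_at(pos_v) if len(pos_v) else np.empty(0)
        if np.any(cyc):
            p_cyc = self.pO2_at(pop.view("pos")[cyc])
            g1df = g1_delay_factor(p_cyc, cfg.cycle)
            phases = phase_from_clock(pop.view("clock")[cyc], pop.view("tau")[cyc],
                                      g1df, cfg.cycle)
            counts = np.bincount(phases, minlength=4)
        else:
            counts = np.zeros(4, dtype=int)
        return {
            "time_h": self.time,
            "n_G1": int(counts[0]), "n_S": int(counts[1]),
            "n_G2": int(counts[2]), "n_M": int(counts[3]),
            "n_SNP": int(np.count_nonzero(snp)),
            "n_dying": int(np.count_nonzero(pop.view("present") & pop.view("dying"))),
            "hypoxic_fraction": hypoxic_fraction(pO2, cfg.oxygen.hypoxia_threshold),
            "hap_mass": float(self.HAP.sum()) if self.HAP is not None else 0.0,
            "ahap_mass": float(self.AHAP.sum()) if self.AHAP is not None else 0.0,
        }


def new_state(config: SimulationConfig, seed_cell: bool = True) -> SimulationState:
    """Fresh state with one seeding cell at the lattice centre."""
    config.validate()
    grid = LatticeGrid(config.dims, config.spacing_um)
    pop = CellPopulation()
    rng = np.random.default_rng(config.seed)
    state = SimulationState(config=config, grid=grid, pop=pop, rng=rng,
                            oxygen_scale=config.oxygen_scale_factor)
    if seed_cell:
        center = tuple(d // 2 for d in config.dims)
        i = pop.add(center, sample_doubling_time(config.cycle, rng))
        grid.occupancy[center] = i
        _refresh_oxygen(state, force=True)
    return state


# ---------------------------------------------------------------------------
# per-step machinery

def _refresh_oxygen(state: SimulationState, force: bool = False) -> None:
    if state.khat_frozen:
        return
    cfg = state.config
    due = state._oxy_dirty and (state.time - state._last_refresh >= cfg.oxygen_refresh_every)
    if not (force or due or state.khat is None):
        return
    if not np.any(state.consuming()):
        # no sinks left: oxygen equilibrates to a uniform, fully oxygenated field
        state.K = np.ones(state.grid.dims)
        state.khat = np.full(state.grid.dims, cfg.oxygen.h_effective)
        state._last_refresh = state.time
        state._oxy_dirty = False
        return
    # 1e-7 relative residual leaves the scaled field accurate far below the
    # 10 mmHg hypoxia threshold resolution while keeping refreshes cheap
    K = solve_oxygen_steady(
        state.occupied(), state.consuming(), state.exterior(), cfg.oxygen,
        spacing_um=cfg.spacing_um, x0=state.K, rtol=1e-7,
    )
    state.K = K
    state.khat = scaled_oxygen(K, cfg.oxygen.h_effective)
    state._last_refresh = state.time
    state._oxy_dirty = False


def _advance_and_divide(state: SimulationState, dt: float) -> None:
    pop, cfg = state.pop, state.config
    n = len(pop)
    if n == 0:
        return
    v = pop.viable
    if not np.any(v):
        return
    st = pop.view("state")
    rate = np.zeros(n)
    rate[st == CellState.CYCLING] = 1.0
    if cfg.mode is GrowthMode.IN_VITRO:
        rate[st == CellState.SLOW_CYCLING] = cfg.cycle.slow_cycle_factor
    pos = pop.view("pos")
    pO2 = state.pO2_at(pos[v])
    g1df = np.ones(n)
    g1df[v] = g1_delay_factor(pO2, cfg.cycle)
    total = cycle_length(pop.view("tau"), g1df, cfg.cycle)
    clock = pop.view("clock")
    clock[v] = np.minimum(clock[v] + rate[v] * dt, total[v])
    ready = v & (st == CellState.CYCLING) & (clock >= total)
    for i in np.flatnonzero(ready):
        site = find_division_site(state.grid, pos[i], cfg.nu, state.rng)
        if site is None:
            st[i] = (CellState.SLOW_CYCLING if cfg.mode is GrowthMode.IN_VITRO
                     else CellState.QUIESCENT_G0)
            continue
        clock[i] = 0.0
        j = pop.add(site, sample_doubling_time(cfg.cycle, state.rng))
        state.grid.occupancy[site] = j
        # pop views may have been reallocated by growth
        pos = pop.view("pos")
        st = pop.view("state")
        clock = pop.view("clock")
        state._oxy_dirty = True
        state._occ_version += 1


def apply_schedule_event(event: ScheduleEvent, state: SimulationState) -> None:
    """Execute one dose event on the current state."""
    cfg = state.config
    if event.modality == "IR":
        _refresh_oxygen(state, force=state._oxy_dirty)
        pop = state.pop
        v = pop.viable
        idx = np.flatnonzero(v)
        if len(idx) == 0 or event.magnitude == 0:
            state.event_log.append({"time": state.time, "modality": "IR",
                                    "magnitude": event.magnitude,
                                    "viable_before": len(idx),
                                    "viable_after": len(idx), "expected_sf": 1.0})
            state.events_fired += 1
            return
        pos = pop.view("pos")[idx]
        pO2 = state.pO2_at(pos)
        st = pop.view("state")[idx]
        g1df = g1_delay_factor(pO2, cfg.cycle)
        phases = phase_from_clock(pop.view("clock")[idx], pop.view("tau")[idx],
                                  g1df, cfg.cycle).astype(int)
        phases[st != CellState.CYCLING] = 4  # G0 radiosensitivity row
        from .radiation import survival_probability
        expected_sf = float(np.mean(
            survival_probability(phases, pO2, event.magnitude, cfg.radio)))
        killed = apply_irradiation(phases, pO2, IRDose(event.magnitude, event.time),
                                   cfg.radio, state.rng)
        ki = idx[killed]
        pop.view("dying")[ki] = True
        pop.view("death_time")[ki] = state.time
        pop.view("death_cause")[ki] = 2
        state.event_log.append({"time": state.time, "modality": "IR",
                                "magnitude": event.magnitude,
                                "viable_before": len(idx),
                                "viable_after": len(idx) - len(ki),
                                "expected_sf": expected_sf})
        if len(ki):
            state._oxy_dirty = True
    elif event.modality == "HAP":
        duration = event.duration if event.duration is not None else cfg.drugs.dose_duration
        state.dose_windows.append(
            _DoseWindow(state.time, state.time + duration, event.magnitude))
        state.event_log.append({"time": state.time, "modality": "HAP",
                                "magnitude": event.magnitude,
                                "viable_before": state.n_viable(),
                                "pop_len": len(state.pop)})
        if state.HAP is None:
            state.HAP = np.zeros(state.grid.dims)
            state.AHAP = np.zeros(state.grid.dims)
    else:
        raise ValueError(f"unknown treatment modality {event.modality!r}")
    state.events_fired += 1


def _drug_present(state: SimulationState) -> bool:
    if state.HAP is None:
        return False
    if any(w.end > state.time for w in state.dose_windows):
        return True
    # kills need AHAP >= psi; fields two orders below the threshold can no
    # longer produce a lethal concentration anywhere, so stop integrating
    tol = 1e-2 * state.config.drugs.psi
    return float(state.HAP.max()) > tol or float(state.AHAP.max()) > tol


def _get_stepper(state: SimulationState, dt: float) -> DrugStepper:
    cfg = state.config
    rebuild = (
        state._stepper is None
        or state._stepper.dt != dt
        # tolerate a few divisions without reassembling the operators
        or state._occ_version - state._stepper_version > max(50, len(state.pop) // 100)
    )
    if rebuild:
        state._stepper = DrugStepper(
            state.occupied(), state.exterior(), cfg.drugs, cfg.oxygen, dt,
            spacing_um=cfg.spacing_um, method=cfg.solver,
        )
        state._stepper_version = state._occ_version
    return state._stepper


def _step_drug_fields(state: SimulationState, dt: float) -> None:
    cfg = state.config
    dt_d = min(cfg.drug_dt, dt)
    n_sub = max(1, int(round(dt / dt_d)))
    dt_d = dt / n_sub
    stepper = _get_stepper(state, dt_d)
    pO2 = state.khat_effective()
    t = state.time
    for _ in range(n_sub):
        active = [w for w in state.dose_windows if w.start <= t < w.end]
        if cfg.mode is GrowthMode.IN_VITRO:
            bath = sum(w.magnitude for w in active) if active else None
            rate = 0.0
        else:
            bath = None
            rate = sum(w.magnitude for w in active)
        state.HAP, state.AHAP = stepper.step(state.HAP, state.AHAP, pO2,
                                             dosing_rate=rate, bath=bath)
        t += dt_d


def _apply_cytotoxicity(state: SimulationState, now: float) -> None:
    pop = state.pop
    psi = state.config.drugs.psi
    v = pop.viable
    idx = np.flatnonzero(v)
    if len(idx) == 0:
        return
    pos = pop.view("pos")[idx]
    lethal = state.AHAP[pos[:, 0], pos[:, 1], pos[:, 2]] >= psi
    ki = idx[lethal]
    if len(ki):
        pop.view("dying")[ki] = True
        pop.view("death_time")[ki] = now
        pop.view("death_cause")[ki] = 1
        state._oxy_dirty = True


def _process_removals(state: SimulationState, now: float) -> None:
    cfg = state.config
    policy = cfg.drugs.removal_policy
    if policy is RemovalPolicy.NEVER:
        return
    pop = state.pop
    d = pop.view("present") & pop.view("dying")
    if policy is RemovalPolicy.DOUBLING_TIME:
        d = d & (now - pop.view("death_time") >= pop.view("tau"))
    idx = np.flatnonzero(d)
    if len(idx) == 0:
        return
    pos = pop.view("pos")[idx]
    state.grid.occupancy[pos[:, 0], pos[:, 1], pos[:, 2]] = EMPTY
    pop.view("present")[idx] = False
    state._oxy_dirty = True
    state._occ_version += len(idx)
    _revert_resting_cells(state)


def _revert_resting_cells(state: SimulationState) -> None:
    """Resting cells with freed space within order nu resume cycling."""
    cfg = state.config
    pop = state.pop
    resting = pop.viable & (pop.view("state") != CellState.CYCLING)
    idx = np.flatnonzero(resting)
    if len(idx) == 0:
        return
    free = state.grid.occupancy == EMPTY
    near_free = ndimage.maximum_filter(free, size=2 * cfg.nu + 1)
    pos = pop.view("pos")[idx]
    revert = near_free[pos[:, 0], pos[:, 1], pos[:, 2]]
    pop.view("state")[idx[revert]] = CellState.CYCLING


def _step(state: SimulationState, dt: float, pending: list[ScheduleEvent]) -> None:
    t_end = state.time + dt
    _advance_and_divide(state, dt)
    while pending and pending[0].time <= t_end + 1e-9:
        apply_schedule_event(pending.pop(0), state)
    if _drug_present(state):
        _step_drug_fields(state, dt)
        _apply_cytotoxicity(state, t_end)
    _process_removals(state, t_end)
    state.time = t_end
    _refresh_oxygen(state)


def run_simulation(
    config: SimulationConfig,
    duration: float,
    initial_state: SimulationState | None = None,
    stop_when=None,
    record: bool = True,
) -> tuple[pd.DataFrame, SimulationState]:
    """Run (or continue) a simulation for ``duration`` hours.

    Returns the summary time series and the final state. ``initial_state``
    is advanced in place; pass ``state.copy()`` to keep the original.
    ``stop_when(state)`` may end the run early (checked at every step).
    """
    config.validate()
    state = initial_state if initial_state is not None else new_state(config)
    t0 = state.time
    pending = sorted(config.schedule.events, key=lambda e: e.time)
    pending = [ScheduleEvent(e.time + t0, e.modality, e.magnitude, e.duration)
               for e in pending][state.events_fired:]
    rows = []
    next_record = t0
    if record:
        rows.append(state.summary_row())
        next_record = t0 + config.output_every
    n_steps = int(np.ceil(duration / config.dt - 1e-9))
    for k in range(n_steps):
        dt = min(config.dt, t0 + duration - state.time)
        if dt <= 0:
            break
        _step(state, dt, pending)
        if record and state.time + 1e-9 >= next_record:
            rows.append(state.summary_row())
            next_record += config.output_every
        if stop_when is not None and stop_when(state):
            break
    df = pd.DataFrame(rows, columns=SUMMARY_COLUMNS) if record else pd.DataFrame(
        columns=SUMMARY_COLUMNS)
    return df, state


def scale_oxygen_landscape(state: SimulationState, factor: float) -> SimulationState:
    """Scale the oxygen landscape seen by every oxygen-dependent response."""
    if factor <= 0:
        raise ValueError("oxygen scale factor must be > 0")
    state.oxygen_scale = factor
    return state


def run_replicates(
    config: SimulationConfig,
    duration: float,
    n_runs: int | None = None,
    initial_state: SimulationState | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, list[pd.DataFrame]]:
    """Mean and SD time series over independent replicate runs.

    Replicates share the initial state (if given) but draw from
    independently spawned random streams.
    """
    n_runs = n_runs if n_runs is not None else config.run_count
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    children = np.random.SeedSequence(config.seed).spawn(n_runs)
    runs = []
    for child in children:
        if initial_state is not None:
            st = initial_state.copy()
            st.reseed(child)
        else:
            st = new_state(config)
            st.reseed(child)
        df, _ = run_simulation(config, duration, initial_state=st)
        runs.append(df.set_index("time_h"))
    aligned = pd.concat(runs, keys=range(n_runs))
    mean = aligned.groupby(level=1).mean()
    sd = aligned.groupby(level=1).std(ddof=0)
    return mean.reset_index(), sd.reset_index(), [r.reset_index() for r in runs]
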