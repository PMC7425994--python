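"""Cell-cycle model: doubling times, oxygen-dependent G1 delay, division."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spheroidca.cells import (
    CellAgent,
    CellState,
    CycleParameters,
    GrowthMode,
    advance_cell,
    cycle_length,
    divide,
    g1_delay_factor,
    phase_durations,
    phase_from_clock,
    sample_doubling_time,
    update_proliferative_state,
)
from spheroidca.lattice import LatticeGrid

PARAMS = CycleParameters()


def test_phase_fractions_sum_to_one():
    assert sum(PARAMS.theta) == pytest.approx(1.0, abs=1e-15)
    assert CycleParameters(theta=(0.5, 0.3, 0.1, 0.2)).validate()


class TestDoublingTime:
    def test_zero_sigma_is_deterministic(self, rng):
        assert all(sample_doubling_time(CycleParameters(sigma=0.0), rng) == 40.0
                   for _ in range(5))

    def test_moments_recovered_at_large_n(self, rng):
        draws = np.array([sample_doubling_time(PARAMS, rng) for _ in range(100_000)])
        # 3-4 SE around the configured normal moments
        assert abs(draws.mean() - 40.0) < 0.05
        assert abs(draws.std(ddof=1) - 4.0) < 0.05
        assert (draws > 0).all()


class TestG1DelayFactor:
    @pytest.mark.parametrize(
        "pO2,expected",
        [
            (0.0, 2.0),
            (0.5, 2.0),
            (20.0, 1.0),
            (1.0, 0.9209 + 0.82 / 0.7611),
            (10.5, 0.9209 + 0.82 / (-0.2389 + 10.5)),
        ],
    )
    def test_branch_values(self, pO2, expected):
        assert g1_delay_factor(pO2, PARAMS) == pytest.approx(expected, rel=1e-9)

    def test_negative_oxygen_rejected(self):
        with pytest.raises(ValueError):
            g1_delay_factor(-0.1, PARAMS)

    def test_bounded_and_nonincreasing(self):
        grid = np.linspace(0, 60, 2001)
        vals = g1_delay_factor(grid, PARAMS)
        assert ((vals >= 1.0 - 1e-12) & (vals <= 2.0)).all()
        mid = (grid >= 1.0) & (grid <= 10.5)
        assert (np.diff(vals[mid]) <= 1e-12).all()

    def test_near_continuity_at_breakpoints(self):
        # the empirical fit meets its constant branches within 2e-3
        assert abs(g1_delay_factor(1.0, PARAMS) - 2.0) < 2e-3
        assert abs(g1_delay_factor(10.5, PARAMS) - 1.0) < 2e-3


class TestPhaseDurations:
    def test_normoxic_partition_of_doubling_time(self):
        g1, s, g2, m = phase_durations(40.0, 1.0, PARAMS)
        assert g1 == pytest.approx(11 / 24 * 40)
        assert s == pytest.approx(8 / 24 * 40)
        assert g2 == pytest.approx(4 / 24 * 40)
        assert m == pytest.approx(1 / 24 * 40)
        assert g1 + s + g2 + m == pytest.approx(40.0)

    def test_hypoxic_delay_extends_only_g1(self):
        g1, s, g2, m = phase_durations(40.0, 2.0, PARAMS)
        assert g1 == pytest.approx(2 * 11 / 24 * 40)
        assert (s, g2, m) == pytest.approx((8 / 24 * 40, 4 / 24 * 40, 1 / 24 * 40))
        assert g1 + s + g2 + m == pytest.approx(cycle_length(40.0, 2.0, PARAMS))

    @given(tau=st.floats(1.0, 200.0), g1df=st.floats(1.0, 2.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_durations_sum_to_cycle_length(self, tau, g1df):
        assert sum(phase_durations(tau, g1df, PARAMS)) == pytest.approx(
            cycle_length(tau, g1df, PARAMS), rel=1e-12)

    def test_phase_code_follows_clock(self):
        tau = 24.0
        assert phase_from_clock(0.0, tau, 1.0, PARAMS) == 0  # G1
        assert phase_from_clock(12.0, tau, 1.0, PARAMS) == 1  # S
        assert phase_from_clock(20.0, tau, 1.0, PARAMS) == 2  # G2
        assert phase_from_clock(23.5, tau, 1.0, PARAMS) == 3  # M


class TestAdvanceCell:
    def test_cycling_cell_reaches_division_readiness(self):
        cell = CellAgent(position=(0, 0, 0), tau=40.0, clock=39.95)
        cell, ready = advance_cell(cell, 0.1, 100.0, GrowthMode.IN_VITRO, PARAMS)
        assert ready

    def test_quiescent_clock_frozen_in_vivo(self):
        cell = CellAgent(position=(0, 0, 0), tau=40.0, clock=5.0,
                         state=CellState.QUIESCENT_G0)
        cell, ready = advance_cell(cell, 1.0, 100.0, GrowthMode.IN_VIVO, PARAMS)
        assert cell.clock == 5.0 and not ready

    def test_slow_cycling_advances_at_reduced_rate(self):
        cell = CellAgent(position=(0, 0, 0), tau=40.0, clock=5.0,
                         state=CellState.SLOW_CYCLING)
        cell, _ = advance_cell(cell, 1.0, 100.0, GrowthMode.IN_VITRO, PARAMS)
        assert cell.clock == pytest.approx(5.0 + PARAMS.slow_cycle_factor)

    def test_dying_cell_rejected(self):
        cell = CellAgent(position=(0, 0, 0), tau=40.0, viable=False)
        with pytest.raises(ValueError):
            advance_cell(cell, 0.1, 100.0, GrowthMode.IN_VITRO, PARAMS)


class TestDivision:
    def test_daughter_starts_fresh_in_g1(self, rng):
        grid = LatticeGrid((5, 5, 5))
        mother = CellAgent(position=(2, 2, 2), tau=40.0, clock=40.0)
        grid.occupancy[2, 2, 2] = 0
        daughter = divide(mother, (2, 2, 3), grid, PARAMS, rng)
        assert daughter.clock == 0.0
        assert phase_from_clock(daughter.clock, daughter.tau, 1.0, PARAMS) == 0
        assert mother.clock == 0.0

    def test_occupied_site_rejected(self, rng):
        grid = LatticeGrid((5, 5, 5))
        grid.occupancy[2, 2, 3] = 7
        mother = CellAgent(position=(2, 2, 2), tau=40.0)
        with pytest.raises(ValueError):
            divide(mother, (2, 2, 3), grid, PARAMS, rng)

    def test_daughter_tau_independent_of_mother(self, rng):
        grid = LatticeGrid((5, 5, 5))
        taus_m, taus_d = [], []
        for _ in range(10_000):
            grid.occupancy[:] = -1
            mother = CellAgent(position=(2, 2, 2),
                               tau=sample_doubling_time(PARAMS, rng))
            daughter = divide(mother, (2, 2, 3), grid, PARAMS, rng)
            taus_m.append(mother.tau)
            taus_d.append(daughter.tau)
        corr = np.corrcoef(taus_m, taus_d)[0, 1]
        assert abs(corr) < 0.05


class TestProliferativeState:
    def _enclosed_grid(self):
        grid = LatticeGrid((11, 11, 11))
        grid.occupancy[2:9, 2:9, 2:9] = 1  # Chebyshev ball radius 3 around centre
        return grid

    def test_enclosed_ready_cell_rests(self):
        grid = self._enclosed_grid()
        cell = CellAgent(position=(5, 5, 5), tau=40.0, clock=40.0)
        vivo = update_proliferative_state(cell, grid, 3, GrowthMode.IN_VIVO,
                                          division_ready=True)
        vitro = update_proliferative_state(cell, grid, 3, GrowthMode.IN_VITRO,
                                           division_ready=True)
        assert vivo.state is CellState.QUIESCENT_G0
        assert vitro.state is CellState.SLOW_CYCLING

    def test_resting_cell_resumes_when_space_frees(self):
        grid = self._enclosed_grid()
        grid.occupancy[5, 5, 7] = -1  # treatment freed a voxel two steps away
        cell = CellAgent(position=(5, 5, 5), tau=40.0, state=CellState.QUIESCENT_G0)
        out = update_proliferative_state(cell, grid, 3, GrowthMode.IN_VIVO)
        assert out.state is CellState.CYCLING

    def test_surface_cell_keeps_cycling(self):
        grid = LatticeGrid((11, 11, 11))
        grid.occupancy[5, 5, 5] = 0
        cell = CellAgent(position=(5, 5, 5), tau=40.0, clock=40.0)
        out = update_proliferative_state(cell, grid, 3, GrowthMode.IN_VITRO,
                                         division_ready=True)
        assert out.state is CellState.CYCLING
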