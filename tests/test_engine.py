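"""Treatment engine: determinism, event handling, oxygen scaling, replicates."""

import numpy as np
import pytest

from spheroidca.config import ScheduleEvent, SimulationConfig, TreatmentSchedule, ConfigError
from spheroidca.drugs import RemovalPolicy
from spheroidca.engine import (
    new_state,
    run_replicates,
    run_simulation,
    scale_oxygen_landscape,
)
from spheroidca.reference import grow_reference_spheroid, reduced_config


def tiny_config(seed=0, **overrides):
    return reduced_config(seed=seed, dims=(24, 24, 24), output_every=5.0, **overrides)


@pytest.fixture(scope="module")
def tiny_spheroid():
    return grow_reference_spheroid(tiny_config(seed=11), 250)


def _treated(snapshot, events, duration, seed=0):
    import copy
    st = snapshot.copy()
    st.config = copy.deepcopy(snapshot.config)
    st.config.schedule = TreatmentSchedule(events)
    st.reseed(seed)
    return run_simulation(st.config, duration, initial_state=st)


class TestDeterminism:
    def test_same_seed_is_bit_identical(self):
        runs = []
        for _ in range(2):
            cfg = tiny_config(seed=42)
            df, state = run_simulation(cfg, 150.0)
            runs.append((df, state))
        df0, st0 = runs[0]
        df1, st1 = runs[1]
        assert df0.equals(df1)
        assert np.array_equal(st0.pop.view("pos"), st1.pop.view("pos"))
        assert np.array_equal(st0.pop.view("tau"), st1.pop.view("tau"))
        assert np.array_equal(st0.K, st1.K)

    def test_growth_from_single_seed(self):
        cfg = tiny_config(seed=7)
        df, state = run_simulation(cfg, 120.0)
        assert state.n_viable() > 4  # a few doublings in 120 h
        assert df["n_G1"].iloc[0] == 1  # the seeding cell starts in G1
        counts = df[["n_G1", "n_S", "n_G2", "n_M", "n_SNP"]].sum(axis=1)
        assert (counts.diff().dropna() >= 0).all()


class TestEvents:
    def test_ir_event_drops_viable_count(self, tiny_spheroid):
        _, st = _treated(tiny_spheroid, [ScheduleEvent(0.0, "IR", 2.0)], 1.0)
        ev = st.event_log[0]
        assert ev["viable_after"] < ev["viable_before"]
        assert st.n_viable() < tiny_spheroid.n_viable()

    def test_zero_dose_ir_is_a_noop(self, tiny_spheroid):
        _, st = _treated(tiny_spheroid, [ScheduleEvent(0.0, "IR", 0.0)], 1.0)
        ev = st.event_log[0]
        assert ev["viable_after"] == ev["viable_before"]

    def test_viable_count_never_increases_at_a_dose(self, tiny_spheroid):
        _, st = _treated(tiny_spheroid,
                         [ScheduleEvent(0.0, "IR", 2.0), ScheduleEvent(4.0, "IR", 2.0)],
                         6.0)
        for ev in st.event_log:
            assert ev["viable_after"] <= ev["viable_before"]

    def test_simultaneous_events_fire_in_schedule_order(self, tiny_spheroid):
        _, st = _treated(tiny_spheroid,
                         [ScheduleEvent(0.0, "IR", 2.0),
                          ScheduleEvent(0.0, "HAP", 5.0, 1.0)], 1.0)
        assert [e["modality"] for e in st.event_log] == ["IR", "HAP"]

    def test_overlapping_hap_doses_superpose(self, tiny_spheroid):
        _, st1 = _treated(tiny_spheroid, [ScheduleEvent(0.0, "HAP", 10.0, 1.0)], 0.5)
        _, st2 = _treated(tiny_spheroid, [ScheduleEvent(0.0, "HAP", 10.0, 1.0),
                                          ScheduleEvent(0.0, "HAP", 10.0, 1.0)], 0.5)
        assert st2.HAP.max() == pytest.approx(2 * st1.HAP.max(), rel=1e-9)

    def test_unknown_modality_rejected(self, tiny_spheroid):
        with pytest.raises(ConfigError):
            _treated(tiny_spheroid, [ScheduleEvent(0.0, "XRAY", 2.0)], 1.0)


class TestRemovalPolicies:
    def _kill_everything(self, snapshot, policy, duration):
        import copy
        st = snapshot.copy()
        st.config = copy.deepcopy(snapshot.config)
        st.config.drugs.removal_policy = policy
        st.config.schedule = TreatmentSchedule([ScheduleEvent(0.0, "IR", 50.0)])
        st.reseed(0)
        _, out = run_simulation(st.config, duration, initial_state=st)
        return out

    def test_never_removed_cells_persist_as_obstacles(self, tiny_spheroid):
        st = self._kill_everything(tiny_spheroid, RemovalPolicy.NEVER, 5.0)
        dying = st.pop.view("present") & st.pop.view("dying")
        assert dying.sum() > 0
        assert st.occupied().sum() == st.pop.view("present").sum()

    def test_instantaneous_removal_frees_voxels(self, tiny_spheroid):
        st = self._kill_everything(tiny_spheroid, RemovalPolicy.INSTANTANEOUS, 5.0)
        gone = st.pop.view("dying") & ~st.pop.view("present")
        assert gone.sum() > 0
        assert st.occupied().sum() == st.pop.view("present").sum()

    def test_doubling_time_removal_waits_tau(self, tiny_spheroid):
        st = self._kill_everything(tiny_spheroid, RemovalPolicy.DOUBLING_TIME, 5.0)
        # after 5 h nobody with tau ~ 40 h should be removed yet
        assert (~st.pop.view("present") & st.pop.view("dying")).sum() == 0
        st2 = self._kill_everything(tiny_spheroid, RemovalPolicy.DOUBLING_TIME, 60.0)
        removed = st2.pop.view("dying") & ~st2.pop.view("present")
        assert removed.sum() > 0


class TestOxygenScaling:
    def test_identity_and_pointwise_product(self, tiny_spheroid):
        st = tiny_spheroid.copy()
        base = st.khat_effective().copy()
        scale_oxygen_landscape(st, 0.25)
        assert np.allclose(st.khat_effective(), 0.25 * base)
        with pytest.raises(ValueError):
            scale_oxygen_landscape(st, 0.0)

    def test_hypoxic_fraction_monotone_in_scale(self, tiny_spheroid):
        fracs = []
        for f in (1.0, 0.5, 0.25):
            st = tiny_spheroid.copy()
            scale_oxygen_landscape(st, f)
            fracs.append(st.summary_row()["hypoxic_fraction"])
        assert fracs[0] <= fracs[1] <= fracs[2]


class TestReplicates:
    def test_single_run_has_zero_sd(self, tiny_spheroid):
        mean, sd, runs = run_replicates(tiny_spheroid.config, 10.0, n_runs=1,
                                        initial_state=tiny_spheroid)
        assert len(runs) == 1
        assert (sd.drop(columns="time_h").to_numpy() == 0).all()
        assert np.allclose(mean["n_G1"], runs[0]["n_G1"])

    def test_replicates_differ_but_agree_on_average(self, tiny_spheroid):
        import copy
        cfg = copy.deepcopy(tiny_spheroid.config)
        cfg.schedule = TreatmentSchedule([ScheduleEvent(0.0, "IR", 2.0)])
        cfg.output_every = 0.5
        mean, sd, runs = run_replicates(cfg, 2.0, n_runs=4,
                                        initial_state=tiny_spheroid)
        finals = [r["n_dying"].iloc[-1] for r in runs]
        assert len(set(finals)) > 1  # independent Bernoulli draws
        assert mean["n_dying"].iloc[-1] == pytest.approx(np.mean(finals))

    def test_relative_spread_shrinks_with_population_size(self, tiny_spheroid, large):
        """Replicate noise on the post-IR viable count scales ~ N^(-1/2)."""
        import copy
        rel = {}
        for name, snap in (("small", tiny_spheroid), ("large", large)):
            cfg = copy.deepcopy(snap.config)
            cfg.schedule = TreatmentSchedule([ScheduleEvent(0.0, "IR", 2.0)])
            cfg.seed = 99
            cfg.output_every = 0.5
            mean, sd, _ = run_replicates(cfg, 1.0, n_runs=6, initial_state=snap)
            rel[name] = sd["n_dying"].iloc[-1] / mean["n_dying"].iloc[-1]
        # ~250 vs ~19000 cells: expect roughly sqrt(76) ~ 9x tighter
        assert rel["large"] < rel["small"] / 2
        assert rel["large"] < 0.05


def test_invalid_config_lists_offending_fields():
    cfg = SimulationConfig(dt=-1, nu=0, oxygen_scale_factor=2.0)
    with pytest.raises(ConfigError) as err:
        cfg.validate()
    msg = str(err.value)
    assert "dt" in msg and "nu" in msg and "oxygen_scale_factor" in msg
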