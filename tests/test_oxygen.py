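"""Oxygen field: conservation, steady states, scaling and hypoxia."""

import numpy as np
import pytest

from spheroidca.oxygen import (
    OxygenParameters,
    classify_hypoxic,
    hypoxic_fraction,
    oxygen_histogram,
    scaled_oxygen,
    solve_oxygen_steady,
    step_oxygen,
)
from spheroidca import pde


def _no_masks(shape):
    return np.zeros(shape, dtype=bool), np.zeros(shape, dtype=bool)


class TestExplicitStepper:
    def test_uniform_field_unchanged_by_diffusion(self):
        shape = (8, 8, 8)
        occupied, consuming = _no_masks(shape)
        params = OxygenParameters(r_K=0.0, phi_K=0.0)
        K = np.full(shape, 3.5)
        out = step_oxygen(K, occupied, consuming, np.zeros(shape, bool), params, 1e-3)
        assert np.allclose(out, 3.5, rtol=1e-13)

    def test_mass_conserved_without_reactions(self, rng):
        """No-flux diffusion alone conserves the field total to 1e-10."""
        shape = (12, 12, 12)
        occupied = rng.random(shape) < 0.4  # heterogeneous diffusivity
        consuming = np.zeros(shape, bool)
        params = OxygenParameters(r_K=0.0, phi_K=0.0, D_K_cm2_s=1e-8)
        K = rng.random(shape)
        out = step_oxygen(K, occupied, consuming, np.zeros(shape, bool), params, 0.5)
        assert abs(out.sum() - K.sum()) / K.sum() < 1e-10

    def test_pure_source_grows_uniformly_at_rate_r(self):
        shape = (6, 6, 6)
        occupied, consuming = _no_masks(shape)
        params = OxygenParameters(r_K=2.0, phi_K=0.0, D_K_cm2_s=1e-9)
        K = np.zeros(shape)
        dt = 0.25
        out = step_oxygen(K, occupied, consuming, np.ones(shape, bool), params, dt)
        assert np.allclose(out, params.r_K * dt, rtol=1e-10)

    def test_field_stays_nonnegative_with_strong_sinks(self):
        shape = (6, 6, 6)
        occupied = np.ones(shape, bool)
        params = OxygenParameters(r_K=0.0, phi_K=50.0, D_K_cm2_s=1e-8)
        K = np.full(shape, 1.0)
        out = step_oxygen(K, occupied, occupied, np.zeros(shape, bool), params, 1.0)
        assert (out >= 0).all()

    def test_substep_cap_raises_stability_error(self):
        shape = (6, 6, 6)
        occupied, consuming = _no_masks(shape)
        params = OxygenParameters()  # physical D -> huge sub-step count
        with pytest.raises(pde.StabilityError):
            step_oxygen(np.ones(shape), occupied, consuming, np.zeros(shape, bool),
                        params, 1.0, max_substeps=10)


class TestQuasiSteady:
    def test_column_profile_matches_closed_form(self):
        """A consuming half-column decays as cosh toward the sealed end.

        The discrete quasi-steady solution on a 4x-refined 1D column is
        compared with the separation-of-variables profile
        K(x) = K(a) cosh(kappa (L - x)) / cosh(kappa (L - a)) inside the
        tissue; agreement within 1% (L-infinity, relative to the interface
        value) is required.
        """
        n, refine = 60, 4
        nf = n * refine
        a = nf // 2
        D_in, phi = 4.0, 0.02  # fine-voxel units; kappa * dx ~ 0.07
        occupied = np.zeros((nf, 1, 1), bool)
        occupied[a:] = True
        exterior = ~occupied
        D = np.where(occupied, D_in, D_in * 1.5)
        sink = np.where(occupied, phi, 0.0)
        source = np.where(exterior, 1.0, 0.0)
        K = pde.steady_state(D, sink, source.astype(float)).ravel()
        kappa = np.sqrt(phi / D_in)
        x = np.arange(nf, dtype=float)
        analytic = K[a] * np.cosh(kappa * (nf - 1 - x[a:])) / np.cosh(kappa * (nf - 1 - a))
        err = np.max(np.abs(K[a:] - analytic)) / K[a]
        assert err < 0.01

    def test_requires_a_sink(self):
        shape = (6, 6, 6)
        occupied, consuming = _no_masks(shape)
        with pytest.raises(ValueError):
            solve_oxygen_steady(occupied, consuming, np.ones(shape, bool),
                                OxygenParameters())

    def test_centred_cell_ball_is_hypoxic_at_core(self):
        """Sinks inside, sources outside: minimum at the centre, radially monotone."""
        shape = (24, 24, 24)
        x, y, z = np.indices(shape)
        r = np.sqrt((x - 11.5) ** 2 + (y - 11.5) ** 2 + (z - 11.5) ** 2)
        occupied = r < 8
        params = OxygenParameters(phi_K=8000.0)
        K = solve_oxygen_steady(occupied, occupied, ~occupied, params)
        khat = scaled_oxygen(K, 100.0)
        assert khat[12, 12, 12] == pytest.approx(khat.min(), rel=1e-6)
        # monotone along the positive x ray from the centre
        ray = khat[12:, 12, 12]
        assert (np.diff(ray) >= -1e-9).all()
        assert khat[12, 12, 12] < 10.0 < khat[0, 0, 0]


class TestScaling:
    def test_uniform_field_maps_to_ceiling(self):
        K = np.full((4, 4, 4), 0.37)
        assert np.allclose(scaled_oxygen(K, 100.0), 100.0)

    def test_linear_rescale_and_order_preservation(self, rng):
        K = rng.random((5, 5, 5))
        khat = scaled_oxygen(K, 100.0)
        assert np.allclose(khat, K / K.max() * 100.0)
        assert np.unravel_index(khat.argmin(), khat.shape) == \
            np.unravel_index(K.argmin(), K.shape)

    def test_zero_field_rejected(self):
        with pytest.raises(ValueError):
            scaled_oxygen(np.zeros((3, 3, 3)), 100.0)


class TestHypoxiaClassification:
    @pytest.mark.parametrize("pO2,expected", [(10.0, True), (100.0, False),
                                              (1.0, True), (10.001, False)])
    def test_threshold_inclusive(self, pO2, expected):
        assert classify_hypoxic(pO2) is expected

    def test_histogram_counts_conserved(self, rng):
        pO2 = rng.uniform(0, 100, size=500)
        counts = oxygen_histogram(pO2, np.linspace(0, 100, 21))
        assert counts.sum() == 500
        assert hypoxic_fraction(pO2) == pytest.approx(np.mean(pO2 <= 10))
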