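"""Intra-tumoural oxygen: reaction-diffusion field, scaling and hypoxia.

Oxygen K(x,t) obeys dK/dt = div(D_K grad K) + r_K m(x) - phi_K K cell(x)
with no-flux boundaries: every exterior voxel (free space connected to the
domain boundary) is a source, every *viable* cell a sink, and diffusion is
slowed by a factor 1.5 across cell-occupied voxels. Because oxygen
equilibrates orders of magnitude faster than the cell dynamics, runs use
the quasi-steady solution (a direct sparse solve); the explicit time
stepper is kept for solver certification and transients.

The raw field is only defined up to the arbitrary source rate, so all
oxygen-dependent biology consumes the *scaled* field K-hat = K / max(K) *
h_effective (mmHg), where h_effective is the oxygen value assigned to the
best-oxygenated voxel (default 100 mmHg). A cell is hypoxic when its
scaled oxygen is <= 10 mmHg.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import pde

__all__ = [
    "OxygenParameters",
    "step_oxygen",
    "solve_oxygen_steady",
    "scaled_oxygen",
    "classify_hypoxic",
    "hypoxic_fraction",
    "oxygen_histogram",
]

#: physical voxel edge used for unit conversion (matches the lattice default)
VOXEL_UM_DEFAULT = 20.0


def diffusivity_voxel_units(D_cm2_s: float, spacing_um: float) -> float:
    """Convert a diffusion coefficient from cm^2/s to voxel^2/h."""
    dx_cm = spacing_um * 1e-4
    return D_cm2_s * 3600.0 / dx_cm**2


@dataclass
class OxygenParameters:
    """Oxygen-field parameters.

    ``phi_K`` (the cellular consumption rate, h^-1) defaults to the value
    implied by a ~100 um oxygen diffusion length in tissue,
    phi = (D_K / divisor) / L^2; the reference-spheroid calibration routine
    can replace it to hit a target hypoxic fraction. ``r_K`` is arbitrary:
    the scaled field is invariant to it.
    """

    D_K_cm2_s: float = 2.5e-5
    intracellular_divisor: float = 1.5
    r_K: float = 1.0
    phi_K: float | None = None  # h^-1; None -> derived from diffusion_length_um
    diffusion_length_um: float = 100.0
    h_table: float = 0.5  # tabulated scaling factor (mmHg); kept for record
    h_effective: float = 100.0  # mmHg assigned to the lattice maximum
    hypoxia_threshold: float = 10.0  # mmHg

    def D_voxel(self, spacing_um: float = VOXEL_UM_DEFAULT) -> float:
        return diffusivity_voxel_units(self.D_K_cm2_s, spacing_um)

    def phi_voxel(self, spacing_um: float = VOXEL_UM_DEFAULT) -> float:
        if self.phi_K is not None:
            return self.phi_K
        d_in = self.D_voxel(spacing_um) / self.intracellular_divisor
        ell_vox = self.diffusion_length_um / spacing_um
        return d_in / ell_vox**2

    def validate(self) -> list[str]:
        errs = []
        if self.D_K_cm2_s <= 0:
            errs.append("oxygen.D_K_cm2_s must be > 0")
        if self.intracellular_divisor < 1:
            errs.append("oxygen.intracellular_divisor must be >= 1")
        if self.r_K < 0:
            errs.append("oxygen.r_K must be >= 0")
        if self.phi_K is not None and self.phi_K < 0:
            errs.append("oxygen.phi_K must be >= 0")
        if self.h_effective <= 0:
            errs.append("oxygen.h_effective must be > 0")
        return errs


def _diffusivity_field(occupied: np.ndarray, params: OxygenParameters, spacing_um: float):
    D = np.full(occupied.shape, params.D_voxel(spacing_um))
    D[occupied] /= params.intracellular_divisor
    return D


def step_oxygen(
    K: np.ndarray,
    occupied: np.ndarray,
    consuming: np.ndarray,
    exterior: np.ndarray,
    params: OxygenParameters,
    dt: float,
    spacing_um: float = VOXEL_UM_DEFAULT,
    max_substeps: int = 500_000,
) -> np.ndarray:
    """One explicit macro-step of the oxygen PDE.

    ``occupied`` marks voxels holding any cell (slower diffusion);
    ``consuming`` marks viable cells only (dying cells occupy space but no
    longer consume oxygen). Sub-stepped to the stability bound; raises
    :class:`~spheroidca.pde.StabilityError` beyond ``max_substeps``.
    """
    D = _diffusivity_field(occupied, params, spacing_um)
    source = params.r_K * exterior.astype(float)
    sink = params.phi_voxel(spacing_um) * consuming.astype(float)
    return pde.explicit_step(K, D, dt, source=source, sink=sink, max_substeps=max_substeps)


def solve_oxygen_steady(
    occupied: np.ndarray,
    consuming: np.ndarray,
    exterior: np.ndarray,
    params: OxygenParameters,
    spacing_um: float = VOXEL_UM_DEFAULT,
    x0: np.ndarray | None = None,
    rtol: float = 1e-10,
) -> np.ndarray:
    """Quasi-steady oxygen field (direct solve of the linear balance).

    Requires at least one consuming cell (with no sink, the no-flux source
    accumulates without bound and no steady state exists).
    """
    if not np.any(consuming):
        raise ValueError("steady oxygen requires at least one consuming cell")
    D = _diffusivity_field(occupied, params, spacing_um)
    source = params.r_K * exterior.astype(float)
    sink = params.phi_voxel(spacing_um) * consuming.astype(float)
    K = pde.steady_state(D, sink, source, x0=x0, rtol=rtol)
    return np.maximum(K, 0.0)


def scaled_oxygen(K: np.ndarray, h_effective: float) -> np.ndarray:
    """Scale the raw field so its lattice maximum maps to ``h_effective`` mmHg."""
    m = float(np.max(K))
    if m <= 0:
        raise ValueError("cannot scale an all-zero oxygen field")
    return K * (h_effective / m)


def classify_hypoxic(pO2, threshold: float = 10.0):
    """Hypoxia classification: scaled oxygen <= threshold (boundary inclusive)."""
    p = np.asarray(pO2)
    if np.any(p < 0):
        raise ValueError("pO2 must be non-negative")
    out = p <= threshold
    return bool(out) if np.ndim(pO2) == 0 else out


def hypoxic_fraction(pO2_at_cells: np.ndarray, threshold: float = 10.0) -> float:
    if len(pO2_at_cells) == 0:
        return 0.0
    return float(np.mean(classify_hypoxic(pO2_at_cells, threshold)))


def oxygen_histogram(pO2_at_cells: np.ndarray, bin_edges: np.ndarray) -> np.ndarray:
    """Counts of viable cells per oxygenation bin (total = cell count)."""
    counts, _ = np.histogram(pO2_at_cells, bins=bin_edges)
    return counts
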