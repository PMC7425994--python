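"""Hypoxia-activated prodrug (HAP) pharmacology.

The inert prodrug (HAP, modelled on TH-302/evofosfamide) and its activated
cytotoxin (AHAP, Br-IPM) obey coupled reaction-diffusion-decay PDEs on the
lattice. Bioreduction HAP -> AHAP proceeds at rate b * BRF(pO2) where
BRF(p) = [pO2]_50 / ([pO2]_50 + p) is the fraction of prodrug converted
per hour ([pO2]_50 = 0.2 mmHg gives 50% hourly conversion). HAPs
out-diffuse oxygen (D_HAP = 2 D_K) so they reach hypoxic cores; the
cytotoxin is less mobile (D_AHAP = D_K / 4), which localises bystander
damage. First-order decay rates come from the clinical plasma half-lives
(0.81 h and 0.70 h).

Reactions are integrated with the exact per-step exponential solution of
the local linear ODE pair (diffusion/reaction Lie splitting), so the
HAP + AHAP budget is conserved analytically when decay is off and both
fields stay non-negative for any step size.

A viable cell is marked dying once the local AHAP concentration reaches
the lethal threshold Psi; dying cells linger on the lattice for T_L->R
according to the removal policy (never / instantaneous / one doubling
time).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from . import pde
from .oxygen import OxygenParameters, VOXEL_UM_DEFAULT

__all__ = [
    "RemovalPolicy",
    "DrugParameters",
    "bioreduction_factor",
    "activation_rate",
    "decay_rate_from_half_life",
    "DrugStepper",
    "step_drugs",
]


class RemovalPolicy(enum.Enum):
    NEVER = "never"
    INSTANTANEOUS = "instantaneous"
    DOUBLING_TIME = "doubling_time"


def decay_rate_from_half_life(t_half: float) -> float:
    """First-order decay rate ln(2)/t_half (h^-1)."""
    if t_half <= 0:
        raise ValueError("half-life must be positive")
    return float(np.log(2.0) / t_half)


@dataclass
class DrugParameters:
    """HAP/AHAP parameters. Concentrations are in arbitrary units; only the
    ratio of dose to the lethal threshold Psi is meaningful, so Psi is fixed
    at 1 and the dose is calibrated (see the reference-spheroid module).

    The default diffusivity anchoring ("mixed") realises the two defining
    transport properties of this drug class: the inert prodrug is highly
    mobile (D_HAP = 2 D_K with the tabulated oxygen diffusion coefficient,
    so it floods the whole lattice within minutes and reaches hypoxic
    cores), while the activated cytotoxin is short-lived and confined to a
    ~50 um penetration depth around its activation sites (D_AHAP =
    eta_AHAP * L_AHAP^2), which is what makes bystander damage an
    interface effect. Pure anchorings are available too:
    ``anchor="oxygen_table"`` (both diffusivities as tabulated multiples
    of D_K; the cytotoxin then spreads over millimetres and spatial
    selectivity washes out) and ``anchor="lengths"`` (both from nominal
    penetration depths; the prodrug is then attenuated before it reaches
    a spheroid core).
    """

    b: float = 1.0  # bioreduction time-scaling, h^-1
    pO2_50: float = 0.2  # mmHg, half-maximal activation
    D_HAP_ratio: float = 2.0  # x local D_K (tabulated ratio)
    D_AHAP_ratio: float = 0.25  # x local D_K (tabulated ratio)
    diffusion_length_HAP_um: float = 150.0
    diffusion_length_AHAP_um: float = 50.0
    anchor: str = "mixed"  # or "oxygen_table" / "lengths"
    t_half_HAP: float = 0.81  # h
    t_half_AHAP: float = 0.70  # h
    dose_bath: float = 0.0  # in-vitro bath concentration per dose unit
    r_HAP: float = 0.0  # in-vivo exterior source rate per dose unit, h^-1
    dose_duration: float = 2.0  # h, default exposure window
    psi: float = 1.0  # lethal AHAP threshold
    removal_policy: RemovalPolicy = RemovalPolicy.NEVER

    @property
    def eta_HAP(self) -> float:
        return decay_rate_from_half_life(self.t_half_HAP)

    @property
    def eta_AHAP(self) -> float:
        return decay_rate_from_half_life(self.t_half_AHAP)

    def D_voxel(self, oxygen_params, spacing_um: float):
        """(D_HAP, D_AHAP) in voxel^2/h for free (extracellular) space."""
        if self.anchor == "mixed":
            d_hap = self.D_HAP_ratio * oxygen_params.D_voxel(spacing_um)
            d_ahap = self.eta_AHAP * (self.diffusion_length_AHAP_um / spacing_um) ** 2
        elif self.anchor == "lengths":
            d_hap = self.eta_HAP * (self.diffusion_length_HAP_um / spacing_um) ** 2
            d_ahap = self.eta_AHAP * (self.diffusion_length_AHAP_um / spacing_um) ** 2
        elif self.anchor == "oxygen_table":
            base = oxygen_params.D_voxel(spacing_um)
            d_hap = self.D_HAP_ratio * base
            d_ahap = self.D_AHAP_ratio * base
        else:
            raise ValueError(f"unknown diffusivity anchor {self.anchor!r}")
        return d_hap, d_ahap

    def validate(self) -> list[str]:
        errs = []
        if self.b < 0:
            errs.append("drugs.b must be >= 0")
        if self.pO2_50 <= 0:
            errs.append("drugs.pO2_50 must be > 0")
        if self.t_half_HAP <= 0 or self.t_half_AHAP <= 0:
            errs.append("drugs.t_half_* must be > 0")
        if self.psi <= 0:
            errs.append("drugs.psi must be > 0")
        if self.D_HAP_ratio <= self.D_AHAP_ratio:
            errs.append("drugs.D_HAP_ratio must exceed D_AHAP_ratio "
                        "(prodrug out-diffuses the cytotoxin)")
        if self.dose_duration <= 0:
            errs.append("drugs.dose_duration must be > 0")
        return errs


def bioreduction_factor(pO2, pO2_50: float = 0.2):
    """Fraction of HAP converting to AHAP per hour at the given oxygenation."""
    p = np.asarray(pO2, dtype=float)
    if np.any(p < 0):
        raise ValueError("pO2 must be non-negative")
    out = pO2_50 / (pO2_50 + p)
    return float(out) if np.ndim(pO2) == 0 else out


def activation_rate(pO2, params: DrugParameters):
    """HAP -> AHAP conversion rate b * BRF(pO2), h^-1."""
    return params.b * bioreduction_factor(pO2, params.pO2_50)


def _exact_reaction(H, A, f, eta_h, eta_a, dt):
    """Exact step of dH/dt = -(f+eta_h)H ; dA/dt = fH - eta_a A."""
    a = f + eta_h
    eH = np.exp(-a * dt)
    eA = np.exp(-eta_a * dt)
    H_new = H * eH
    denom = a - eta_a
    small = np.abs(denom) < 1e-12
    with np.errstate(divide="ignore", invalid="ignore"):
        transfer = f * H * (eA - eH) / denom
    if np.any(small):
        # degenerate a ~= eta_a limit: f H t e^{-a t}
        limit = f * H * dt * eH
        transfer = np.where(small, limit, transfer)
    A_new = A * eA + transfer
    return H_new, A_new


class DrugStepper:
    """Time stepper for the coupled HAP/AHAP fields on a frozen geometry.

    Caches the implicit diffusion operators; rebuild (a new instance)
    whenever occupancy or the macro-step changes. ``method`` selects the
    backward-Euler solver ("implicit", production default) or the
    sub-stepped explicit scheme ("explicit", small grids only).
    """

    def __init__(
        self,
        occupied: np.ndarray,
        exterior: np.ndarray,
        params: DrugParameters,
        oxygen_params: OxygenParameters,
        dt: float,
        spacing_um: float = VOXEL_UM_DEFAULT,
        method: str = "implicit",
    ):
        self.params = params
        self.exterior = exterior
        self.dt = float(dt)
        self.method = method
        d_hap, d_ahap = params.D_voxel(oxygen_params, spacing_um)
        self.D_hap = np.full(occupied.shape, d_hap)
        self.D_ahap = np.full(occupied.shape, d_ahap)
        # cell-occupied voxels slow diffusion, as for oxygen
        self.D_hap[occupied] /= oxygen_params.intracellular_divisor
        self.D_ahap[occupied] /= oxygen_params.intracellular_divisor
        if method == "implicit":
            self._imp_h = pde.ImplicitDiffusion(self.D_hap, dt)
            self._imp_a = pde.ImplicitDiffusion(self.D_ahap, dt)

    def step(self, HAP, AHAP, pO2_field, dosing_rate: float = 0.0, bath: float | None = None):
        """Advance both fields by one macro-step ``dt``.

        ``bath`` (in-vitro dosing): hold exterior voxels at this HAP
        concentration. ``dosing_rate`` (in-vivo dosing): exterior HAP source
        term, concentration/h. Returns new (HAP, AHAP).
        """
        p = self.params
        if bath is not None:
            HAP = HAP.copy()
            HAP[self.exterior] = bath
        if dosing_rate:
            HAP = HAP + (dosing_rate * self.dt) * self.exterior
        if self.method == "implicit":
            HAP = self._imp_h.step(HAP)
            AHAP = self._imp_a.step(AHAP)
        else:
            HAP = pde.explicit_step(HAP, self.D_hap, self.dt)
            AHAP = pde.explicit_step(AHAP, self.D_ahap, self.dt)
        f = activation_rate(pO2_field, p)
        HAP, AHAP = _exact_reaction(HAP, AHAP, f, p.eta_HAP, p.eta_AHAP, self.dt)
        return np.maximum(HAP, 0.0), np.maximum(AHAP, 0.0)


def step_drugs(
    HAP: np.ndarray,
    AHAP: np.ndarray,
    pO2_field: np.ndarray,
    occupied: np.ndarray,
    exterior: np.ndarray,
    params: DrugParameters,
    oxygen_params: OxygenParameters,
    dt: float,
    dosing_active: bool = False,
    mode: str = "in_vitro",
    spacing_um: float = VOXEL_UM_DEFAULT,
    method: str = "implicit",
):
    """Single-shot convenience wrapper around :class:`DrugStepper`."""
    stepper = DrugStepper(occupied, exterior, params, oxygen_params, dt,
                          spacing_um=spacing_um, method=method)
    bath = params.dose_bath if (dosing_active and mode == "in_vitro") else None
    rate = params.r_HAP if (dosing_active and mode == "in_vivo") else 0.0
    return stepper.step(HAP, AHAP, pO2_field, dosing_rate=rate, bath=bath)
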