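"""Independent reference implementations used to certify the solvers.

Everything here is deliberately naive — dense loops, closed forms, direct
formula evaluation — and shares no code with the production kernels it
checks. The test suite compares production output against these oracles;
they are not used by simulations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "OracleCase",
    "diffusion_oracle_1d",
    "cosine_mode_amplitude",
    "decay_oracle",
    "survival_cohort_oracle",
    "enumerate_shell",
    "kernel_reference_cases",
]


@dataclass
class OracleCase:
    """One frozen kernel check: inputs, independently computed expectation,
    and the tolerance budget it must meet."""

    description: str
    func: str
    args: tuple
    expected: float
    rtol: float = 1e-12


def diffusion_oracle_1d(D: float, profile: np.ndarray, t: float, refine: int = 4) -> np.ndarray:
    """Reference 1D no-flux diffusion: dense explicit integration, refined grid.

    The coarse profile is prolonged onto a ``refine``-times finer grid
    (piecewise constant), integrated with a tiny stable step, and restricted
    back by averaging. D is in (coarse-voxel)^2 per unit time.
    """
    n = len(profile)
    fine = np.repeat(np.asarray(profile, dtype=float), refine)
    Df = D * refine**2  # fine-cell units
    dt = 0.2 / (2.0 * Df)
    steps = max(1, int(np.ceil(t / dt)))
    dt = t / steps
    f = fine.copy()
    for _ in range(steps):
        lap = np.zeros_like(f)
        lap[1:-1] = f[2:] - 2 * f[1:-1] + f[:-2]
        lap[0] = f[1] - f[0]
        lap[-1] = f[-2] - f[-1]
        f = f + Df * dt * lap
    return f.reshape(n, refine).mean(axis=1)


def cosine_mode_amplitude(D: float, k: float, t: float) -> float:
    """Amplitude decay factor exp(-D k^2 t) of a cosine eigenmode under
    no-flux boundaries (separation of variables)."""
    return float(np.exp(-D * k**2 * t))


def decay_oracle(c0: float, eta: float, t: float) -> float:
    """First-order decay closed form c0 * exp(-eta t)."""
    if eta < 0:
        raise ValueError("eta must be >= 0")
    return float(c0 * np.exp(-eta * t))


def survival_cohort_oracle(survival_prob: float, n: int, confidence: float = 0.99):
    """Expected survivors and a binomial CI for an irradiated cohort."""
    if not 0 <= survival_prob <= 1:
        raise ValueError("survival_prob must be a probability")
    mean = n * survival_prob
    if survival_prob in (0.0, 1.0):
        return mean, (mean, mean)
    lo, hi = stats.binom.interval(confidence, n, survival_prob)
    return mean, (float(lo), float(hi))


def enumerate_shell(center, dims, topology: str, order: int) -> set:
    """Brute-force shell enumeration by scanning every voxel of the lattice."""
    cx, cy, cz = center
    out = set()
    for x in range(dims[0]):
        for y in range(dims[1]):
            for z in range(dims[2]):
                dx, dy, dz = abs(x - cx), abs(y - cy), abs(z - cz)
                dist = max(dx, dy, dz) if topology == "moore" else dx + dy + dz
                if dist == order:
                    out.add((x, y, z))
    return out


def kernel_reference_cases() -> list[OracleCase]:
    """Direct-formula evaluations of every scalar kernel (>= 20 cases).

    Expected values are computed here with plain arithmetic, independent of
    the production modules.
    """
    cases = []
    # G1 delay factor: 2 below 1 mmHg; a1 + a2/(a3+p) on [1, 10.5]; 1 above
    a1, a2, a3 = 0.9209, 0.8200, -0.2389
    for p in (0.0, 0.5, 0.999):
        cases.append(OracleCase(f"G1DF anoxic branch p={p}", "g1df", (p,), 2.0))
    for p in (1.0, 2.0, 5.0, 10.5):
        cases.append(OracleCase(f"G1DF fit branch p={p}", "g1df", (p,), a1 + a2 / (a3 + p)))
    for p in (10.6, 20.0, 100.0):
        cases.append(OracleCase(f"G1DF normoxic p={p}", "g1df", (p,), 1.0))
    # bioreduction factor
    for p in (0.0, 0.2, 1.0, 9.8, 100.0):
        cases.append(OracleCase(f"BRF p={p}", "brf", (p,), 0.2 / (0.2 + p)))
    # oxygen enhancement ratio / modification factor (OER_m=3, K_m=3)
    for p in (0.0, 3.0, 10.0, 1e6):
        cases.append(OracleCase(f"OER p={p}", "oer", (p,), (3 * p + 3) / (p + 3)))
        cases.append(OracleCase(f"OMF p={p}", "omf", (p,), (3 * p + 3) / (p + 3) / 3))
    # LQ survival, well-oxygenated (OMF ~ 1 at p = 1e6) and anoxic (OMF = 1/3)
    table = {"G1": (0.351, 0.04), "S": (0.1235, 0.04), "G2": (0.793, 0.0)}
    for phase, (al, be) in table.items():
        omf_hi = (3e6 + 3) / (1e6 + 3) / 3
        cases.append(OracleCase(
            f"LQ survival {phase} 2 Gy normoxic", "survival", (phase, 1e6, 2.0),
            np.exp(-2 * (omf_hi * al + 2 * omf_hi**2 * be)), rtol=1e-9))
        cases.append(OracleCase(
            f"LQ survival {phase} 2 Gy anoxic", "survival", (phase, 0.0, 2.0),
            np.exp(-2 * (al / 3 + 2 * be / 9))))
    # decay rates
    for th in (0.81, 0.70, 1.0):
        cases.append(OracleCase(f"decay rate t1/2={th}", "decay_rate", (th,),
                                np.log(2.0) / th))
    return cases
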