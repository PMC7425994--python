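"""Finite-difference kernels shared by the oxygen and drug fields.

All fields live on the cell-automaton lattice. Internally lengths are in
voxel units and time in hours, so a physical diffusion coefficient D
(cm^2/s) becomes ``D * 3600 / dx_cm**2`` voxel^2/h. No-flux (homogeneous
Neumann) boundaries are built into every operator, and the spatially
varying diffusivity (slower across cell-occupied voxels) enters through
harmonic-mean face values, which keeps the discrete operator symmetric and
exactly conservative.

Two steppers are provided:

* an explicit, flux-form FTCS scheme with automatic sub-stepping to the
  stability bound dt <= 1/(6 max D + max sink) — simple, exactly
  mass-conserving, used for solver certification and small test grids;
* a backward-Euler scheme (conjugate-gradient solve of the SPD system
  ``(I + dt L) x = b``) for production runs, where the physical diffusion
  number per macro-step is in the thousands and explicit sub-stepping is
  not a usable option.

Steady states (quasi-equilibrated oxygen) are computed directly from the
linear system ``(L + diag(sink)) x = source``.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import cg

__all__ = [
    "StabilityError",
    "face_diffusivities",
    "explicit_step",
    "diffusion_matrix",
    "ImplicitDiffusion",
    "steady_state",
]


class StabilityError(RuntimeError):
    """Raised when the explicit stepper would need more sub-steps than allowed."""

    def __init__(self, needed: int, allowed: int):
        super().__init__(
            f"explicit diffusion step requires {needed} sub-steps "
            f"(cap {allowed}); use the implicit stepper or a smaller macro-step"
        )
        self.needed = needed
        self.allowed = allowed


def face_diffusivities(D: np.ndarray):
    """Harmonic-mean diffusivity on the faces between adjacent voxels."""
    D = np.asarray(D, dtype=float)

    def h(a, b):
        s = a + b
        out = np.zeros_like(a)
        np.divide(2.0 * a * b, s, out=out, where=s > 0)
        return out

    wx = h(D[:-1, :, :], D[1:, :, :])
    wy = h(D[:, :-1, :], D[:, 1:, :])
    wz = h(D[:, :, :-1], D[:, :, 1:])
    return wx, wy, wz


def _apply_div_flux(field, wx, wy, wz, out):
    """out += div(D grad field), flux form (exactly conservative, no-flux)."""
    fx = wx * (field[1:, :, :] - field[:-1, :, :])
    fy = wy * (field[:, 1:, :] - field[:, :-1, :])
    fz = wz * (field[:, :, 1:] - field[:, :, :-1])
    out[:-1, :, :] += fx
    out[1:, :, :] -= fx
    out[:, :-1, :] += fy
    out[:, 1:, :] -= fy
    out[:, :, :-1] += fz
    out[:, :, 1:] -= fz
    return out


def explicit_step(
    field: np.ndarray,
    D: np.ndarray,
    dt: float,
    source: np.ndarray | float = 0.0,
    sink: np.ndarray | float = 0.0,
    max_substeps: int = 500_000,
) -> np.ndarray:
    """One macro-step of ``df/dt = div(D grad f) + source - sink * f``.

    Sub-steps internally to satisfy the explicit stability bound. ``sink``
    is a (non-negative) linear reaction-rate field; ``source`` a production
    field. Returns a new array; the input is not modified.
    """
    field = np.asarray(field, dtype=float)
    maxD = float(np.max(D)) if np.ndim(D) else float(D)
    max_sink = float(np.max(sink)) if np.ndim(sink) else float(sink)
    denom = 6.0 * maxD + max_sink
    n_sub = max(1, int(np.ceil(dt * denom))) if denom > 0 else 1
    if n_sub > max_substeps:
        raise StabilityError(n_sub, max_substeps)
    dts = dt / n_sub
    wx, wy, wz = face_diffusivities(np.broadcast_to(D, field.shape))
    f = field.copy()
    rate = np.empty_like(f)
    for _ in range(n_sub):
        rate.fill(0.0)
        _apply_div_flux(f, wx, wy, wz, rate)
        rate += source
        rate -= sink * f
        f += dts * rate
    return f


def diffusion_matrix(D: np.ndarray) -> sp.csr_matrix:
    """Sparse SPD matrix L = -div(D grad .) with no-flux boundaries."""
    D = np.asarray(D, dtype=float)
    nx, ny, nz = D.shape
    n = nx * ny * nz
    idx = np.arange(n).reshape(D.shape)
    wx, wy, wz = face_diffusivities(D)

    rows, cols, vals = [], [], []
    diag = np.zeros(D.shape)
    for w, sl_a, sl_b in (
        (wx, (slice(None, -1), slice(None), slice(None)), (slice(1, None), slice(None), slice(None))),
        (wy, (slice(None), slice(None, -1), slice(None)), (slice(None), slice(1, None), slice(None))),
        (wz, (slice(None), slice(None), slice(None, -1)), (slice(None), slice(None), slice(1, None))),
    ):
        a = idx[sl_a].ravel()
        b = idx[sl_b].ravel()
        wv = w.ravel()
        rows.append(a)
        cols.append(b)
        vals.append(-wv)
        rows.append(b)
        cols.append(a)
        vals.append(-wv)
        diag[sl_a] += w
        diag[sl_b] += w
    rows.append(idx.ravel())
    cols.append(idx.ravel())
    vals.append(diag.ravel())
    L = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))), shape=(n, n)
    )
    return L


class _Jacobi(sp.linalg.LinearOperator):
    def __init__(self, A: sp.csr_matrix):
        d = A.diagonal()
        d[d == 0] = 1.0
        self._inv = 1.0 / d
        super().__init__(dtype=float, shape=A.shape)

    def _matvec(self, x):
        return self._inv * x


class ImplicitDiffusion:
    """Backward-Euler diffusion stepper with a cached operator.

    Solves ``(I + dt L) f_new = f_old`` by preconditioned CG, warm-started
    from the previous solution. Mass is conserved up to the solver tolerance
    (the operator's column sums are exactly one).
    """

    def __init__(self, D: np.ndarray, dt: float, rtol: float = 1e-9):
        self.shape = np.asarray(D).shape
        self.dt = float(dt)
        self.rtol = rtol
        L = diffusion_matrix(D)
        self.A = (sp.identity(L.shape[0], format="csr") + dt * L).tocsr()
        self.M = _Jacobi(self.A)
        self._x0: np.ndarray | None = None

    def step(self, field: np.ndarray) -> np.ndarray:
        b = np.asarray(field, dtype=float).ravel()
        x0 = self._x0 if self._x0 is not None else b
        x, info = cg(self.A, b, x0=x0, rtol=self.rtol, atol=0.0, M=self.M)
        if info != 0:
            raise RuntimeError(f"implicit diffusion CG did not converge (info={info})")
        self._x0 = x
        return x.reshape(self.shape)


def steady_state(
    D: np.ndarray,
    sink: np.ndarray,
    source: np.ndarray,
    rtol: float = 1e-10,
    x0: np.ndarray | None = None,
) -> np.ndarray:
    """Steady solution of ``div(D grad f) + source - sink * f = 0``.

    Requires a nonempty sink (otherwise no steady state exists under
    no-flux boundaries with a positive source).
    """
    sink = np.asarray(sink, dtype=float)
    if not np.any(sink > 0):
        raise ValueError("steady state requires a nonzero sink somewhere")
    A = (diffusion_matrix(np.broadcast_to(D, sink.shape))
         + sp.diags(sink.ravel(), format="csr")).tocsr()
    b = np.broadcast_to(np.asarray(source, dtype=float), sink.shape).ravel()
    x, info = cg(A, b, x0=None if x0 is None else np.asarray(x0).ravel(),
                 rtol=rtol, atol=0.0, M=_Jacobi(A), maxiter=20_000)
    if info != 0:
        raise RuntimeError(f"steady-state CG did not converge (info={info})")
    return x.reshape(sink.shape)
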