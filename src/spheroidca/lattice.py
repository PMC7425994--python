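"""The 3D cell-automaton lattice: occupancy, neighbourhood shells, exterior mask.

The simulated domain is a cubic lattice (default 100^3 voxels, 20 um edge,
i.e. a (2 mm)^3 volume) where each voxel holds at most one cell. Daughter
cells are placed into "spherical" neighbourhood shells of increasing order
around the mother; to keep the aggregate round the placement alternates
stochastically between Moore (Chebyshev) and von Neumann (Manhattan) shell
geometry.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import ndimage

__all__ = [
    "Topology",
    "NeighbourhoodSpec",
    "LatticeGrid",
    "neighbourhood_sites",
    "find_division_site",
    "exterior_mask",
]

EMPTY = -1


class Topology(enum.Enum):
    MOORE = "moore"
    VON_NEUMANN = "von_neumann"


@dataclass(frozen=True)
class NeighbourhoodSpec:
    """A single neighbourhood shell: topology plus shell order (>= 1)."""

    topology: Topology
    order: int

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError(f"neighbourhood order must be >= 1, got {self.order}")


@lru_cache(maxsize=None)
def shell_offsets(topology: Topology, order: int) -> np.ndarray:
    """Integer offsets of the shell at exactly the given order.

    Moore shells collect offsets at Chebyshev distance == order, von Neumann
    shells at Manhattan distance == order. Offsets are sorted
    lexicographically so placement draws are reproducible.
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    rng_ = np.arange(-order, order + 1)
    di, dj, dk = np.meshgrid(rng_, rng_, rng_, indexing="ij")
    offs = np.stack([di.ravel(), dj.ravel(), dk.ravel()], axis=1)
    if topology is Topology.MOORE:
        dist = np.abs(offs).max(axis=1)
    else:
        dist = np.abs(offs).sum(axis=1)
    offs = offs[dist == order]
    key = np.lexsort((offs[:, 2], offs[:, 1], offs[:, 0]))
    out = offs[key]
    out.setflags(write=False)
    return out


class LatticeGrid:
    """Cubic lattice with at most one cell per voxel.

    ``occupancy`` stores the index of the resident cell (or ``EMPTY``). The
    grid itself knows nothing about cell biology; it only does geometry and
    bookkeeping.
    """

    def __init__(self, dims=(100, 100, 100), spacing_um: float = 20.0):
        dims = tuple(int(d) for d in dims)
        if len(dims) != 3 or any(d < 1 for d in dims):
            raise ValueError(f"dims must be three positive integers, got {dims}")
        if spacing_um <= 0:
            raise ValueError("spacing_um must be positive")
        self.dims = dims
        self.spacing_um = float(spacing_um)
        self.occupancy = np.full(dims, EMPTY, dtype=np.int32)

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        return tuple(d * self.spacing_um / 1000.0 for d in self.dims)

    def inside(self, site) -> bool:
        return all(0 <= c < d for c, d in zip(site, self.dims))

    def is_free(self, site) -> bool:
        return self.occupancy[tuple(site)] == EMPTY

    def occupied_mask(self) -> np.ndarray:
        return self.occupancy != EMPTY

    def check_site(self, site) -> None:
        if not self.inside(site):
            raise IndexError(f"site {tuple(site)} outside lattice {self.dims}")


def neighbourhood_sites(grid: LatticeGrid, center, spec: NeighbourhoodSpec) -> np.ndarray:
    """Sites of the shell at exactly ``spec.order`` around ``center``.

    Shells are not cumulative; out-of-lattice sites are clipped. The result
    is ordered deterministically (lexicographic offsets).
    """
    grid.check_site(center)
    offs = shell_offsets(spec.topology, spec.order)
    sites = np.asarray(center, dtype=np.int64)[None, :] + offs
    ok = np.all((sites >= 0) & (sites < np.asarray(grid.dims)[None, :]), axis=1)
    return sites[ok]


def find_division_site(grid: LatticeGrid, mother, max_order: int, rng: np.random.Generator):
    """Pick a daughter-cell site around ``mother``, or ``None`` if enclosed.

    The shell topology is a fair coin flip per call; shells are scanned from
    order 1 upward and the first order containing any free voxel is used,
    choosing uniformly among its free voxels.
    """
    grid.check_site(mother)
    topology = Topology.MOORE if rng.random() < 0.5 else Topology.VON_NEUMANN
    for order in range(1, max_order + 1):
        sites = neighbourhood_sites(grid, mother, NeighbourhoodSpec(topology, order))
        free = sites[grid.occupancy[sites[:, 0], sites[:, 1], sites[:, 2]] == EMPTY]
        if len(free):
            return tuple(int(c) for c in free[rng.integers(len(free))])
    return None


_FACE_STRUCTURE = ndimage.generate_binary_structure(3, 1)


def exterior_mask(occupied: np.ndarray) -> np.ndarray:
    """True at cell-free voxels reachable from the lattice boundary.

    Cell-free voxels fully enclosed by cells (e.g. a hollow core) are *not*
    exterior: the mask is the face-connected flood fill of free space from
    the domain boundary. Oxygen/drug source terms act only where this mask
    is true.
    """
    free = ~np.asarray(occupied, dtype=bool)
    labels, n = ndimage.label(free, structure=_FACE_STRUCTURE)
    if n == 0:
        return np.zeros_like(free)
    border = np.concatenate(
        [
            labels[0].ravel(), labels[-1].ravel(),
            labels[:, 0].ravel(), labels[:, -1].ravel(),
            labels[:, :, 0].ravel(), labels[:, :, -1].ravel(),
        ]
    )
    outside = np.setdiff1d(np.unique(border), [0])
    return np.isin(labels, outside)
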