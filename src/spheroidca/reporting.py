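"""Persistence and reporting: snapshots, VTK export, summary tables.

Snapshots are single HDF5 files carrying the full simulation state —
lattice geometry, the cell table, all fields, the resolved configuration
(as YAML) and the random-generator state — so a resumed run is
bit-identical to an uninterrupted one. VTK export writes an XML ImageData
(.vti) dataset with per-voxel arrays (occupancy, phase/state codes, scaled
oxygen, drug concentrations) for inspection in ParaView-class viewers; it
is derived output, never the source of truth.
"""

from __future__ import annotations

import json
import io

import h5py
import numpy as np
import pandas as pd

from .cells import CellState, g1_delay_factor, phase_from_clock
from .config import config_from_yaml, config_to_yaml
from .engine import SUMMARY_COLUMNS, CellPopulation, SimulationState
from .lattice import LatticeGrid

__all__ = ["write_snapshot", "read_snapshot", "export_vtk",
           "summarize", "write_timeseries_csv", "SnapshotError"]

SNAPSHOT_VERSION = 1

_CELL_FIELDS = ("pos", "tau", "clock", "state", "dying", "death_time", "death_cause", "present")
_GRID_FIELDS = ("K", "khat", "HAP", "AHAP")


class SnapshotError(IOError):
    pass


def write_snapshot(state: SimulationState, path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["format"] = "spheroidca-snapshot"
        f.attrs["version"] = SNAPSHOT_VERSION
        f.attrs["time"] = state.time
        f.attrs["config_yaml"] = config_to_yaml(state.config)
        f.attrs["rng_state"] = json.dumps(state.rng.bit_generator.state)
        f.attrs["khat_frozen"] = state.khat_frozen
        f.attrs["oxygen_scale"] = state.oxygen_scale
        f.attrs["events_fired"] = state.events_fired
        f.attrs["spacing_um"] = state.grid.spacing_um
        f.attrs["dims"] = state.grid.dims
        # units recorded alongside the data they describe
        f.attrs["units"] = json.dumps(
            {"time": "hours", "khat": "mmHg", "tau": "hours", "dose": "Gy"})
        cells = f.create_group("cells")
        n = len(state.pop)
        cells.attrs["n"] = n
        for name in _CELL_FIELDS:
            cells.create_dataset(name, data=getattr(state.pop, name)[:n])
        fields = f.create_group("fields")
        for name in _GRID_FIELDS:
            arr = getattr(state, name)
            if arr is not None:
                fields.create_dataset(name, data=arr)
        dose = f.create_group("dose_windows")
        dose.create_dataset(
            "windows",
            data=np.array([(w.start, w.end, w.magnitude) for w in state.dose_windows])
            .reshape(-1, 3),
        )


def read_snapshot(path) -> SimulationState:
    from .engine import _DoseWindow

    try:
        f = h5py.File(path, "r")
    except OSError as e:
        raise SnapshotError(f"cannot open snapshot {path}: {e}") from e
    with f:
        if f.attrs.get("format") != "spheroidca-snapshot":
            raise SnapshotError(f"{path} is not a spheroidca snapshot")
        version = int(f.attrs["version"])
        if version != SNAPSHOT_VERSION:
            raise SnapshotError(
                f"snapshot version {version} not supported (expected {SNAPSHOT_VERSION})")
        config = config_from_yaml(f.attrs["config_yaml"])
        grid = LatticeGrid(tuple(f.attrs["dims"]), float(f.attrs["spacing_um"]))
        pop = CellPopulation()
        n = int(f["cells"].attrs["n"])
        for _ in range(n):
            pop.add((0, 0, 0), 1.0)
        for name in _CELL_FIELDS:
            getattr(pop, name)[:n] = f["cells"][name][...]
        pres = pop.view("present")
        pos = pop.view("pos")
        for i in np.flatnonzero(pres):
            grid.occupancy[tuple(pos[i])] = i
        rng = np.random.default_rng(0)
        rng.bit_generator.state = json.loads(f.attrs["rng_state"])
        state = SimulationState(config=config, grid=grid, pop=pop, rng=rng,
                                time=float(f.attrs["time"]),
                                khat_frozen=bool(f.attrs["khat_frozen"]),
                                oxygen_scale=float(f.attrs["oxygen_scale"]))
        state.events_fired = int(f.attrs["events_fired"])
        for name in _GRID_FIELDS:
            if name in f["fields"]:
                setattr(state, name, f["fields"][name][...])
        for row in f["dose_windows"]["windows"][...]:
            state.dose_windows.append(_DoseWindow(*row))
        state._oxy_dirty = False
        state._last_refresh = state.time
    return state


def _phase_code_field(state: SimulationState) -> np.ndarray:
    """Per-voxel phase code: -1 empty, 0..3 cycling phases, 4 resting, 5 dying."""
    code = np.full(state.grid.dims, -1, dtype=np.int8)
    pop = state.pop
    pres = np.flatnonzero(pop.view("present"))
    if len(pres) == 0:
        return code
    pos = pop.view("pos")[pres]
    pO2 = state.pO2_at(pos)
    g1df = g1_delay_factor(pO2, state.config.cycle)
    phases = phase_from_clock(pop.view("clock")[pres], pop.view("tau")[pres],
                              g1df, state.config.cycle).astype(np.int8)
    phases[pop.view("state")[pres] != CellState.CYCLING] = 4
    phases[pop.view("dying")[pres]] = 5
    code[pos[:, 0], pos[:, 1], pos[:, 2]] = phases
    return code


def export_vtk(state: SimulationState, path) -> None:
    """Write the state as an ascii VTK XML ImageData (.vti) file.

    Arrays: occupancy (0/1), phase_state code, scaled oxygen K-hat (mmHg),
    and the HAP/AHAP concentrations. One value per voxel (VTK cell data).
    """
    nx, ny, nz = state.grid.dims
    spacing = state.grid.spacing_um / 1000.0  # mm
    arrays = {
        "occupancy": state.occupied().astype(np.int8),
        "phase_state": _phase_code_field(state),
        "khat_mmHg": state.khat_effective() if state.khat is not None
        else np.zeros(state.grid.dims),
        "HAP": state.HAP if state.HAP is not None else np.zeros(state.grid.dims),
        "AHAP": state.AHAP if state.AHAP is not None else np.zeros(state.grid.dims),
    }
    buf = io.StringIO()
    buf.write('<?xml version="1.0"?>\n')
    buf.write('<VTKFile type="ImageData" version="0.1" byte_order="LittleEndian">\n')
    buf.write(f'  <ImageData WholeExtent="0 {nx} 0 {ny} 0 {nz}" '
              f'Origin="0 0 0" Spacing="{spacing} {spacing} {spacing}">\n')
    buf.write(f'    <Piece Extent="0 {nx} 0 {ny} 0 {nz}">\n')
    buf.write("      <CellData>\n")
    for name, arr in arrays.items():
        kind = "Int8" if arr.dtype.kind == "i" else "Float64"
        buf.write(f'        <DataArray type="{kind}" Name="{name}" format="ascii">\n')
        # VTK expects x fastest; our arrays are (x, y, z) C-ordered -> z fastest
        flat = np.transpose(arr, (2, 1, 0)).ravel()
        buf.write("          " + " ".join(map(str, flat)) + "\n")
        buf.write("        </DataArray>\n")
    buf.write("      </CellData>\n")
    buf.write("    </Piece>\n  </ImageData>\n</VTKFile>\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def summarize(state: SimulationState) -> dict:
    """One summary record: phase counts (cycling), S/N-P and dying counts,
    hypoxic fraction and total drug masses."""
    return state.summary_row()


def write_timeseries_csv(df: pd.DataFrame, path) -> None:
    df.loc[:, SUMMARY_COLUMNS].to_csv(path, index=False)
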