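"""File formats: PES grids, parameter tables, structures, trajectories.

Plain-text conventions:

* PES grids are CSV with columns ``Q`` (angstrom) and ``V`` (hartree),
  plus optional per-component columns (ELEC, PAULI, ...) for decomposed
  curves; lines starting with ``#`` carry unit declarations.
* Feature tables and spectra are CSV with a header row.
* Structures (PDB/GRO) and trajectories (DCD/XTC/multi-frame XYZ/PDB) are
  read through MDAnalysis; force-field metadata (charge, sigma, epsilon,
  role per atom name) comes from a JSON parameter table, since structure
  formats carry no force-field information.

All writers go through :func:`atomic_write` (write to a temp file in the
target directory, then rename), so a crashed run never leaves a truncated
output behind.
"""

from __future__ import annotations

import json
import os
import tempfile
from contextlib import contextmanager
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .dvr import PotentialGrid
from .fda import DecomposedPotential
from .features import FeatureVector
from .frames import ROLE_CH, ROLE_CR, ROLE_H, ROLES, SnapshotFrame
from .raman import FrequencyTrajectory, Spectrum

__all__ = [
    "atomic_write",
    "read_pes_csv",
    "write_pes_csv",
    "read_parameter_table",
    "read_topology_parameters",
    "iter_trajectory_frames",
    "write_features_csv",
    "read_features_csv",
    "read_frequency_csv",
    "write_spectrum",
]


@contextmanager
def atomic_write(path: str | Path, mode: str = "w") -> Iterator:
    """Write to a sibling temp file and rename into place on success."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, mode) as fh:
            yield fh
        os.replace(tmp, path)
    except BaseException:
        try:
            os.unlink(tmp)
        except OSError:
            pass
        raise


def read_pes_csv(
    path: str | Path, reduced_mass: float
) -> PotentialGrid | DecomposedPotential:
    """Read a (possibly decomposed) PES grid.

    Two columns (Q, V) give a plain :class:`PotentialGrid`; additional
    columns are interaction components and give a
    :class:`DecomposedPotential` whose grid energies are the V column
    (V_ISO).  ``#`` lines are comments.
    """
    df = pd.read_csv(path, comment="#")
    cols = list(df.columns)
    if len(cols) < 2 or cols[0].strip().upper() != "Q":
        raise ValueError(f"{path}: expected a leading 'Q' column, got {cols}")
    grid = PotentialGrid(
        points=df[cols[0]].to_numpy(),
        energies=df[cols[1]].to_numpy(),
        reduced_mass=reduced_mass,
    )
    if len(cols) == 2:
        return grid
    components = {c: df[c].to_numpy() for c in cols[2:]}
    return DecomposedPotential(grid=grid, components=components)


def write_pes_csv(
    path: str | Path, pes: PotentialGrid | DecomposedPotential
) -> None:
    if isinstance(pes, DecomposedPotential):
        grid, components = pes.grid, dict(pes.components)
    else:
        grid, components = pes, {}
    df = pd.DataFrame({"Q": grid.points, "V": grid.energies, **components})
    with atomic_write(path) as fh:
        fh.write("# units: Q angstrom, energies hartree\n")
        v_name = "V_ISO" if components else "V"
        fh.write(f"# columns: Q, {v_name}" + (", " + ", ".join(components) if components else "") + "\n")
        df.to_csv(fh, index=False)


def read_parameter_table(path: str | Path) -> dict[str, dict]:
    """JSON per-atom-name force-field table.

    Layout ``{atom_name: {"charge": e, "sigma": A, "epsilon": kJ/mol,
    "role": <role>}}``; roles must come from the known set.
    """
    with open(path) as fh:
        table = json.load(fh)
    for name, row in table.items():
        missing = {"charge", "sigma", "epsilon", "role"} - set(row)
        if missing:
            raise ValueError(
                f"parameter table entry {name!r} is missing field(s) {sorted(missing)}"
            )
        if row["role"] not in ROLES:
            raise ValueError(
                f"parameter table entry {name!r} has unknown role {row['role']!r}"
            )
    return table


def _frame_from_universe(universe, table: dict[str, dict]) -> SnapshotFrame:
    names = [a.name for a in universe.atoms]
    missing = [n for n in names if n not in table]
    if missing:
        raise KeyError(
            f"no parameter-table row for atom(s) {sorted(set(missing))}"
        )
    rows = [table[n] for n in names]
    box = universe.dimensions[:3].astype(float)
    return SnapshotFrame(
        coordinates=universe.atoms.positions.astype(float),
        charges=np.array([r["charge"] for r in rows]),
        lj_sigma=np.array([r["sigma"] for r in rows]),
        lj_epsilon=np.array([r["epsilon"] for r in rows]),
        roles=np.array([r["role"] for r in rows], dtype=object),
        box=box,
    )


def read_topology_parameters(
    structure_path: str | Path, params_path: str | Path
) -> SnapshotFrame:
    """Frame template from a structure file plus a JSON parameter table.

    Atom names in the structure (1-based serials at the PDB boundary,
    0-based indices internally) are matched against the table; the frame
    validates that exactly one terminal hydrogen and one of each
    triple-bond carbon exist.
    """
    import MDAnalysis as mda

    table = read_parameter_table(params_path)
    universe = mda.Universe(str(structure_path))
    if universe.dimensions is None or not np.all(universe.dimensions[:3] > 0):
        raise ValueError(f"{structure_path}: structure carries no box dimensions")
    return _frame_from_universe(universe, table)


def iter_trajectory_frames(
    structure_path: str | Path,
    params_path: str | Path,
    trajectory_path: str | Path | None = None,
) -> Iterator[SnapshotFrame]:
    """Yield one :class:`SnapshotFrame` per trajectory frame."""
    import MDAnalysis as mda

    table = read_parameter_table(params_path)
    if trajectory_path is None:
        universe = mda.Universe(str(structure_path))
    else:
        universe = mda.Universe(str(structure_path), str(trajectory_path))
    for _ in universe.trajectory:
        yield _frame_from_universe(universe, table)


_FEATURE_COLUMNS = ("f0", "f1", "f2", "u_H", "u_CH", "u_CR")


def write_features_csv(
    path: str | Path, features: Sequence[FeatureVector]
) -> None:
    df = pd.DataFrame(
        [f.as_array() for f in features], columns=list(_FEATURE_COLUMNS)
    )
    with atomic_write(path) as fh:
        fh.write("# units: f* atomic units (E_h/(e a0^(1+k))), u_* hartree\n")
        df.to_csv(fh, index=False)


def read_features_csv(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path, comment="#")
    missing = set(_FEATURE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing feature column(s) {sorted(missing)}")
    return df[list(_FEATURE_COLUMNS)].to_numpy(dtype=float)


def read_frequency_csv(
    path: str | Path, dt: float | None = None, t1: float = 5.0
) -> FrequencyTrajectory:
    """Read a (time, omega[, alpha01]) CSV into a frequency trajectory.

    The time column (ps) must be uniform; ``dt`` overrides it when there is
    no time column.
    """
    df = pd.read_csv(path, comment="#")
    cols = {c.lower(): c for c in df.columns}
    if "omega" not in cols:
        raise ValueError(f"{path}: need an 'omega' column, got {list(df.columns)}")
    omega = df[cols["omega"]].to_numpy(dtype=float)
    alpha = df[cols["alpha01"]].to_numpy(dtype=float) if "alpha01" in cols else None
    if "time" in cols:
        times = df[cols["time"]].to_numpy(dtype=float)
        steps = np.diff(times)
        if steps.size and (np.any(steps <= 0) or np.ptp(steps) > 1e-9 * steps[0]):
            raise ValueError(f"{path}: time column is not uniformly spaced")
        dt = float(steps[0]) if steps.size else dt
    if dt is None:
        raise ValueError(f"{path}: no time column and no dt given")
    return FrequencyTrajectory(omega=omega, dt=dt, alpha01=alpha, t1=t1)


def write_spectrum(path: str | Path, spec: Spectrum) -> None:
    """Spectrum as CSV plus a JSON sidecar with the peak and FWHM."""
    df = pd.DataFrame({"wavenumber": spec.wavenumber, "intensity": spec.intensity})
    with atomic_write(path) as fh:
        fh.write("# units: wavenumber cm^-1, intensity normalized to unit maximum\n")
        df.to_csv(fh, index=False)
    summary = Path(path).with_suffix(".json")
    with atomic_write(summary) as fh:
        json.dump({"peak": spec.peak, "fwhm": spec.fwhm}, fh, indent=2)
        fh.write("\n")
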