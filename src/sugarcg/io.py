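"""File I/O helpers: coordinate reading (via MDAnalysis), GRO/NDX/table writers.

All in-memory coordinates are nm; MDAnalysis readers (which use Angstrom)
are converted on the way in and out.
"""

from __future__ import annotations

import json

import numpy as np

from .analysis import WallForceSeries
from .errors import SugarCGError


def read_coordinates(path, topology_path=None):
    """Read coordinates (and trajectory) with MDAnalysis.

    Returns ``(coords, box)`` with coords (n_frames, n_atoms, 3) in nm and
    box ``None`` or (3,) nm.  Hydrogens are not filtered here; pass heavy-atom
    files or slice afterwards.
    """
    try:
        import MDAnalysis as mda
    except ImportError as exc:  # pragma: no cover
        raise SugarCGError("reading coordinate files requires MDAnalysis") from exc
    u = mda.Universe(topology_path, path) if topology_path else mda.Universe(path)
    frames = []
    box = None
    for ts in u.trajectory:
        frames.append(u.atoms.positions.copy() / 10.0)
        if ts.dimensions is not None and ts.dimensions[:3].any():
            box = ts.dimensions[:3] / 10.0
    names = [a.name for a in u.atoms]
    resids = [int(a.resid) - 1 for a in u.atoms]
    return np.array(frames), (None if box is None else np.asarray(box)), names, resids


def write_gro(path, names, resnames, positions, box=None, title="sugarcg", resids=None):
    """Write a single-frame GRO file (positions in nm)."""
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    if resids is None:
        resids = [1] * n
    with open(path, "w") as fh:
        fh.write(f"{title}\n{n:5d}\n")
        for i in range(n):
            fh.write(
                f"{resids[i] % 100000:5d}{resnames[i][:5]:<5s}{names[i][:5]:>5s}"
                f"{(i + 1) % 100000:5d}"
                f"{positions[i, 0]:8.3f}{positions[i, 1]:8.3f}{positions[i, 2]:8.3f}\n"
            )
        if box is None:
            fh.write("   0.00000   0.00000   0.00000\n")
        else:
            fh.write(f"{box[0]:10.5f}{box[1]:10.5f}{box[2]:10.5f}\n")


def write_restraints(path, restraints):
    """Flat-bottom restraint table: atom, type, center_z, offset, force constant."""
    with open(path, "w") as fh:
        fh.write("# atom\ttype\tcenter_z_nm\toffset_nm\tk_kJ_mol_nm2\n")
        for atom, rtype, center, offset, k in restraints:
            fh.write(f"{atom}\t{rtype}\t{center:.5f}\t{offset:.5f}\t{k:.1f}\n")


def read_wall_forces(path) -> WallForceSeries:
    """Read a wall-force table (columns: time, lower-wall force, upper-wall force)."""
    data = np.loadtxt(path, comments=("#", "@"))
    if data.ndim == 1:
        data = data[None, :]
    if data.shape[1] < 3:
        raise SugarCGError("wall-force table needs columns: time, lower, upper")
    return WallForceSeries(times=data[:, 0], lower=data[:, 1], upper=data[:, 2])


def write_wall_forces(path, series: WallForceSeries) -> None:
    with open(path, "w") as fh:
        fh.write("# time\tF_lower\tF_upper\n")
        for t, lo, hi in zip(series.times, series.lower, series.upper):
            fh.write(f"{t:.6g}\t{lo:.8g}\t{hi:.8g}\n")


def write_parameter_table(path, fitted: dict) -> None:
    """Plain-text fitted-parameter table consumed by the topology builder."""
    with open(path, "w") as fh:
        fh.write("# kind\tbeads\tparams\n")
        for (kind, beads), value in fitted.items():
            if hasattr(value, "kind"):  # FittedParameters
                if value.series:
                    payload = [list(t) for t in value.series]
                elif value.force_constant is not None:
                    payload = [value.value, value.force_constant]
                else:
                    payload = value.value
            else:
                payload = value if np.isscalar(value) else list(np.asarray(value, dtype=object).tolist())
            fh.write(f"{kind}\t{','.join(map(str, beads))}\t{json.dumps(payload)}\n")


def read_parameter_table(path) -> dict:
    out = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            kind, beads_s, payload = line.rstrip("\n").split("\t")
            beads = tuple(int(b) for b in beads_s.split(","))
            out[(kind, beads)] = json.loads(payload)
    return out
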