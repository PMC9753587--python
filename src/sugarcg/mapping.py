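"""Atomistic-to-CG mapping: index construction and center-of-geometry mapping.

Beads are the unweighted centers of geometry (COG) of their heavy atoms;
hydrogens are excluded so the mapping is independent of the hydrogen model.
At a glycosidic bond the donor residue loses its anomeric hydroxyl oxygen to
condensation and the bridging ether oxygen is bookkept with the B-bead
fragment of the donor-side residue (the residue with the higher bead
numbers), which keeps mappings transferable across oligosaccharides built
with CHARMM-GUI style naming.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import MappingError
from .graph import GlycanGraph

__all__ = [
    "BeadGroup",
    "VirtualSiteGroup",
    "MappingIndex",
    "CGFrame",
    "build_mapping_index",
    "map_coordinates",
    "map_trajectory",
    "make_whole",
    "write_ndx",
]

#: atom-name synonyms per naming convention, applied when resolving external files
NAMING_SYNONYMS = {
    "charmm-gui": {},
    "pdb": {"O6A": "O61", "O6B": "O62", "C7": "C10", "O7": "O10", "C8": "C11"},
}


@dataclass(frozen=True)
class BeadGroup:
    """One CG bead: canonical name, owning residue and its heavy-atom indices (0-based)."""

    name: str
    residue: int
    letter: str
    kind: str
    size: str
    atoms: tuple[int, ...]


@dataclass(frozen=True)
class VirtualSiteGroup:
    """A ring virtual site constructed from bead list positions (0-based)."""

    name: str
    residue: int
    beads: tuple[int, ...]


@dataclass
class MappingIndex:
    """Partition of the molecule's heavy atoms into per-bead groups plus virtual sites."""

    molecule: str
    atom_names: list[str]
    atom_residues: list[int]
    beads: list[BeadGroup]
    virtual_sites: list[VirtualSiteGroup] = field(default_factory=list)

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def n_beads(self) -> int:
        return len(self.beads)

    def bead(self, residue: int, letter: str) -> int:
        """Bead list position of (residue, letter)."""
        for i, b in enumerate(self.beads):
            if b.residue == residue and b.letter == letter:
                return i
        raise KeyError((residue, letter))

    def validate(self) -> None:
        covered = [a for b in self.beads for a in b.atoms]
        if len(covered) != len(set(covered)):
            raise MappingError(f"{self.molecule}: bead atom groups overlap")
        if sorted(covered) != list(range(self.n_atoms)):
            raise MappingError(f"{self.molecule}: bead atom groups do not cover all heavy atoms")
        per_res = {}
        for vs in self.virtual_sites:
            per_res[vs.residue] = per_res.get(vs.residue, 0) + 1
        if any(c != 1 for c in per_res.values()):
            raise MappingError(f"{self.molecule}: a ring must carry exactly one virtual site")


@dataclass
class CGFrame:
    """Bead (and realized virtual-site) coordinates in nm."""

    positions: np.ndarray
    labels: list[str]
    box: np.ndarray | None = None


def _donor_lost_oxygen(template) -> str:
    return f"O{template.anomeric_position}"


def build_mapping_index(g: GlycanGraph, naming: str = "charmm-gui") -> MappingIndex:
    """Build the atomistic->CG mapping index for a validated glycan graph.

    The canonical atom order is residue-major in template order, with
    condensation-lost hydroxyl oxygens removed.  The glycosidic ether oxygen
    (the acceptor's ``O<pos>``) is assigned to the donor residue's B bead.
    """
    if naming not in NAMING_SYNONYMS:
        raise MappingError(f"unknown naming convention {naming!r}")
    donors = {l.donor: l for l in g.linkages}
    acceptors: dict[int, list] = {}
    for l in g.linkages:
        acceptors.setdefault(l.acceptor, []).append(l)

    atom_names: list[str] = []
    atom_residues: list[int] = []
    index_of: dict[tuple[int, str], int] = {}
    for res in range(g.n_residues):
        tpl = g.template(res)
        lost = {_donor_lost_oxygen(tpl)} if res in donors else set()
        for a in tpl.atoms:
            if a in lost:
                continue
            index_of[(res, a)] = len(atom_names)
            atom_names.append(a)
            atom_residues.append(res)

    # per-residue fragment atom lists, adjusted for linkage bookkeeping
    frag_atoms: dict[tuple[int, str], list[str]] = {}
    for res in range(g.n_residues):
        tpl = g.template(res)
        lost = {_donor_lost_oxygen(tpl)} if res in donors else set()
        for letter, frag in tpl.fragments:
            frag_atoms[(res, letter)] = [a for a in frag.atom_names if a not in lost]
    for l in g.linkages:
        bridge = f"O{l.linkage.acceptor_position}"
        src = g.template(l.acceptor)
        letter = src.letter_of(bridge)
        frag_atoms[(l.acceptor, letter)].remove(bridge)
        frag_atoms[(l.donor, "B")].append((l.acceptor, bridge))

    beads: list[BeadGroup] = []
    vsites: list[VirtualSiteGroup] = []
    bead_pos: dict[tuple[int, str], int] = {}
    for res in range(g.n_residues):
        tpl = g.template(res)
        for letter, frag in tpl.fragments:
            atoms = []
            for a in frag_atoms[(res, letter)]:
                key = a if isinstance(a, tuple) else (res, a)
                atoms.append(index_of[key])
            bead_pos[(res, letter)] = len(beads)
            beads.append(
                BeadGroup(
                    name=f"{res + 1}{letter}",
                    residue=res,
                    letter=letter,
                    kind=frag.name,
                    size=frag.size.label,
                    atoms=tuple(atoms),
                )
            )
    for res in range(g.n_residues):
        tpl = g.template(res)
        if tpl.has_virtual_site:
            ring_beads = tuple(bead_pos[(res, letter)] for letter in tpl.ring_letters)
            vsites.append(VirtualSiteGroup(name=f"{res + 1}VS", residue=res, beads=ring_beads))

    idx = MappingIndex(
        molecule="-".join(dict.fromkeys(g.residues)) if g.n_residues <= 2 else f"{g.residues[0]}x{g.n_residues}",
        atom_names=atom_names,
        atom_residues=atom_residues,
        beads=beads,
        virtual_sites=vsites,
    )
    idx.validate()
    return idx


def resolve_atom_order(
    idx: MappingIndex, atom_names, atom_residues, naming: str = "charmm-gui"
) -> np.ndarray:
    """Permutation mapping the index's canonical atom order onto an external one.

    ``atom_names``/``atom_residues`` describe the external file (heavy atoms
    only); synonyms of the naming convention are applied.  Raises
    :class:`MappingError` naming residue, atom and convention when an atom
    cannot be resolved.
    """
    syn = NAMING_SYNONYMS[naming]
    table = {}
    for i, (name, res) in enumerate(zip(atom_names, atom_residues)):
        table[(res, syn.get(name, name))] = i
    perm = np.empty(idx.n_atoms, dtype=int)
    for i, (name, res) in enumerate(zip(idx.atom_names, idx.atom_residues)):
        try:
            perm[i] = table[(res, name)]
        except KeyError:
            raise MappingError(
                f"cannot resolve atom {name!r} of residue {res} under naming convention {naming!r}"
            ) from None
    return perm


def map_coordinates(coords: np.ndarray, idx: MappingIndex, box=None, realize_virtual_sites: bool = True) -> CGFrame:
    """Map one atomistic frame (nm) to CG by per-bead center of geometry.

    Virtual-site coordinates, when realized, are the unweighted mean of their
    constituent bead coordinates.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise MappingError(f"expected (n_atoms, 3) coordinates, got {coords.shape}")
    if coords.shape[0] < idx.n_atoms:
        raise MappingError(
            f"frame has {coords.shape[0]} atoms, mapping index needs {idx.n_atoms}"
        )
    bead_xyz = np.empty((idx.n_beads, 3))
    for i, b in enumerate(idx.beads):
        bead_xyz[i] = coords[list(b.atoms)].mean(axis=0)
    labels = [b.name for b in idx.beads]
    if realize_virtual_sites and idx.virtual_sites:
        vs_xyz = np.empty((len(idx.virtual_sites), 3))
        for i, vs in enumerate(idx.virtual_sites):
            vs_xyz[i] = bead_xyz[list(vs.beads)].mean(axis=0)
        bead_xyz = np.vstack([bead_xyz, vs_xyz])
        labels += [vs.name for vs in idx.virtual_sites]
    return CGFrame(positions=bead_xyz, labels=labels, box=None if box is None else np.asarray(box, float))


def make_whole(coords: np.ndarray, box) -> np.ndarray:
    """Reconstruct an unbroken molecule across periodic boundaries.

    Sequential minimum-image chaining in atom index order (atoms of one
    residue are contiguous, so chains longer than half the box stay intact).
    Orthorhombic boxes only.
    """
    coords = np.asarray(coords, dtype=float)
    box = np.asarray(box, dtype=float)
    diffs = np.diff(coords, axis=-2)
    diffs -= box * np.round(diffs / box)
    out = np.empty_like(coords)
    out[..., 0, :] = coords[..., 0, :]
    out[..., 1:, :] = coords[..., [0], :] + np.cumsum(diffs, axis=-2)
    return out


def map_trajectory(traj, idx: MappingIndex, box=None, whole: bool = True) -> list[CGFrame]:
    """Frame-wise COG mapping of a trajectory (F, n_atoms, 3) in nm.

    Molecules are made whole before averaging when a periodic box is given;
    the atom count must be constant across frames.
    """
    frames = [np.asarray(f, dtype=float) for f in traj]
    if not frames:
        return []
    n0 = frames[0].shape[0]
    for k, f in enumerate(frames):
        if f.shape[0] != n0:
            raise MappingError(f"atom count changed mid-trajectory at frame {k}: {f.shape[0]} != {n0}")
    out = []
    for f in frames:
        if box is not None and whole:
            f = make_whole(f, box)
        out.append(map_coordinates(f, idx, box=box))
    return out


def cg_array(frames: list[CGFrame]) -> np.ndarray:
    """Stack CG frames into an (F, n_sites, 3) array."""
    return np.stack([f.positions for f in frames])


def write_ndx(idx: MappingIndex, path) -> None:
    """Write the mapping as a named-group index file (1-based atom indices)."""
    with open(path, "w") as fh:
        for b in idx.beads:
            fh.write(f"[ {idx.molecule}_{b.name} ]\n")
            fh.write(" ".join(str(a + 1) for a in b.atoms) + "\n")
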