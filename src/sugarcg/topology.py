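"""CG topology assembly: beads, scaled ring constraints, virtual sites, bonded terms.

Monosaccharides are rigid polygons of 2-4 beads held by constraints whose
lengths are the COG-mapped mean distances scaled up uniformly by 15% to
recover the atomistic molecular volume.  Each ring carries a massless TC4
virtual site at its center of geometry.  Across a glycosidic bond the model
defines one (unscaled) bond between the linked beads, all angles spanning
that bond, one dihedral controlling rotation around the bond, and one triad
dihedral per three consecutive residues; angles covered by any dihedral use
the restricted bending potential to avoid collinear instabilities.
Exclusions default to one bonded neighbor, or three for alpha-1,6 polymers
such as dextran.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from . import fragments as frag_mod
from .errors import MissingParameterError, SugarCGError
from .fragments import glycosidic_fragment_type
from .graph import GlycanGraph
from .mapping import MappingIndex, build_mapping_index

__all__ = [
    "ScalingPolicy",
    "ExclusionPolicy",
    "Bead",
    "VirtualSiteDef",
    "BondedTerm",
    "CGTopology",
    "build_beads",
    "place_virtual_sites",
    "enumerate_bonded_terms",
    "derive_ring_geometry",
    "assign_exclusions",
    "assemble_topology",
    "default_exclusion_policy",
    "write_itp",
    "parse_itp",
]

BEAD_MASS = {"regular": 72.0, "small": 54.0, "tiny": 36.0}

#: GROMACS interaction function codes used in the include files
FUNCT_CONSTRAINT = 1
FUNCT_BOND_HARMONIC = 1
FUNCT_ANGLE_HARMONIC = 1
FUNCT_ANGLE_RESTRICTED = 10
FUNCT_DIHEDRAL_PROPER = 1
FUNCT_DIHEDRAL_MULTI = 9
FUNCT_VSITE_COG = 1


@dataclass(frozen=True)
class ScalingPolicy:
    """Bond-length scaling: rings scaled by 15%, glycosidic and substituent
    distances left unscaled by default."""

    ring_scale: float = 1.15
    scale_glycosidic: bool = False
    scale_substituent: bool = False

    def __post_init__(self):
        if self.ring_scale < 1.0:
            raise SugarCGError(f"ring_scale must be >= 1, got {self.ring_scale}")


@dataclass(frozen=True)
class ExclusionPolicy:
    """Nonbonded exclusion depth over the constraint+bond graph (1, 2 or 3)."""

    bonded_neighbor_depth: int = 1

    def __post_init__(self):
        if self.bonded_neighbor_depth not in (1, 2, 3):
            raise SugarCGError("exclusion depth must be 1, 2 or 3")


@dataclass(frozen=True)
class Bead:
    index: int  # 1-based, as serialized
    name: str
    btype: str
    residue: int
    resname: str
    size: str
    mass: float
    charge: float = 0.0
    is_ring: bool = False
    virtual: bool = False


@dataclass(frozen=True)
class VirtualSiteDef:
    """Equal-weight centroid site over the ring beads of one residue (COG, massless)."""

    site: int
    constituents: tuple[int, ...]
    funct: int = FUNCT_VSITE_COG

    @property
    def weights(self) -> tuple[float, ...]:
        n = len(self.constituents)
        return tuple(1.0 / n for _ in range(n))


@dataclass(frozen=True)
class BondedTerm:
    """kind in {constraint, bond, angle, angle_restricted, dihedral, dihedral_triad};
    params empty for skeletons."""

    kind: str
    beads: tuple[int, ...]
    params: tuple = ()

    def key(self):
        return (self.kind, self.beads)


@dataclass
class CGTopology:
    name: str
    beads: list[Bead]
    virtual_sites: list[VirtualSiteDef]
    terms: list[BondedTerm]
    exclusions: list[tuple[int, int]] = field(default_factory=list)

    def terms_of(self, *kinds: str) -> list[BondedTerm]:
        return [t for t in self.terms if t.kind in kinds]

    @property
    def n_real_beads(self) -> int:
        return sum(1 for b in self.beads if not b.virtual)

    def validate(self) -> None:
        indices = {b.index for b in self.beads}
        for t in self.terms:
            if not set(t.beads) <= indices:
                raise SugarCGError(f"term {t.kind} references missing beads {t.beads}")
        for i, j in self.exclusions:
            if i not in indices or j not in indices:
                raise SugarCGError(f"exclusion ({i},{j}) references missing beads")
        # ring constraint polygons must satisfy the triangle inequality
        by_res: dict[int, list[BondedTerm]] = {}
        bead_of = {b.index: b for b in self.beads}
        for t in self.terms_of("constraint"):
            b1, b2 = bead_of[t.beads[0]], bead_of[t.beads[1]]
            if b1.is_ring and b2.is_ring and b1.residue == b2.residue:
                by_res.setdefault(b1.residue, []).append(t)
        for res, cons in by_res.items():
            if len(cons) != 3:
                continue
            lengths = sorted(t.params[0] for t in cons)
            if lengths[2] >= lengths[0] + lengths[1]:
                raise SugarCGError(
                    f"residue {res}: ring constraints {lengths} violate the triangle inequality"
                )

    def __eq__(self, other) -> bool:
        if not isinstance(other, CGTopology):
            return NotImplemented
        return (
            self.name == other.name
            and self.beads == other.beads
            and self.virtual_sites == other.virtual_sites
            and self.terms == other.terms
            and sorted(self.exclusions) == sorted(other.exclusions)
        )


# ---------------------------------------------------------------------------
# bead table and term enumeration

def _linked_bead(tpl, position: int) -> str:
    """Letter of the fragment containing ring carbon C<position>."""
    return tpl.letter_of(f"C{position}")


def build_beads(g: GlycanGraph, idx: MappingIndex | None = None) -> tuple[list[Bead], dict]:
    """Bead table (real beads residue-major, virtual sites appended) plus lookup maps."""
    if idx is None:
        idx = build_mapping_index(g)
    beads: list[Bead] = []
    pos: dict[tuple[int, str], int] = {}
    donor_retype: dict[tuple[int, str], str] = {}
    for link in g.linkages:
        donor_retype[(link.donor, "A")] = glycosidic_fragment_type(
            link.linkage, donor_code=g.residues[link.donor]
        )
    for b in idx.beads:
        tpl = g.template(b.residue)
        btype = donor_retype.get((b.residue, b.letter), tpl.fragment(b.letter).bead_type)
        pos[(b.residue, b.letter)] = len(beads) + 1
        beads.append(
            Bead(
                index=len(beads) + 1,
                name=b.name,
                btype=btype,
                residue=b.residue,
                resname=g.residues[b.residue],
                size=b.size,
                mass=BEAD_MASS[b.size],
                is_ring=b.letter in tpl.ring_letters,
            )
        )
    vs_index: dict[int, int] = {}
    for vs in idx.virtual_sites:
        i = len(beads) + 1
        vs_index[vs.residue] = i
        beads.append(
            Bead(
                index=i,
                name=vs.name,
                btype=frag_mod.fragment_kinds()["virtual_site"].bead_type,
                residue=vs.residue,
                resname=g.residues[vs.residue],
                size="tiny",
                mass=0.0,
                virtual=True,
            )
        )
    info = {"pos": pos, "vs": vs_index, "index": idx}
    return beads, info


def place_virtual_sites(g: GlycanGraph, beads: list[Bead], info: dict) -> list[VirtualSiteDef]:
    """One equal-weight TC4 centroid site per ring, over that residue's ring beads."""
    out = []
    for res, site in sorted(info["vs"].items()):
        tpl = g.template(res)
        constituents = tuple(info["pos"][(res, letter)] for letter in tpl.ring_letters)
        out.append(VirtualSiteDef(site=site, constituents=constituents))
    return out


def _norm(beads: tuple[int, ...]) -> tuple[int, ...]:
    return beads if beads[0] <= beads[-1] else tuple(reversed(beads))


def enumerate_bonded_terms(g: GlycanGraph, info: dict | None = None) -> list[BondedTerm]:
    """Parameter-free skeletons of every bonded term the model defines.

    Per residue: one constraint per ring-bead pair plus two anchoring
    constraints per substituent bead.  Per linkage: one bond between the
    linked beads, every angle spanning it (ring neighbors on both sides) and
    one glycosidic dihedral.  Per pair of linkages sharing a residue: one
    triad dihedral.  Angles whose bead triple is covered by a dihedral are
    emitted as ``angle_restricted``.
    """
    if info is None:
        _, info = build_beads(g)
    pos = info["pos"]
    terms: list[BondedTerm] = []

    ring_letters: dict[int, tuple[str, ...]] = {}
    for res in range(g.n_residues):
        tpl = g.template(res)
        rl = tpl.ring_letters
        ring_letters[res] = rl
        for i in range(len(rl)):
            for j in range(i + 1, len(rl)):
                terms.append(BondedTerm("constraint", _norm((pos[(res, rl[i])], pos[(res, rl[j])]))))
        # substituent beads: anchor to the fragment they branch from plus one more
        bonded_to = {a: set() for a in tpl.atoms}
        for a, b in tpl.bonds:
            bonded_to[a].add(b)
            bonded_to[b].add(a)
        for letter, frag in tpl.fragments:
            if letter in rl:
                continue
            anchor = None
            for a in frag.atom_names:
                for nb in bonded_to[a]:
                    if nb not in frag.atom_names:
                        other = tpl.letter_of(nb)
                        if other != letter:
                            anchor = other
                            break
                if anchor:
                    break
            if anchor is None:
                raise SugarCGError(f"{tpl.code}: substituent {letter} is unattached")
            if anchor in rl:
                second = rl[(rl.index(anchor) + 1) % len(rl)]
            else:
                second = rl[0]
            terms.append(BondedTerm("constraint", _norm((pos[(res, letter)], pos[(res, anchor)]))))
            terms.append(BondedTerm("constraint", _norm((pos[(res, letter)], pos[(res, second)]))))

    def ring_neighbors(res: int, letter: str) -> list[int]:
        return [pos[(res, l)] for l in ring_letters[res] if l != letter]

    dihedrals: list[BondedTerm] = []
    angles: list[tuple[int, int, int]] = []
    for link in g.linkages:
        d_tpl, a_tpl = g.template(link.donor), g.template(link.acceptor)
        d_letter = "A"
        a_letter = _linked_bead(a_tpl, link.linkage.acceptor_position)
        d_bead = pos[(link.donor, d_letter)]
        a_bead = pos[(link.acceptor, a_letter)]
        terms.append(BondedTerm("bond", _norm((d_bead, a_bead))))
        for nb in ring_neighbors(link.donor, d_letter):
            angles.append(_norm((nb, d_bead, a_bead)))
        for nb in ring_neighbors(link.acceptor, a_letter):
            angles.append(_norm((nb, a_bead, d_bead)))
        nb_d = min(ring_neighbors(link.donor, d_letter))
        nb_a = min(ring_neighbors(link.acceptor, a_letter))
        dihedrals.append(BondedTerm("dihedral", _norm((nb_d, d_bead, a_bead, nb_a))))

    by_res: dict[int, list] = {}
    for link in g.linkages:
        d_tpl, a_tpl = g.template(link.donor), g.template(link.acceptor)
        a_letter = _linked_bead(a_tpl, link.linkage.acceptor_position)
        by_res.setdefault(link.donor, []).append(
            (link.acceptor, pos[(link.donor, "A")], pos[(link.acceptor, a_letter)])
        )
        by_res.setdefault(link.acceptor, []).append(
            (link.donor, pos[(link.acceptor, a_letter)], pos[(link.donor, "A")])
        )
    for mid, incident in by_res.items():
        incident = sorted(incident)
        for i in range(len(incident)):
            for j in range(i + 1, len(incident)):
                _, m1, o1 = incident[i]
                _, m2, o2 = incident[j]
                if m1 == m2:
                    continue  # both links leave through the same bead
                dihedrals.append(BondedTerm("dihedral_triad", _norm((o1, m1, m2, o2))))

    covered = set()
    for t in dihedrals:
        b = t.beads
        covered.add(_norm(b[:3]))
        covered.add(_norm(b[1:]))
    for a in dict.fromkeys(angles):
        kind = "angle_restricted" if a in covered else "angle"
        terms.append(BondedTerm(kind, a))
    terms.extend(dihedrals)
    return terms


def default_exclusion_policy(g: GlycanGraph) -> ExclusionPolicy:
    """Three-bonded-neighbor exclusions for alpha-1,6 (dextran-like) polymers,
    one-bonded otherwise."""
    if g.n_residues >= 3 and g.linkages and all(
        l.linkage.anomer == "a" and l.linkage.acceptor_position == 6 for l in g.linkages
    ):
        return ExclusionPolicy(3)
    return ExclusionPolicy(1)


def assign_exclusions(
    beads: list[Bead],
    terms: list[BondedTerm],
    policy: ExclusionPolicy,
    virtual_sites: list[VirtualSiteDef] = (),
) -> list[tuple[int, int]]:
    """Bead pairs within the policy depth over the constraint+bond graph,
    plus each virtual site against its own ring beads."""
    adj: dict[int, set[int]] = {b.index: set() for b in beads}
    for t in terms:
        if t.kind in ("constraint", "bond"):
            i, j = t.beads
            adj[i].add(j)
            adj[j].add(i)
    pairs: set[tuple[int, int]] = set()
    depth = policy.bonded_neighbor_depth
    for start in adj:
        frontier = {start}
        seen = {start}
        for _ in range(depth):
            frontier = {n for f in frontier for n in adj[f]} - seen
            for n in frontier:
                pairs.add((min(start, n), max(start, n)))
            seen |= frontier
    for vs in virtual_sites:
        for c in vs.constituents:
            pairs.add((min(vs.site, c), max(vs.site, c)))
    return sorted(pairs)


# ---------------------------------------------------------------------------
# geometry derivation and assembly

def derive_ring_geometry(
    cg_positions: np.ndarray,
    terms: list[BondedTerm],
    beads: list[Bead],
    policy: ScalingPolicy = ScalingPolicy(),
    min_frames: int = 10,
) -> dict:
    """Mean COG distances for distance-like terms, with the scaling policy applied.

    Intra-ring pairs are multiplied by ``ring_scale``; glycosidic bonds and
    substituent constraints stay unscaled unless the policy says otherwise.
    """
    xyz = np.asarray(cg_positions, dtype=float)
    if xyz.ndim == 2:
        xyz = xyz[None]
    if xyz.shape[0] < min_frames:
        warnings.warn(
            f"only {xyz.shape[0]} reference frames (< {min_frames}); distance means may be noisy",
            stacklevel=2,
        )
    bead_of = {b.index: b for b in beads}
    out = {}
    for t in terms:
        if t.kind not in ("constraint", "bond"):
            continue
        i, j = t.beads
        d = np.linalg.norm(xyz[:, i - 1] - xyz[:, j - 1], axis=1).mean()
        if d <= 0.0:
            raise SugarCGError(f"zero reference distance for beads {t.beads}")
        b1, b2 = bead_of[i], bead_of[j]
        if t.kind == "bond":
            scale = policy.ring_scale if policy.scale_glycosidic else 1.0
        elif b1.is_ring and b2.is_ring and b1.residue == b2.residue:
            scale = policy.ring_scale
        else:
            scale = policy.ring_scale if policy.scale_substituent else 1.0
        out[t.key()] = d * scale
    return out


def _term_params(kind: str, value) -> tuple:
    """Normalize fitted parameters to the rounded tuples stored in the topology."""
    if hasattr(value, "kind"):  # FittedParameters
        fp = value
        if kind == "constraint":
            return (round(float(fp.value), 5),)
        if kind == "bond":
            return (round(float(fp.value), 5), round(float(fp.force_constant), 2))
        if kind in ("angle", "angle_restricted"):
            return (round(float(fp.value), 2), round(float(fp.force_constant), 2))
        return tuple(
            (int(m), round(float(ph), 2), round(float(k), 3)) for m, ph, k in fp.series
        )
    if kind == "constraint":
        if np.isscalar(value):
            return (round(float(value), 5),)
        return (round(float(value[0]), 5),)
    if kind == "bond":
        b0, k = value
        return (round(float(b0), 5), round(float(k), 2))
    if kind in ("angle", "angle_restricted"):
        t0, k = value
        return (round(float(t0), 2), round(float(k), 2))
    if kind in ("dihedral", "dihedral_triad"):
        return tuple((int(m), round(float(ph), 2), round(float(k), 3)) for m, ph, k in value)
    raise SugarCGError(f"unknown term kind {kind!r}")


def assemble_topology(
    g: GlycanGraph,
    fitted: dict,
    scaling: ScalingPolicy = ScalingPolicy(),
    exclusion: ExclusionPolicy | None = None,
    name: str = "MOL",
    triad_dihedrals: bool = True,
) -> CGTopology:
    """Compose the full CG topology from the graph and fitted parameters.

    ``fitted`` maps ``(kind, beads)`` skeleton keys to parameters: a length
    for constraints, ``(b0, k)`` for bonds, ``(theta0, k)`` for angles, a
    cosine series ``[(mult, phase, amplitude), ...]`` for dihedrals (or
    :class:`~sugarcg.fitting.FittedParameters` for any of them).
    """
    beads, info = build_beads(g)
    vsites = place_virtual_sites(g, beads, info)
    skeletons = enumerate_bonded_terms(g, info)
    if not triad_dihedrals:
        skeletons = [t for t in skeletons if t.kind != "dihedral_triad"]
    missing = [t.key() for t in skeletons if t.key() not in fitted]
    if missing:
        raise MissingParameterError(f"no fitted parameters for terms: {missing}")
    terms = [replace(t, params=_term_params(t.kind, fitted[t.key()])) for t in skeletons]
    if exclusion is None:
        exclusion = default_exclusion_policy(g)
    excl = assign_exclusions(beads, terms, exclusion, vsites)
    top = CGTopology(name=name, beads=beads, virtual_sites=vsites, terms=terms, exclusions=excl)
    top.validate()
    return top


# ---------------------------------------------------------------------------
# itp serialization

_GENERATOR_TAG = "; generated by sugarcg (deterministic output)"


def write_itp(top: CGTopology) -> str:
    """Serialize to a GROMACS topology include file (1-based indices).

    Output is deterministic: identical topologies give byte-identical text.
    """
    lines = [_GENERATOR_TAG, ""]
    lines += ["[ moleculetype ]", f"{top.name} 1", ""]
    lines.append("[ atoms ]")
    for b in top.beads:
        lines.append(
            f"{b.index:5d} {b.btype:>6s} {b.residue + 1:4d} {b.resname:>8s} "
            f"{b.name:>6s} {b.index:4d} {b.charge:8.3f} {b.mass:8.3f}"
        )
    lines.append("")

    cons = top.terms_of("constraint")
    if cons:
        lines.append("[ constraints ]")
        for t in cons:
            i, j = t.beads
            lines.append(f"{i:5d} {j:5d} {FUNCT_CONSTRAINT:3d} {t.params[0]:9.5f}")
        lines.append("")
    bonds = top.terms_of("bond")
    if bonds:
        lines.append("[ bonds ]")
        for t in bonds:
            i, j = t.beads
            lines.append(
                f"{i:5d} {j:5d} {FUNCT_BOND_HARMONIC:3d} {t.params[0]:9.5f} {t.params[1]:10.2f}"
            )
        lines.append("")
    angles = top.terms_of("angle", "angle_restricted")
    if angles:
        lines.append("[ angles ]")
        for t in angles:
            i, j, k = t.beads
            funct = FUNCT_ANGLE_RESTRICTED if t.kind == "angle_restricted" else FUNCT_ANGLE_HARMONIC
            lines.append(
                f"{i:5d} {j:5d} {k:5d} {funct:3d} {t.params[0]:8.2f} {t.params[1]:10.2f}"
            )
        lines.append("")
    dihedrals = top.terms_of("dihedral", "dihedral_triad")
    if dihedrals:
        lines.append("[ dihedrals ]")
        for t in dihedrals:
            i, j, k, l = t.beads
            funct = FUNCT_DIHEDRAL_PROPER if len(t.params) == 1 else FUNCT_DIHEDRAL_MULTI
            tag = " ; triad" if t.kind == "dihedral_triad" else ""
            for mult, phase, amp in t.params:
                lines.append(
                    f"{i:5d} {j:5d} {k:5d} {l:5d} {funct:3d} {phase:8.2f} {amp:9.3f} {mult:2d}{tag}"
                )
        lines.append("")
    if top.virtual_sites:
        lines.append("[ virtual_sitesn ]")
        for vs in top.virtual_sites:
            cons_s = " ".join(f"{c:d}" for c in vs.constituents)
            lines.append(f"{vs.site:5d} {vs.funct:3d}  {cons_s}")
        lines.append("")
    if top.exclusions:
        lines.append("[ exclusions ]")
        grouped: dict[int, list[int]] = {}
        for i, j in sorted(top.exclusions):
            grouped.setdefault(i, []).append(j)
        for i in sorted(grouped):
            lines.append(f"{i:5d}  " + " ".join(str(j) for j in sorted(grouped[i])))
        lines.append("")
    return "\n".join(lines)


def parse_itp(text: str) -> CGTopology:
    """Re-read a sugarcg-generated include file into an equal :class:`CGTopology`."""
    section = None
    name = "MOL"
    atoms: list[tuple] = []
    terms: list[BondedTerm] = []
    vsites: list[VirtualSiteDef] = []
    exclusions: list[tuple[int, int]] = []
    dih_acc: dict[tuple, list] = {}
    dih_kind: dict[tuple, str] = {}
    dih_order: list[tuple] = []

    for raw in text.splitlines():
        line, _, comment = raw.partition(";")
        comment = comment.strip()
        line = line.strip()
        if not line:
            continue
        if line.startswith("["):
            section = line.strip("[] ").lower()
            continue
        f = line.split()
        if section == "moleculetype":
            name = f[0]
        elif section == "atoms":
            atoms.append((int(f[0]), f[1], int(f[2]) - 1, f[3], f[4], float(f[6]), float(f[7])))
        elif section == "constraints":
            terms.append(BondedTerm("constraint", (int(f[0]), int(f[1])), (float(f[3]),)))
        elif section == "bonds":
            terms.append(BondedTerm("bond", (int(f[0]), int(f[1])), (float(f[3]), float(f[4]))))
        elif section == "angles":
            kind = "angle_restricted" if int(f[3]) == FUNCT_ANGLE_RESTRICTED else "angle"
            terms.append(BondedTerm(kind, (int(f[0]), int(f[1]), int(f[2])), (float(f[4]), float(f[5]))))
        elif section == "dihedrals":
            beads = (int(f[0]), int(f[1]), int(f[2]), int(f[3]))
            if beads not in dih_acc:
                dih_acc[beads] = []
                dih_order.append(beads)
                dih_kind[beads] = "dihedral_triad" if comment == "triad" else "dihedral"
            dih_acc[beads].append((int(f[7]), float(f[5]), float(f[6])))
        elif section == "virtual_sitesn":
            vsites.append(VirtualSiteDef(site=int(f[0]), constituents=tuple(int(x) for x in f[2:]), funct=int(f[1])))
        elif section == "exclusions":
            i = int(f[0])
            exclusions.extend((i, int(j)) for j in f[1:])
    for beads_key in dih_order:
        terms.append(BondedTerm(dih_kind[beads_key], beads_key, tuple(dih_acc[beads_key])))

    vs_ids = {vs.site for vs in vsites}
    bead_objs = []
    for index, btype, res, resname, aname, charge, mass in atoms:
        virtual = index in vs_ids
        size = "tiny" if btype.startswith("T") else ("small" if btype.startswith("S") else "regular")
        # ring membership back-derived from the virtual-site constituents
        is_ring = any(index in vs.constituents for vs in vsites)
        bead_objs.append(
            Bead(
                index=index,
                name=aname,
                btype=btype,
                residue=res,
                resname=resname,
                size=size,
                mass=mass,
                charge=charge,
                is_ring=is_ring,
                virtual=virtual,
            )
        )
    # restore the canonical term ordering used by the writer
    order = {"constraint": 0, "bond": 1, "angle": 2, "angle_restricted": 2, "dihedral": 3, "dihedral_triad": 3}
    terms.sort(key=lambda t: order[t.kind])
    top = CGTopology(name=name, beads=bead_objs, virtual_sites=vsites, terms=terms, exclusions=sorted(exclusions))
    return top
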