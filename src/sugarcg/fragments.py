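"""Canonical fragment decomposition of monosaccharides and the fragment/bead tables.

Martini 3 carbohydrate beads represent 2-5 heavy atoms each.  A monosaccharide
ring is decomposed into fragments following three rules:

1. maximize the number of diols mapped 4:1 onto a single bead,
2. keep declared functional groups (acids, acetamides, ...) together,
   overriding rule 1 where the two conflict,
3. start at the anomeric carbon and proceed along increasing ring-carbon
   numbering, which makes the decomposition canonical across sugars.

Ring fragments are lettered A, B, C, ... where A always contains the anomeric
carbon and the last ring fragment contains the ring ether oxygen; substituent
fragments continue the alphabet in order of attachment.  Each fragment kind
carries a bead size class (regular/small/tiny) and a Martini 3 bead type
label; the tables ship as plain-text data files next to this module.

Open-chain sugars are not modeled, and the anomers of free monosaccharides
are not distinguished.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from importlib import resources

import networkx as nx

from .errors import RingNotFoundError, SugarCGError, UnsupportedLinkageError, UnsupportedResidueError

__all__ = [
    "BeadSizeClass",
    "REGULAR",
    "SMALL",
    "TINY",
    "BEAD_SIZES",
    "FragmentKind",
    "Fragment",
    "MonosaccharideTemplate",
    "Linkage",
    "MismatchReport",
    "fragment_kinds",
    "supported_residues",
    "get_template",
    "assign_fragments",
    "glycosidic_fragment_type",
    "check_atom_bead_mismatch",
]


@dataclass(frozen=True)
class BeadSizeClass:
    """One of the three Martini 3 bead size classes.

    ``implied_heavy_atoms`` is the nominal number of heavy atoms a bead of
    this class accounts for in the atom/bead mismatch bookkeeping (4, 3 and 2
    for regular, small and tiny beads).
    """

    label: str
    implied_heavy_atoms: int


REGULAR = BeadSizeClass("regular", 4)
SMALL = BeadSizeClass("small", 3)
TINY = BeadSizeClass("tiny", 2)
BEAD_SIZES = {s.label: s for s in (REGULAR, SMALL, TINY)}

#: Lennard-Jones sigma of the self-interaction per size class, nm.
MARTINI_SIGMA = {"regular": 0.47, "small": 0.41, "tiny": 0.34}


@dataclass(frozen=True)
class FragmentKind:
    """A named chemical fragment class (diol, hemiacetal, ...) with its bead assignment."""

    name: str
    size: BeadSizeClass
    bead_type: str
    verified: bool
    note: str = ""


@dataclass(frozen=True)
class Fragment:
    """A fragment instance: a kind bound to a concrete, ordered set of atom names."""

    name: str
    atom_names: tuple[str, ...]
    size: BeadSizeClass
    bead_type: str

    def __post_init__(self):
        if not self.atom_names:
            raise SugarCGError(f"fragment {self.name!r} has an empty atom set")
        if not self.bead_type:
            raise SugarCGError(f"fragment {self.name!r} has an empty bead type")
        if not 2 <= len(self.atom_names) <= 5:
            raise SugarCGError(
                f"fragment {self.name!r} maps {len(self.atom_names)} heavy atoms; 2-5 are allowed"
            )


@dataclass(frozen=True)
class Linkage:
    """A glycosidic linkage class: anomer ('a'/'b'), donor and acceptor positions."""

    anomer: str
    donor_position: int
    acceptor_position: int

    def __post_init__(self):
        if self.anomer not in ("a", "b"):
            raise UnsupportedLinkageError(f"anomer must be 'a' or 'b', got {self.anomer!r}")
        if self.donor_position not in (1, 2):
            raise UnsupportedLinkageError(f"donor (anomeric) position must be 1 or 2, got {self.donor_position}")
        if not 1 <= self.acceptor_position <= 6:
            raise UnsupportedLinkageError(f"acceptor position must be in 1..6, got {self.acceptor_position}")

    def label(self) -> str:
        return f"{self.anomer}{self.donor_position}-{self.acceptor_position}"


@dataclass(frozen=True)
class MonosaccharideTemplate:
    """Heavy-atom structure and canonical fragment list of one residue type."""

    code: str
    ring_class: str
    anomeric_position: int
    atoms: tuple[str, ...]
    bonds: tuple[tuple[str, str], ...]
    ring: tuple[str, ...]
    anomeric_atom: str
    ring_ether_atom: str | None
    fragments: tuple[tuple[str, Fragment], ...]
    substituents: tuple[tuple[tuple[str, ...], bool], ...]
    has_virtual_site: bool = True

    @property
    def heavy_atoms(self) -> int:
        return len(self.atoms)

    @property
    def ring_letters(self) -> tuple[str, ...]:
        """Letters of the fragments composed of ring-path atoms (A, B, [C])."""
        ring_set = set(self.ring)
        return tuple(letter for letter, frag in self.fragments if ring_set & set(frag.atom_names))

    def fragment(self, letter: str) -> Fragment:
        for let, frag in self.fragments:
            if let == letter:
                return frag
        raise KeyError(letter)

    def letter_of(self, atom: str) -> str:
        for let, frag in self.fragments:
            if atom in frag.atom_names:
                return let
        raise KeyError(atom)

    def _validate(self) -> None:
        letters = [letter for letter, _ in self.fragments]
        expected = [chr(ord("A") + i) for i in range(len(letters))]
        if letters != expected:
            raise SugarCGError(f"{self.code}: fragment letters {letters} are not consecutive")
        if self.anomeric_atom not in self.fragments[0][1].atom_names:
            raise SugarCGError(f"{self.code}: A-bead does not contain the anomeric carbon")
        if self.ring_ether_atom is not None:
            last_ring_letter = self.ring_letters[-1]
            if self.ring_ether_atom not in self.fragment(last_ring_letter).atom_names:
                raise SugarCGError(f"{self.code}: last ring fragment misses the ring ether oxygen")
        covered = [a for _, frag in self.fragments for a in frag.atom_names]
        if sorted(covered) != sorted(self.atoms) or len(covered) != len(set(covered)):
            raise SugarCGError(f"{self.code}: fragments do not partition the heavy atoms")


@dataclass(frozen=True)
class MismatchReport:
    """Atom/bead mismatch bookkeeping: at most one stray heavy atom per ten mapped."""

    heavy_atoms: int
    implied_heavy_atoms: int

    @property
    def mismatch(self) -> int:
        return abs(self.heavy_atoms - self.implied_heavy_atoms)

    @property
    def tolerance(self) -> float:
        return self.heavy_atoms / 10.0

    @property
    def passed(self) -> bool:
        return self.mismatch <= self.tolerance


# ---------------------------------------------------------------------------
# data tables

_KIND_CACHE: dict[str, FragmentKind] | None = None
_TEMPLATE_CACHE: dict[str, MonosaccharideTemplate] | None = None


def _data_text(name: str) -> str:
    return resources.files("sugarcg.data").joinpath(name).read_text()


def fragment_kinds() -> dict[str, FragmentKind]:
    """Fragment kind table (name -> size class, bead type, provenance flag)."""
    global _KIND_CACHE
    if _KIND_CACHE is None:
        kinds = {}
        for line in _data_text("fragments.tsv").splitlines():
            if not line.strip() or line.startswith("#") or line.startswith("name\t"):
                continue
            name, size, bead, _example, status, note = line.rstrip("\n").split("\t")
            kinds[name] = FragmentKind(name, BEAD_SIZES[size], bead, status == "text", note)
        _KIND_CACHE = kinds
    return _KIND_CACHE


def _templates() -> dict[str, MonosaccharideTemplate]:
    global _TEMPLATE_CACHE
    if _TEMPLATE_CACHE is None:
        kinds = fragment_kinds()
        data = json.loads(_data_text("monosaccharides.json"))
        out = {}
        for code, rec in data["templates"].items():
            frags = tuple(
                (letter, Fragment(kname, tuple(atoms), kinds[kname].size, kinds[kname].bead_type))
                for letter, kname, atoms in rec["fragments"]
            )
            tpl = MonosaccharideTemplate(
                code=code,
                ring_class=rec["ring_class"],
                anomeric_position=rec["anomeric_position"],
                atoms=tuple(rec["atoms"]),
                bonds=tuple((a, b) for a, b in rec["bonds"]),
                ring=tuple(rec["ring"]),
                anomeric_atom=rec["anomeric_atom"],
                ring_ether_atom=rec["ring_ether_atom"],
                fragments=frags,
                substituents=tuple((tuple(s["atoms"]), bool(s["separate"])) for s in rec["substituents"]),
            )
            tpl._validate()
            out[code] = tpl
        _TEMPLATE_CACHE = out
    return _TEMPLATE_CACHE


def supported_residues() -> tuple[str, ...]:
    return tuple(sorted(_templates()))


def get_template(code: str) -> MonosaccharideTemplate:
    """Return the immutable template for a residue code.

    Raises
    ------
    UnsupportedResidueError
        If the code has no shipped template.
    """
    try:
        return _templates()[code]
    except KeyError:
        raise UnsupportedResidueError(
            f"unsupported residue {code!r}; supported: {', '.join(supported_residues())}"
        ) from None


# ---------------------------------------------------------------------------
# fragment assignment

_NUM_RE = re.compile(r"(\d+)")


def _atom_sort_key(name: str):
    # oxygens (and other heteroatoms) before carbons, then by position number
    m = _NUM_RE.search(name)
    num = int(m.group(1)) if m else 0
    return (0 if not name.startswith("C") else 1, num, name)


def _find_ring(graph: nx.Graph):
    cycles = nx.cycle_basis(graph)
    if not cycles:
        raise RingNotFoundError("ring not found: open-chain structures are not supported")
    if len(cycles) > 1:
        raise SugarCGError("multiple rings in one residue are not supported")
    return cycles[0]


def _ordered_ring(graph: nx.Graph, ring: list[str], anomeric: str) -> list[str]:
    neighbors = [n for n in graph.neighbors(anomeric) if n in ring]
    carbons = sorted((n for n in neighbors if n.startswith("C")), key=_atom_sort_key)
    start_next = carbons[0] if carbons else neighbors[0]
    ordered = [anomeric, start_next]
    while len(ordered) < len(ring):
        nxt = [n for n in graph.neighbors(ordered[-1]) if n in ring and n != ordered[-2]]
        ordered.append(nxt[0])
    return ordered


def _anomeric_atom(graph: nx.Graph, ring: list[str]) -> str:
    ring_oxygens = [a for a in ring if not a.startswith("C")]
    if not ring_oxygens:  # carbocycle (inositol): lowest-numbered ring carbon
        return min(ring, key=_atom_sort_key)
    candidates = []
    for o in ring_oxygens:
        for c in graph.neighbors(o):
            if c in ring and any(
                n.startswith("O") and n not in ring for n in graph.neighbors(c)
            ):
                candidates.append(c)
    if not candidates:
        raise SugarCGError("no anomeric (hemiacetal) carbon found")
    return min(candidates, key=_atom_sort_key)


def assign_fragments(
    atoms,
    bonds,
    substituents=(),
    anomeric_atom: str | None = None,
) -> list[tuple[str, tuple[str, ...]]]:
    """Partition the heavy atoms of one closed-ring residue into canonical fragments.

    Parameters
    ----------
    atoms, bonds
        Heavy-atom names and the bond list among them (single ring plus
        branches).
    substituents
        Declared functional groups, each ``(atom_names, separate)``.  A
        ``separate`` group becomes its own fragment (rule 2, superseding
        rule 1); a non-separate group must stay intact inside a ring
        fragment, which may then grow to five atoms.
    anomeric_atom
        Override the hemiacetal-carbon detection (needed only for exotic
        naming).

    Returns
    -------
    list of ``(letter, atom_names)`` in canonical order: ring fragments
    A, B, ... first, then substituent fragments by attachment order.
    """
    atoms = list(atoms)
    graph = nx.Graph()
    graph.add_nodes_from(atoms)
    graph.add_edges_from(tuple(b) for b in bonds)

    subs = []
    for entry in substituents:
        if isinstance(entry, dict):
            subs.append((tuple(entry["atoms"]), bool(entry.get("separate", True))))
        else:
            grp, sep = entry
            subs.append((tuple(grp), bool(sep)))
    separate = [grp for grp, sep in subs if sep]
    merged = [frozenset(grp) for grp, sep in subs if not sep]
    sep_atoms = {a for grp in separate for a in grp}

    core = graph.subgraph([a for a in atoms if a not in sep_atoms])
    ring = _find_ring(core)
    if anomeric_atom is None:
        anomeric_atom = _anomeric_atom(graph, ring)
    ring_order = _ordered_ring(core, ring, anomeric_atom)
    ring_set = set(ring)
    ring_ether = next((a for a in ring if not a.startswith("C")), None)

    # flatten: each ring atom followed by its exocyclic subtree, depth first
    flat: list[str] = []
    for ratom in ring_order:
        flat.append(ratom)
        stack = sorted(
            (n for n in core.neighbors(ratom) if n not in ring_set),
            key=_atom_sort_key,
            reverse=True,
        )
        seen = {ratom}
        while stack:
            a = stack.pop()
            if a in seen:
                continue
            seen.add(a)
            flat.append(a)
            stack.extend(
                sorted(
                    (n for n in core.neighbors(a) if n not in ring_set and n not in seen),
                    key=_atom_sort_key,
                    reverse=True,
                )
            )

    best = _best_chunking(flat, graph, ring_ether, merged)
    result = [(chr(ord("A") + i), tuple(chunk)) for i, chunk in enumerate(best)]

    # substituent fragments, lettered by attachment order around the ring
    def sub_key(grp):
        dists = nx.multi_source_dijkstra_path_length(graph, set(grp))
        ring_dists = {r: d for r, d in dists.items() if r in ring_set}
        nearest = min(ring_dists, key=lambda r: (ring_dists[r], ring_order.index(r)))
        return (ring_order.index(nearest), ring_dists[nearest])

    next_letter = len(best)
    for grp in sorted(separate, key=sub_key):
        result.append((chr(ord("A") + next_letter), tuple(grp)))
        next_letter += 1

    covered = [a for _, grp in result for a in grp]
    assert sorted(covered) == sorted(atoms), "fragments must partition the heavy atoms"
    return result


def _best_chunking(flat, graph, ring_ether, merged):
    """Choose contiguous, connected chunks of the flattened ring traversal.

    Chunks are 2-4 atoms (5 when they absorb a declared keep-together group);
    the last chunk must contain the ring ether.  Rule 1 is encoded in the
    score: prefer many 4-atom chunks, then few 2-atom chunks, then few
    chunks, ties broken toward front-loaded sizes.
    """
    n = len(flat)
    valid: list[list[list[str]]] = []

    def rec(start, chunks):
        if start == n:
            if ring_ether is None or ring_ether in chunks[-1]:
                valid.append([list(c) for c in chunks])
            return
        for size in (2, 3, 4, 5):
            end = start + size
            if end > n:
                break
            chunk = flat[start:end]
            chunk_set = set(chunk)
            if size == 5 and not any(g <= chunk_set for g in merged):
                continue
            if any(g & chunk_set and not g <= chunk_set for g in merged):
                continue
            if not nx.is_connected(graph.subgraph(chunk)):
                continue
            chunks.append(chunk)
            rec(end, chunks)
            chunks.pop()

    rec(0, [])
    if not valid:
        raise SugarCGError("no valid fragment partition found")

    def score(chunks):
        sizes = tuple(len(c) for c in chunks)
        return (
            sum(1 for s in sizes if s == 4),
            -sum(1 for s in sizes if s == 2),
            -len(sizes),
            sizes,
        )

    return max(valid, key=score)


# ---------------------------------------------------------------------------
# glycosidic fragments and the mismatch rule

def glycosidic_fragment_type(link: Linkage, donor_code: str | None = None) -> str:
    """Bead type of the fragment formed at a glycosidic bond.

    Hexose/pentose bonds fall into two groups: 1-1 through 1-4 share the
    monosaccharide hemiacetal type (SP1r), while 1-5 and 1-6 turn a hydroxyl
    into an ether and get the weaker-self-interaction SN6r.  Sialic-acid
    donors group their carboxylic acid into the glycosidic fragment and use
    the standard Martini 3 acid bead.
    """
    kinds = fragment_kinds()
    if donor_code == "NEU5AC":
        return kinds["glyc_neu5ac_acid"].bead_type
    pos = link.acceptor_position
    if 1 <= pos <= 4:
        return kinds[f"glyc_1{pos}"].bead_type
    if pos in (5, 6):
        return kinds[f"glyc_1{pos}"].bead_type
    raise UnsupportedLinkageError(f"unsupported glycosidic acceptor position {pos}")


def check_atom_bead_mismatch(obj, size_labels=None) -> MismatchReport:
    """Atom/bead mismatch report for a template or an explicit bead list.

    Accepts either a :class:`MonosaccharideTemplate` (virtual site included
    with its tiny-bead budget) or ``(heavy_atoms, size_labels)`` where
    ``size_labels`` covers every bead and virtual site.
    """
    if isinstance(obj, MonosaccharideTemplate):
        heavy = obj.heavy_atoms
        labels = [frag.size.label for _, frag in obj.fragments]
        if obj.has_virtual_site:
            labels.append(fragment_kinds()["virtual_site"].size.label)
    else:
        heavy = int(obj)
        labels = list(size_labels)
    implied = sum(BEAD_SIZES[lab].implied_heavy_atoms for lab in labels)
    return MismatchReport(heavy_atoms=heavy, implied_heavy_atoms=implied)
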