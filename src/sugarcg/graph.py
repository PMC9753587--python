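"""Glycan descriptor parsing and the residue-linkage graph.

The descriptor DSL is a minimal condensed notation: residue codes joined by
``(<anomer><donor>-<acceptor>)`` links, branches in square brackets written
before the residue they attach to, and a ``{n}`` suffix expanding a
two-residue homopolymer unit into a linear n-mer.  Examples::

    GLC                      a single glucose
    GAL(b1-4)GLC             lactose written conventionally
    GLC(a1-1)GLC             trehalose
    GLC(a1-6)GLC{9}          linear dextran oligomer, DoP 9
    GLC(b1-4)GLC{50}         cellulose analog, DoP 50
    GAL(a1-4)[LFUC(a1-2)]GAL a branched trisaccharide

Residues are numbered reducing-end first (the rightmost residue of the
top-level chain is residue 0); branch residues are numbered depth-first at
the residue they attach to, before the continuing backbone.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from . import fragments
from .errors import GlycanParseError, GlycanValidationError
from .fragments import Linkage

__all__ = ["GlycanLink", "GlycanGraph", "parse_glycan", "serialize_glycan", "validate_graph"]


@dataclass(frozen=True)
class GlycanLink:
    """One glycosidic bond: the donor's anomeric carbon to an acceptor position."""

    donor: int
    acceptor: int
    linkage: Linkage


@dataclass
class GlycanGraph:
    """Residue codes plus typed glycosidic linkages; the single source of connectivity."""

    residues: list[str]
    linkages: list[GlycanLink] = field(default_factory=list)

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    def template(self, index: int) -> fragments.MonosaccharideTemplate:
        return fragments.get_template(self.residues[index])

    def donor_links_of(self, index: int) -> list[GlycanLink]:
        return [l for l in self.linkages if l.donor == index]

    def acceptor_links_of(self, index: int) -> list[GlycanLink]:
        return [l for l in self.linkages if l.acceptor == index]

    def __eq__(self, other) -> bool:
        if not isinstance(other, GlycanGraph):
            return NotImplemented
        return self.residues == other.residues and sorted(
            self.linkages, key=lambda l: (l.donor, l.acceptor)
        ) == sorted(other.linkages, key=lambda l: (l.donor, l.acceptor))


# ---------------------------------------------------------------------------
# tokenizer / parser

_TOKEN_RE = re.compile(
    r"(?P<code>[A-Z][A-Z0-9]*)"
    r"|(?P<link>\((?P<an>[ab])(?P<dp>[12])-(?P<ap>[1-6])\))"
    r"|(?P<lb>\[)"
    r"|(?P<rb>\])"
    r"|(?P<rep>\{(?P<n>\d+)\})"
)


@dataclass(frozen=True)
class _Token:
    kind: str
    pos: int
    value: str = ""
    linkage: Linkage | None = None
    count: int = 0


def _tokenize(s: str) -> list[_Token]:
    toks, i = [], 0
    while i < len(s):
        m = _TOKEN_RE.match(s, i)
        if m is None:
            raise GlycanParseError(f"unexpected character {s[i]!r}", i)
        if m.lastgroup == "code" or m.group("code"):
            toks.append(_Token("code", i, value=m.group("code")))
        elif m.group("link"):
            toks.append(
                _Token(
                    "link",
                    i,
                    linkage=Linkage(m.group("an"), int(m.group("dp")), int(m.group("ap"))),
                )
            )
        elif m.group("lb"):
            toks.append(_Token("lb", i))
        elif m.group("rb"):
            toks.append(_Token("rb", i))
        else:
            toks.append(_Token("rep", i, count=int(m.group("n"))))
        i = m.end()
    return toks


def _parse_chain(toks: list[_Token], i: int):
    """Parse a chain; returns (parts, next_index).

    Each part: ``{'code', 'branches': [subchain...], 'link': Linkage|None}``
    where ``link`` joins the part to the residue on its right (or, for the
    last part of a bracketed branch, to the branch attachment residue).
    """
    parts, pending = [], []
    while i < len(toks):
        t = toks[i]
        if t.kind == "lb":
            sub, j = _parse_chain(toks, i + 1)
            if j >= len(toks) or toks[j].kind != "rb":
                raise GlycanParseError("unclosed '['", t.pos)
            if not sub or sub[-1]["link"] is None:
                raise GlycanParseError("branch must end with a linkage", t.pos)
            pending.append(sub)
            i = j + 1
        elif t.kind == "code":
            part = {"code": t.value, "branches": pending, "link": None}
            pending = []
            i += 1
            if i < len(toks) and toks[i].kind == "link":
                part["link"] = toks[i].linkage
                i += 1
            parts.append(part)
        else:
            break
    if pending:
        raise GlycanParseError("branch not followed by a residue", toks[i - 1].pos if i else 0)
    return parts, i


def parse_glycan(descriptor: str) -> GlycanGraph:
    """Parse a glycan descriptor into a validated :class:`GlycanGraph`."""
    toks = _tokenize(descriptor.strip())
    if not toks:
        raise GlycanParseError("empty descriptor", 0)
    parts, i = _parse_chain(toks, 0)
    if i < len(toks) and toks[i].kind == "rep":
        n = toks[i].count
        if n < 1:
            raise GlycanParseError("repeat count must be >= 1", toks[i].pos)
        if (
            len(parts) != 2
            or parts[0]["code"] != parts[1]["code"]
            or parts[0]["branches"]
            or parts[1]["branches"]
            or parts[0]["link"] is None
        ):
            raise GlycanParseError(
                "'{n}' requires a two-residue homopolymer unit like GLC(a1-6)GLC", toks[i].pos
            )
        link = parts[0]["link"]
        code = parts[0]["code"]
        parts = [{"code": code, "branches": [], "link": link} for _ in range(n - 1)]
        parts.append({"code": code, "branches": [], "link": None})
        i += 1
    if i < len(toks):
        raise GlycanParseError("trailing input after descriptor", toks[i].pos)
    if not parts:
        raise GlycanParseError("no residues in descriptor", 0)
    if parts[-1]["link"] is not None:
        raise GlycanParseError("top-level chain must not end with a dangling linkage", 0)
    for p in parts[:-1]:
        if p["link"] is None:
            raise GlycanParseError(f"missing linkage after residue {p['code']}", 0)

    residues: list[str] = []
    linkages: list[GlycanLink] = []

    def add_chain(chain, attach_to):
        index_of = {}
        for k in reversed(range(len(chain))):
            p = chain[k]
            idx = len(residues)
            residues.append(p["code"])
            index_of[k] = idx
            if p["link"] is not None:
                acceptor = index_of[k + 1] if k + 1 < len(chain) else attach_to
                linkages.append(GlycanLink(idx, acceptor, p["link"]))
            for sub in p["branches"]:
                add_chain(sub, attach_to=idx)

    add_chain(parts, attach_to=None)
    g = GlycanGraph(residues, linkages)
    violations = validate_graph(g)
    if violations:
        raise GlycanValidationError("; ".join(violations))
    return g


def serialize_glycan(g: GlycanGraph) -> str:
    """Write a descriptor that parses back to an equal graph (repeats expanded)."""
    children: dict[int, list[GlycanLink]] = {i: [] for i in range(g.n_residues)}
    for link in g.linkages:
        children[link.acceptor].append(link)

    def chain_text(idx: int) -> str:
        kids = sorted(children[idx], key=lambda l: l.donor)
        text = ""
        if kids:
            backbone = kids[-1]
            text += chain_text(backbone.donor) + f"({backbone.linkage.label()})"
            for br in kids[:-1]:
                text += "[" + chain_text(br.donor) + f"({br.linkage.label()})" + "]"
        return text + g.residues[idx]

    return chain_text(0)


def validate_graph(g: GlycanGraph) -> list[str]:
    """Return structural violations (empty list means the graph is valid)."""
    violations: list[str] = []
    n = g.n_residues
    if n == 0:
        return ["graph has no residues"]

    templates = {}
    for i, code in enumerate(g.residues):
        try:
            templates[i] = fragments.get_template(code)
        except Exception:
            violations.append(f"residue {i}: unsupported code {code!r}")

    adj = {i: set() for i in range(n)}
    seen_acceptor: dict[tuple[int, int], int] = {}
    donors_used: dict[int, int] = {}
    for link in g.linkages:
        d, a, lk = link.donor, link.acceptor, link.linkage
        if not (0 <= d < n and 0 <= a < n):
            violations.append(f"linkage {d}->{a}: residue index out of range")
            continue
        adj[d].add(a)
        adj[a].add(d)
        key = (a, lk.acceptor_position)
        if key in seen_acceptor:
            violations.append(
                f"residue {a}: acceptor position {lk.acceptor_position} used by donors "
                f"{seen_acceptor[key]} and {d}"
            )
        else:
            seen_acceptor[key] = d
        if d in donors_used:
            violations.append(f"residue {d}: anomeric (donor) position used more than once")
        donors_used[d] = a
        tpl_d = templates.get(d)
        if tpl_d is not None and lk.donor_position != tpl_d.anomeric_position:
            violations.append(
                f"residue {d} ({g.residues[d]}): donor position {lk.donor_position} "
                f"does not match anomeric position {tpl_d.anomeric_position}"
            )
        tpl_a = templates.get(a)
        if tpl_a is not None:
            oname = f"O{lk.acceptor_position}"
            if oname not in tpl_a.atoms or oname == tpl_a.ring_ether_atom:
                violations.append(
                    f"residue {a} ({g.residues[a]}): no free hydroxyl at position "
                    f"{lk.acceptor_position}"
                )

    # a donor has condensed away its anomeric hydroxyl and cannot accept there
    donor_set = set(donors_used)
    for link in g.linkages:
        a = link.acceptor
        tpl_a = templates.get(a)
        if a in donor_set and tpl_a is not None and link.linkage.acceptor_position == tpl_a.anomeric_position:
            violations.append(
                f"residue {a} ({g.residues[a]}): cannot accept at its anomeric position "
                f"{tpl_a.anomeric_position} while also acting as a donor"
            )

    # connectivity
    stack, seen = [0], {0}
    while stack:
        cur = stack.pop()
        for nb in adj[cur]:
            if nb not in seen:
                seen.add(nb)
                stack.append(nb)
    if len(seen) != n:
        violations.append(f"graph is disconnected ({n - len(seen)} unreachable residues)")
    return violations
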