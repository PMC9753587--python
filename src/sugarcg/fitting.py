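"""Bonded-distribution extraction and single-pass Boltzmann fitting.

Parameters are fitted by direct inversion of mapped reference distributions:
harmonic bonds and angles from the first two moments (``k = kB*T / var``),
glycosidic dihedrals by a weighted least-squares fit of the inverted
histogram to a proper cosine series with up to three terms.  Iterative
refinement (IBI, force matching) is deliberately out of scope; single-pass
inversion is deterministic and reproducible.

The module also generates synthetic "atomistic" reference trajectories --
idealized ring geometries whose inter-residue placement is sampled from
Boltzmann distributions with known parameters -- so the full
generate -> map -> extract -> fit loop is testable without external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import constants

from .errors import FittingError
from .graph import GlycanGraph, parse_glycan
from .mapping import MappingIndex, build_mapping_index
from .topology import BondedTerm, _norm, build_beads

__all__ = [
    "KB",
    "BondedDistribution",
    "FittedParameters",
    "SyntheticReference",
    "distance_series",
    "angle_series",
    "dihedral_series",
    "extract_distributions",
    "fit_bond",
    "fit_angle",
    "fit_dihedral",
    "generate_synthetic_reference",
]

#: Boltzmann/molar gas constant in kJ mol^-1 K^-1 (computed, not hard-coded)
KB = constants.R / 1000.0

BOND_BIN_NM = 0.002
ANGLE_BIN_DEG = 2.0
LOG_FLOOR = 1e-6


@dataclass
class BondedDistribution:
    """Samples and normalized histogram of one bonded coordinate."""

    kind: str
    beads: tuple[int, ...]
    samples: np.ndarray
    edges: np.ndarray
    density: np.ndarray
    temperature: float

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


@dataclass
class FittedParameters:
    """Fitted bonded parameters plus fit diagnostics.

    ``value``/``force_constant`` hold the equilibrium value and stiffness for
    constraints, bonds and angles; ``series`` holds ``(multiplicity,
    phase_deg, amplitude)`` cosine terms for dihedrals.  ``diagnostics``
    records sample count, residuals and the histogram overlap metric (in
    [0, 1]) between the input and the refitted Boltzmann distribution.
    """

    kind: str
    value: float | None = None
    force_constant: float | None = None
    series: tuple = ()
    diagnostics: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# geometric series with minimum-image convention

def _vec(xyz, i, j, box):
    d = xyz[:, j - 1] - xyz[:, i - 1]
    if box is not None:
        d = d - np.asarray(box) * np.round(d / np.asarray(box))
    return d


def distance_series(xyz, i, j, box=None):
    return np.linalg.norm(_vec(xyz, i, j, box), axis=1)


def angle_series(xyz, i, j, k, box=None):
    """Angle i-j-k per frame, degrees."""
    v1 = _vec(xyz, j, i, box)
    v2 = _vec(xyz, j, k, box)
    cosang = np.einsum("ij,ij->i", v1, v2) / (
        np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1)
    )
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


def dihedral_series(xyz, i, j, k, l, box=None):
    """Dihedral i-j-k-l per frame, degrees in (-180, 180]."""
    b1 = _vec(xyz, i, j, box)
    b2 = _vec(xyz, j, k, box)
    b3 = _vec(xyz, k, l, box)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2, axis=1)[:, None])
    x = np.einsum("ij,ij->i", n1, n2)
    y = np.einsum("ij,ij->i", m1, n2)
    phi = np.degrees(np.arctan2(y, x))
    phi[phi <= -180.0] = 180.0
    return phi


def extract_distributions(
    cg_xyz,
    skeletons: list[BondedTerm],
    box=None,
    temperature: float = 298.15,
    bond_bin: float = BOND_BIN_NM,
    angle_bin: float = ANGLE_BIN_DEG,
) -> list[BondedDistribution]:
    """Compute per-term samples and normalized histograms from a mapped trajectory.

    ``cg_xyz`` is (n_frames, n_sites, 3) in nm with 1-based bead ids in the
    skeletons; distances use the minimum-image convention when a box is given.
    """
    xyz = np.asarray(cg_xyz, dtype=float)
    if xyz.ndim == 2:
        xyz = xyz[None]
    n_sites = xyz.shape[1]
    out = []
    for t in skeletons:
        if max(t.beads) > n_sites:
            raise FittingError(f"term {t.kind} {t.beads} references beads beyond the trajectory ({n_sites} sites)")
        if t.kind in ("constraint", "bond"):
            samples = distance_series(xyz, *t.beads, box=box)
            lo = math.floor(samples.min() / bond_bin) * bond_bin - bond_bin
            hi = math.ceil(samples.max() / bond_bin) * bond_bin + bond_bin
            edges = np.arange(lo, hi + 0.5 * bond_bin, bond_bin)
        elif t.kind in ("angle", "angle_restricted"):
            samples = angle_series(xyz, *t.beads, box=box)
            edges = np.arange(0.0, 180.0 + 0.5 * angle_bin, angle_bin)
        elif t.kind in ("dihedral", "dihedral_triad"):
            samples = dihedral_series(xyz, *t.beads, box=box)
            edges = np.arange(-180.0, 180.0 + 0.5 * angle_bin, angle_bin)
        else:
            raise FittingError(f"unknown term kind {t.kind!r}")
        density, edges = np.histogram(samples, bins=edges, density=True)
        out.append(
            BondedDistribution(
                kind=t.kind,
                beads=t.beads,
                samples=samples,
                edges=edges,
                density=density,
                temperature=temperature,
            )
        )
    return out


def make_distribution(
    kind: str,
    samples,
    temperature: float = 298.15,
    beads: tuple[int, ...] = (),
    bond_bin: float = BOND_BIN_NM,
    angle_bin: float = ANGLE_BIN_DEG,
) -> BondedDistribution:
    """Build a :class:`BondedDistribution` from raw samples (nm or degrees).

    Dihedral samples are wrapped into (-180, 180], so fits are invariant
    under full-turn shifts of the input angles.
    """
    samples = np.asarray(samples, dtype=float)
    if kind in ("constraint", "bond"):
        lo = math.floor(samples.min() / bond_bin) * bond_bin - bond_bin
        hi = math.ceil(samples.max() / bond_bin) * bond_bin + bond_bin
        edges = np.arange(lo, hi + 0.5 * bond_bin, bond_bin)
    elif kind in ("angle", "angle_restricted"):
        edges = np.arange(0.0, 180.0 + 0.5 * angle_bin, angle_bin)
    elif kind in ("dihedral", "dihedral_triad"):
        samples = -((-samples + 180.0) % 360.0) + 180.0  # wrap into (-180, 180]
        edges = np.arange(-180.0, 180.0 + 0.5 * angle_bin, angle_bin)
    else:
        raise FittingError(f"unknown term kind {kind!r}")
    density, edges = np.histogram(samples, bins=edges, density=True)
    return BondedDistribution(kind, tuple(beads), samples, edges, density, temperature)


# ---------------------------------------------------------------------------
# fits

def _overlap(d: BondedDistribution, model_density: np.ndarray) -> float:
    widths = np.diff(d.edges)
    return float(np.sum(np.minimum(d.density, model_density) * widths))


def fit_bond(d: BondedDistribution, as_constraint: bool = False, min_samples: int = 10) -> FittedParameters:
    """Constraint length (mean, pre-scaling) or harmonic bond (b0 = mean, k = kB*T/var)."""
    if d.n_samples < min_samples:
        raise FittingError(f"only {d.n_samples} samples (< {min_samples})")
    mean = float(d.samples.mean())
    var = float(d.samples.var())
    if as_constraint:
        return FittedParameters(kind="constraint", value=mean, diagnostics={"n": d.n_samples, "std": math.sqrt(var)})
    if var < 1e-18:
        raise FittingError("zero variance: model this term as a constraint instead")
    k = KB * d.temperature / var
    model = np.exp(-0.5 * k * (d.centers - mean) ** 2 / (KB * d.temperature))
    model /= np.sum(model * np.diff(d.edges))
    return FittedParameters(
        kind="bond",
        value=mean,
        force_constant=k,
        diagnostics={"n": d.n_samples, "overlap": _overlap(d, model)},
    )


def fit_angle(d: BondedDistribution, covered_by_dihedral: bool = False, min_samples: int = 10) -> FittedParameters:
    """Harmonic angle, or restricted-bending when the angle is covered by a dihedral.

    theta0 is the circular mean; near the minimum the restricted-bending form
    ``U = k/2 (cos(t) - cos(t0))^2 / sin^2(t)`` reduces to the harmonic one,
    so the same moment inversion ``k = kB*T / var`` applies to both.
    """
    if d.n_samples < min_samples:
        raise FittingError(f"only {d.n_samples} samples (< {min_samples})")
    rad = np.radians(d.samples)
    theta0 = math.degrees(math.atan2(np.sin(rad).mean(), np.cos(rad).mean())) % 360.0
    if theta0 > 180.0:
        theta0 = 360.0 - theta0
    if covered_by_dihedral and np.any(d.samples >= 180.0 - 1e-12):
        raise FittingError("samples at 180 degrees: restricted bending potential is singular there")
    dev = np.radians(d.samples) - math.radians(theta0)
    var = float((dev**2).mean())
    if var == 0.0:
        raise FittingError("zero angular variance")
    k = KB * d.temperature / var
    kind = "angle_restricted" if covered_by_dihedral else "angle"
    return FittedParameters(kind=kind, value=theta0, force_constant=k, diagnostics={"n": d.n_samples})


def fit_dihedral(d: BondedDistribution, max_terms: int = 3, floor: float = LOG_FLOOR) -> FittedParameters:
    """Weighted least-squares fit of -kB*T*log(histogram) to a cosine series.

    Empty histogram bins are floored at a small probability before taking the
    log.  Returned terms follow the proper-dihedral convention
    ``U = sum_n k_n (1 + cos(n*phi - phase_n))`` up to an additive constant.
    """
    p = np.maximum(d.density, floor)
    u = -KB * d.temperature * np.log(p)
    phi = np.radians(d.centers)
    cols = [np.ones_like(phi)]
    for n in range(1, max_terms + 1):
        cols.append(np.cos(n * phi))
        cols.append(np.sin(n * phi))
    design = np.column_stack(cols)
    w = np.sqrt(d.density + floor)  # weight well-sampled bins
    coef, *_ = np.linalg.lstsq(design * w[:, None], u * w, rcond=None)
    series = []
    for n in range(1, max_terms + 1):
        a, b = coef[2 * n - 1], coef[2 * n]
        amp = math.hypot(a, b)
        phase = math.degrees(math.atan2(b, a))
        series.append((n, phase, amp))
    fitted = design @ coef
    resid = float(np.sqrt(np.mean((u - fitted) ** 2 * w**2) / np.mean(w**2)))
    return FittedParameters(
        kind="dihedral",
        series=tuple(series),
        diagnostics={"n": d.n_samples, "rms_residual": resid},
    )


# ---------------------------------------------------------------------------
# synthetic reference trajectories

RING_BOND_NM = 0.15
EXO_BOND_NM = 0.145
RING_PUCKER_NM = 0.02

DEFAULT_LINK_TRUTH = {
    "bond": (0.50, 7000.0),
    "angle": (112.0, 250.0),
    "dihedral": ((1, 0.0, 6.0),),
}


@dataclass
class SyntheticReference:
    """A generated reference trajectory with its known bonded ground truth."""

    graph: GlycanGraph
    coords: np.ndarray  # (n_frames, n_atoms, 3) nm
    atom_names: list[str]
    atom_residues: list[int]
    index: MappingIndex
    ground_truth: dict
    temperature: float


def ideal_residue_coords(template) -> dict[str, np.ndarray]:
    """Idealized chair-like heavy-atom geometry for one residue template.

    Ring atoms sit on a circle with alternating pucker; exocyclic atoms
    extend radially outward with alternating axial tilt.  This is a
    synthetic construction geometry, not a chemically optimized structure.
    """
    ring = template.ring
    n = len(ring)
    radius = RING_BOND_NM / (2.0 * math.sin(math.pi / n))
    pos: dict[str, np.ndarray] = {}
    for i, a in enumerate(ring):
        ang = 2.0 * math.pi * i / n
        pos[a] = np.array(
            [radius * math.cos(ang), radius * math.sin(ang), RING_PUCKER_NM * (-1.0) ** i]
        )
    bonded: dict[str, set[str]] = {a: set() for a in template.atoms}
    for a, b in template.bonds:
        bonded[a].add(b)
        bonded[b].add(a)
    # breadth-first out of the ring
    frontier = list(ring)
    depth = {a: 0 for a in ring}
    while frontier:
        nxt = []
        for parent in frontier:
            children = sorted(c for c in bonded[parent] if c not in pos)
            for ci, child in enumerate(children):
                radial = pos[parent].copy()
                radial[2] = 0.0
                nr = np.linalg.norm(radial)
                radial = radial / nr if nr > 1e-9 else np.array([1.0, 0.0, 0.0])
                tilt = 0.8 * (-1.0) ** (depth[parent] + ci)
                direction = radial + np.array([0.0, 0.12 * ci, tilt])
                direction /= np.linalg.norm(direction)
                pos[child] = pos[parent] + EXO_BOND_NM * direction
                depth[child] = depth[parent] + 1
                nxt.append(child)
        frontier = nxt
    return pos


def _sample_dihedral_boltzmann(rng, series, temperature, n):
    grid = np.linspace(-180.0, 180.0, 7201)
    u = np.zeros_like(grid)
    for mult, phase, amp in series:
        u += amp * (1.0 + np.cos(np.radians(mult * grid - phase)))
    p = np.exp(-(u - u.min()) / (KB * temperature))
    cdf = np.cumsum(p)
    cdf /= cdf[-1]
    return np.interp(rng.random(n), cdf, grid)


def _dihedral_minimum(series):
    grid = np.linspace(-180.0, 180.0, 7201)
    u = np.zeros_like(grid)
    for mult, phase, amp in series:
        u += amp * (1.0 + np.cos(np.radians(mult * grid - phase)))
    return float(grid[np.argmin(u)])


def _unit(v):
    return v / np.linalg.norm(v, axis=-1, keepdims=True)


def _nerf(u, v, w, r, theta_deg, phi_deg):
    """Place x with |x-w| = r, angle(v,w,x) = theta, dihedral(u,v,w,x) = phi.

    Vectorized over leading axes; angles in degrees.
    """
    theta = np.radians(theta_deg)
    phi = np.radians(phi_deg)
    bc = _unit(w - v)
    n = _unit(np.cross(v - u, bc))
    m = np.cross(n, bc)
    r = np.asarray(r)
    d1 = (-r * np.cos(theta))[..., None]
    d2 = (r * np.sin(theta) * np.cos(phi))[..., None]
    d3 = (-r * np.sin(theta) * np.sin(phi))[..., None]
    return w + d1 * bc + d2 * m + d3 * n


def _frames_from(e1_raw, ref2):
    """Right-handed orthonormal frames (..., 3, 3) with columns (e1, e2, e1 x e2)."""
    e1 = _unit(e1_raw)
    t = ref2 - np.sum(ref2 * e1, axis=-1, keepdims=True) * e1
    e2 = _unit(t)
    e3 = np.cross(e1, e2)
    return np.stack([e1, e2, e3], axis=-1)


def generate_synthetic_reference(
    glycan,
    temperature: float = 298.15,
    n_frames: int = 1,
    seed: int = 0,
    ground_truth: dict | None = None,
    jitter: float = 0.0,
    rigid: bool = False,
) -> SyntheticReference:
    """Emulate an atomistic reference trajectory for a glycan.

    Residues are rigid idealized rings; for every glycosidic link the
    inter-residue bond length, one spanning angle and one dihedral are drawn
    from Boltzmann distributions with known parameters (``ground_truth``
    overrides the defaults per quantity).  With ``rigid=True`` (or zero
    jitter on a monosaccharide) every frame equals the construction
    geometry, which pins the controlled terms at their equilibrium values.

    Returns the trajectory together with the mapping index and a ground
    truth dict keyed like term skeletons, so ``generate -> map -> extract ->
    fit`` recovery is directly checkable.
    """
    g = parse_glycan(glycan) if isinstance(glycan, str) else glycan
    rng = np.random.default_rng(seed)
    idx = build_mapping_index(g)
    _, info = build_beads(g, idx)
    pos = info["pos"]

    truth_in = dict(DEFAULT_LINK_TRUTH)
    if ground_truth:
        truth_in.update(ground_truth)

    # per-residue local geometry; bridge oxygens live geometrically with the
    # residue they descend from even though the mapping bookkeeps them with
    # the donor's B bead, so local frames use same-residue atoms only
    local = [ideal_residue_coords(g.template(res)) for res in range(g.n_residues)]
    ring_letters = {res: g.template(res).ring_letters for res in range(g.n_residues)}

    def local_anchor(res: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        cogs = []
        for letter in ring_letters[res]:
            b = idx.beads[pos[(res, letter)] - 1]
            own = [a for a in b.atoms if idx.atom_residues[a] == res]
            cogs.append(np.mean([local[res][idx.atom_names[a]] for a in own], axis=0))
        return cogs[0], np.mean(cogs, axis=0), cogs[1]

    # donors are always numbered after their acceptors (reducing-end-first
    # trees), so placing in donor order keeps parents ahead of children
    links = sorted(g.linkages, key=lambda l: l.donor)

    truth: dict = {}
    sampled = []
    for link in links:
        a_tpl = g.template(link.acceptor)
        a_letter = a_tpl.letter_of(f"C{link.linkage.acceptor_position}")
        w = pos[(link.acceptor, a_letter)]
        neighbors = sorted(
            pos[(link.acceptor, l)] for l in ring_letters[link.acceptor] if l != a_letter
        )
        v, u = neighbors[0], neighbors[-1]
        x = pos[(link.donor, "A")]
        b0, kb_ = truth_in["bond"]
        t0, ka_ = truth_in["angle"]
        series = tuple(truth_in["dihedral"])
        truth[("bond", _norm((w, x)))] = (b0, kb_)
        truth[("angle", _norm((v, w, x)))] = (t0, ka_)
        truth[("dihedral", _norm((u, v, w, x)))] = series
        if rigid:
            r_s = np.full(n_frames, b0)
            t_s = np.full(n_frames, t0)
            p_s = np.full(n_frames, _dihedral_minimum(series))
        else:
            r_s = rng.normal(b0, math.sqrt(KB * temperature / kb_), n_frames)
            t_s = np.degrees(
                rng.normal(math.radians(t0), math.sqrt(KB * temperature / ka_), n_frames)
            )
            p_s = _sample_dihedral_boltzmann(rng, series, temperature, n_frames)
        sampled.append((link, (u, v, w, x), r_s, t_s, p_s))

    n_atoms = idx.n_atoms
    coords = np.zeros((n_frames, n_atoms, 3))
    bead_xyz = np.zeros((n_frames, idx.n_beads, 3))
    bead_done = np.zeros(idx.n_beads, dtype=bool)
    placed = np.zeros(g.n_residues, dtype=bool)

    def commit(res: int) -> None:
        placed[res] = True
        for bpos, b in enumerate(idx.beads):
            if not bead_done[bpos] and all(placed[idx.atom_residues[a]] for a in b.atoms):
                bead_xyz[:, bpos] = coords[:, list(b.atoms)].mean(axis=1)
                bead_done[bpos] = True

    root_atoms = [i for i in range(n_atoms) if idx.atom_residues[i] == 0]
    coords[:, root_atoms] = np.array([local[0][idx.atom_names[i]] for i in root_atoms])
    commit(0)

    for link, (u, v, w, x), r_s, t_s, p_s in sampled:
        res = link.donor
        U, V, W = bead_xyz[:, u - 1], bead_xyz[:, v - 1], bead_xyz[:, w - 1]
        X = _nerf(U, V, W, r_s, t_s, p_s)
        lx, lg, l2 = local_anchor(res)
        f_loc = _frames_from((lg - lx)[None, :], (l2 - lx)[None, :])[0]
        f_tgt = _frames_from(X - W, V - W)
        rot = f_tgt @ f_loc.T  # (F, 3, 3)
        res_atoms = [i for i in range(n_atoms) if idx.atom_residues[i] == res]
        offsets = np.array([local[res][idx.atom_names[i]] for i in res_atoms]) - lx
        coords[:, res_atoms] = X[:, None, :] + np.einsum("fij,aj->fai", rot, offsets)
        commit(res)

    if jitter > 0.0:
        coords = coords + rng.normal(0.0, jitter, coords.shape)

    return SyntheticReference(
        graph=g,
        coords=coords,
        atom_names=list(idx.atom_names),
        atom_residues=list(idx.atom_residues),
        index=idx,
        ground_truth=truth,
        temperature=temperature,
    )
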