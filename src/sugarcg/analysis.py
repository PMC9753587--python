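"""Desk-scale validation computations: CG SASA, osmotic-pressure protocol,
molality conversion, cluster sizing and polymer statistics.

SASA uses deterministic Shrake-Rupley-style sphere-point sampling with
per-size-class van der Waals radii taken from the minimum of the
Lennard-Jones self-interaction (half of ``2^(1/6) sigma``) and a 0.191 nm
probe.  The osmotic pressure follows the wall-force protocol: solutes are
confined along z by flat-bottomed harmonic walls and the mean force they
exert on the walls, divided by the xy area, is the osmotic pressure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import constants
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .errors import PackingError, SugarCGError
from .fragments import MARTINI_SIGMA

__all__ = [
    "bead_radius",
    "SasaParams",
    "cg_sasa",
    "topology_radii",
    "OsmoticSetup",
    "OsmoticSystem",
    "WallForceSeries",
    "build_osmotic_system",
    "osmotic_pressure",
    "ideal_wall_force_series",
    "ConcentrationSpec",
    "molar_to_molal",
    "ClusterParams",
    "cluster_sizes",
    "PolymerStats",
    "radius_of_gyration",
    "end_to_end_distance",
    "polymer_stats",
]

#: gas constant, kJ mol^-1 K^-1
R_KJ = constants.R / 1000.0

#: kJ mol^-1 nm^-3 expressed in bar (computed from the molar gas constant's
#: sibling N_A at run time rather than hard-coded)
PRESSURE_KJ_PER_NM3_TO_BAR = 1.0e3 / constants.N_A / 1.0e-27 / 1.0e5


def bead_radius(sigma: float | None = None, size: str | None = None) -> float:
    """Van der Waals radius of a bead: half the LJ 12-6 self-interaction minimum.

    The minimum of ``4 eps [(sigma/r)^12 - (sigma/r)^6]`` sits at
    ``r = 2^(1/6) sigma``; the radius is half of that.  Either an explicit
    ``sigma`` (nm) or a Martini size-class label may be given.
    """
    if sigma is None:
        if size is None:
            raise SugarCGError("give either sigma or a size class label")
        sigma = MARTINI_SIGMA[size]
    if sigma <= 0:
        raise SugarCGError(f"sigma must be positive, got {sigma}")
    return 2.0 ** (1.0 / 6.0) * sigma / 2.0


def _default_radii() -> dict[str, float]:
    return {lab: round(bead_radius(sigma=s), 3) for lab, s in MARTINI_SIGMA.items()}


@dataclass
class SasaParams:
    """Probe radius, per-size-class radii (nm) and sphere-sampling resolution."""

    probe_radius: float = 0.191
    radii: dict[str, float] = field(default_factory=_default_radii)
    n_sphere_points: int = 960

    def __post_init__(self):
        if any(r <= 0 for r in self.radii.values()):
            raise SugarCGError("all bead radii must be positive")


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def topology_radii(topology, params: SasaParams | None = None) -> np.ndarray:
    """Per-site radii for a CG topology; virtual sites get zero (no surface)."""
    params = params or SasaParams()
    return np.array(
        [0.0 if b.virtual else params.radii[b.size] for b in topology.beads]
    )


def cg_sasa(positions, radii, params: SasaParams | None = None) -> float:
    """Solvent-accessible surface area (nm^2) by deterministic sphere sampling.

    ``positions`` is (n, 3) or a trajectory (F, n, 3), averaged over frames;
    sites with zero radius (virtual sites) carry no surface and do not
    occlude.  The probe radius is added to every site radius.
    """
    params = params or SasaParams()
    xyz = np.asarray(positions, dtype=float)
    if xyz.ndim == 3:
        return float(np.mean([cg_sasa(f, radii, params) for f in xyz]))
    radii = np.asarray(radii, dtype=float)
    active = np.flatnonzero(radii > 0)
    if xyz.size == 0 or active.size == 0:
        raise SugarCGError("empty structure: no sites with positive radius")
    # exactly coincident equal spheres contribute one surface, not two
    seen: dict[tuple, int] = {}
    keep = []
    for i in active:
        key = (round(radii[i], 12), *np.round(xyz[i], 12))
        if key not in seen:
            seen[key] = i
            keep.append(i)
    active = np.array(keep)
    sphere = _fibonacci_sphere(params.n_sphere_points)
    ext = radii + params.probe_radius
    total = 0.0
    for i in active:
        pts = xyz[i] + ext[i] * sphere
        exposed = np.ones(len(pts), dtype=bool)
        for j in active:
            if j == i:
                continue
            if np.linalg.norm(xyz[i] - xyz[j]) >= ext[i] + ext[j]:
                continue
            exposed &= np.einsum("ij,ij->i", pts - xyz[j], pts - xyz[j]) >= ext[j] ** 2
        total += 4.0 * math.pi * ext[i] ** 2 * exposed.mean()
    return float(total)


# ---------------------------------------------------------------------------
# osmotic pressure protocol

@dataclass
class OsmoticSetup:
    """Geometry and restraint parameters of the wall-force osmotic system.

    Defaults reproduce the reference protocol exactly: a 5.04156 x 5.04156 x
    10.08312 nm box with flat-bottomed harmonic walls (k = 1000 kJ mol^-1
    nm^-2) at 2.52078 nm either side of the box center.
    """

    box: tuple[float, float, float] = (5.04156, 5.04156, 10.08312)
    wall_offset: float = 2.52078
    wall_force_constant: float = 1000.0
    n_solute: int = 0
    n_solvent: int = 0
    temperature: float = 298.15

    def __post_init__(self):
        if not self.wall_offset < self.box[2] / 2.0:
            raise SugarCGError("wall_offset must be smaller than half the box z length")

    @property
    def area_xy(self) -> float:
        return self.box[0] * self.box[1]

    @property
    def wall_planes(self) -> tuple[float, float]:
        zc = self.box[2] / 2.0
        return (zc - self.wall_offset, zc + self.wall_offset)


@dataclass
class OsmoticSystem:
    """Built coordinates plus the flat-bottom restraint specification."""

    positions: np.ndarray
    names: list[str]
    resnames: list[str]
    is_solute: np.ndarray
    setup: OsmoticSetup

    @property
    def restraints(self) -> list[tuple[int, str, float, float, float]]:
        """(atom index 1-based, type, z center, offset, force constant) per solute site."""
        zc = self.setup.box[2] / 2.0
        return [
            (int(i) + 1, "z_flat_bottom", zc, self.setup.wall_offset, self.setup.wall_force_constant)
            for i in np.flatnonzero(self.is_solute)
        ]


def _random_rotation(rng) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def build_osmotic_system(
    solute_coords,
    setup: OsmoticSetup,
    seed: int = 0,
    solute_name: str = "SOL",
    solvent_name: str = "W",
    min_distance: float = 0.21,
    max_tries: int = 2000,
) -> OsmoticSystem:
    """Place solute copies between the walls and solvent beads everywhere.

    Rigid solute conformations are rotated randomly and inserted with their
    center of geometry inside the slab ``|z - z_center| < wall_offset``;
    solvent single beads fill the whole box.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    box = np.asarray(setup.box)
    zc = box[2] / 2.0
    template = np.asarray(solute_coords, dtype=float)
    if template.ndim != 2:
        raise SugarCGError("solute_coords must be (n_sites, 3)")
    template = template - template.mean(axis=0)
    rmax = float(np.linalg.norm(template, axis=1).max()) if len(template) else 0.0

    placed: list[np.ndarray] = []
    names: list[str] = []
    resnames: list[str] = []
    solute_mask: list[bool] = []

    def clashes(pts: np.ndarray) -> bool:
        if not placed:
            return False
        existing = np.concatenate(placed)
        d = existing[None, :, :] - pts[:, None, :]
        d -= box * np.round(d / box)
        return bool((np.einsum("ijk,ijk->ij", d, d) < min_distance**2).any())

    zlo = zc - setup.wall_offset + min(rmax, setup.wall_offset * 0.5)
    zhi = zc + setup.wall_offset - min(rmax, setup.wall_offset * 0.5)
    for m in range(setup.n_solute):
        for attempt in range(max_tries):
            rot = _random_rotation(rng)
            center = np.array(
                [
                    rng.uniform(0, box[0]),
                    rng.uniform(0, box[1]),
                    rng.uniform(zlo, zhi),
                ]
            )
            pts = center + template @ rot.T
            if not clashes(pts):
                placed.append(pts)
                names.extend(f"B{i + 1}" for i in range(len(pts)))
                resnames.extend(solute_name for _ in pts)
                solute_mask.extend(True for _ in pts)
                break
        else:
            raise PackingError(f"could not place solute molecule {m + 1} after {max_tries} tries")
    for m in range(setup.n_solvent):
        for attempt in range(max_tries):
            pt = rng.uniform(0, 1, 3) * box
            if not clashes(pt[None, :]):
                placed.append(pt[None, :])
                names.append("W")
                resnames.append(solvent_name)
                solute_mask.append(False)
                break
        else:
            raise PackingError(f"could not place solvent bead {m + 1} after {max_tries} tries")

    positions = np.concatenate(placed) if placed else np.zeros((0, 3))
    return OsmoticSystem(
        positions=positions,
        names=names,
        resnames=resnames,
        is_solute=np.array(solute_mask, dtype=bool),
        setup=setup,
    )


@dataclass
class WallForceSeries:
    """Per-frame total restraint force (kJ mol^-1 nm^-1) on each of the two walls."""

    times: np.ndarray
    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        if not (len(self.times) == len(self.lower) == len(self.upper)):
            raise SugarCGError("wall force series must have equal lengths")


def osmotic_pressure(series: WallForceSeries, area_xy: float, n_blocks: int = 5) -> tuple[float, float]:
    """Osmotic pressure in bar with a block-averaging standard error.

    The mean force averaged over the two walls is divided by the xy area and
    converted from kJ mol^-1 nm^-3 to bar via the molar gas constant.
    """
    if area_xy <= 0:
        raise SugarCGError(f"area must be positive, got {area_xy}")
    if len(series.times) == 0:
        raise SugarCGError("empty wall-force series")
    per_frame = 0.5 * (series.lower + series.upper) / area_xy * PRESSURE_KJ_PER_NM3_TO_BAR
    mean = float(per_frame.mean())
    blocks = np.array_split(per_frame, min(n_blocks, len(per_frame)))
    bm = np.array([b.mean() for b in blocks])
    err = float(bm.std(ddof=1) / math.sqrt(len(bm))) if len(bm) > 1 else 0.0
    return mean, err


def ideal_wall_force_series(
    setup: OsmoticSetup, n_frames: int, seed: int = 0
) -> WallForceSeries:
    """Equilibrium wall forces of non-interacting point solutes (van 't Hoff toy).

    Solute z coordinates are drawn from the Boltzmann distribution of the
    flat-bottomed potential (uniform core, Gaussian tails); the per-frame
    force on each wall is ``k * sum(excess)``.  An ideal solution obeys
    ``Pi = c R T``, which the reduced pressure approaches for stiff walls.
    """
    rng = np.random.default_rng(seed)
    kT = R_KJ * setup.temperature
    k = setup.wall_force_constant
    sigma = math.sqrt(kT / k)
    w = setup.wall_offset
    core_weight = 2.0 * w / (2.0 * w + math.sqrt(2.0 * math.pi) * sigma)
    n = setup.n_solute
    lower = np.empty(n_frames)
    upper = np.empty(n_frames)
    for f in range(n_frames):
        u = rng.random(n)
        in_core = u < core_weight
        n_tail = int((~in_core).sum())
        excess = np.abs(rng.normal(0.0, sigma, n_tail))
        side = rng.random(n_tail) < 0.5
        lower[f] = k * excess[side].sum()
        upper[f] = k * excess[~side].sum()
    return WallForceSeries(times=np.arange(n_frames, dtype=float), lower=lower, upper=upper)


# ---------------------------------------------------------------------------
# concentrations

@dataclass(frozen=True)
class ConcentrationSpec:
    """Molarity (mol/L), solution mass density (kg/L) and solute molar mass (kg/mol)."""

    molarity: float
    density: float
    molar_mass: float

    def __post_init__(self):
        if self.density <= self.molarity * self.molar_mass:
            raise SugarCGError(
                "solution density must exceed the solute mass concentration (no solvent mass)"
            )


def molar_to_molal(spec: ConcentrationSpec) -> float:
    """Molality b = c / (rho - c M), mol per kg of solvent."""
    return spec.molarity / (spec.density - spec.molarity * spec.molar_mass)


# ---------------------------------------------------------------------------
# clusters and polymer statistics

@dataclass(frozen=True)
class ClusterParams:
    """Linker-bead cutoff criterion: same cluster if closer than ``cutoff`` (nm)."""

    cutoff: float = 1.4

    def __post_init__(self):
        if self.cutoff <= 0:
            raise SugarCGError("cutoff must be positive")


def cluster_sizes(coords, box, params: ClusterParams | None = None) -> dict[int, float]:
    """Cluster-size histogram from minimum-image linker distances.

    ``coords`` is (n, 3) for one frame or (F, n, 3) for a trajectory, in
    which case counts are averaged over frames.  Returns {size: count}.
    """
    params = params or ClusterParams()
    xyz = np.asarray(coords, dtype=float)
    if xyz.ndim == 3:
        hists = [cluster_sizes(f, box, params) for f in xyz]
        sizes = sorted({s for h in hists for s in h})
        return {s: float(np.mean([h.get(s, 0) for h in hists])) for s in sizes}
    n = len(xyz)
    if n == 0:
        return {}
    box_arr = np.asarray(box, dtype=float)
    d = xyz[None, :, :] - xyz[:, None, :]
    d -= box_arr * np.round(d / box_arr)
    dist2 = np.einsum("ijk,ijk->ij", d, d)
    adj = dist2 < params.cutoff**2
    np.fill_diagonal(adj, False)
    i, j = np.nonzero(adj)
    graph = coo_matrix((np.ones_like(i), (i, j)), shape=(n, n))
    _, labels = connected_components(graph, directed=False)
    _, counts = np.unique(labels, return_counts=True)
    sizes, mult = np.unique(counts, return_counts=True)
    return {int(s): int(m) for s, m in zip(sizes, mult)}


@dataclass
class PolymerStats:
    """Per-frame radius of gyration and end-to-end distance (nm)."""

    rg: np.ndarray
    ree: np.ndarray | None

    def histograms(self, bin_width: float = 0.02):
        out = {}
        for key, arr in (("rg", self.rg), ("ree", self.ree)):
            if arr is None:
                continue
            lo = math.floor(arr.min() / bin_width) * bin_width
            hi = math.ceil(arr.max() / bin_width) * bin_width + bin_width
            density, edges = np.histogram(arr, bins=np.arange(lo, hi, bin_width), density=True)
            out[key] = (edges, density)
        return out


def _chain_coords(traj, chain, box):
    xyz = np.asarray(traj, dtype=float)
    if xyz.ndim == 2:
        xyz = xyz[None]
    sel = xyz[:, list(chain), :]
    if box is not None:
        from .mapping import make_whole

        sel = make_whole(sel, box)
    return sel


def radius_of_gyration(traj, chain, box=None) -> np.ndarray:
    """Unweighted Rg over the selected beads, per frame (molecules made whole)."""
    sel = _chain_coords(traj, chain, box)
    com = sel.mean(axis=1, keepdims=True)
    return np.sqrt(np.einsum("fij,fij->f", sel - com, sel - com) / sel.shape[1])


def end_to_end_distance(traj, chain, box=None) -> np.ndarray:
    """First-to-last bead distance per frame; undefined for chains shorter than 2."""
    if len(chain) < 2:
        raise SugarCGError("end-to-end distance undefined for chains of length < 2")
    sel = _chain_coords(traj, chain, box)
    return np.linalg.norm(sel[:, -1] - sel[:, 0], axis=1)


def polymer_stats(traj, chain, box=None, require_ree: bool = True) -> PolymerStats:
    """Radius of gyration and end-to-end distance of an ordered chain selection.

    ``chain`` holds 0-based site indices ordered from the first to the last
    residue, excluding virtual sites.
    """
    rg = radius_of_gyration(traj, chain, box)
    if len(chain) < 2:
        if require_ree:
            raise SugarCGError("end-to-end distance undefined for chains of length < 2")
        return PolymerStats(rg=rg, ree=None)
    return PolymerStats(rg=rg, ree=end_to_end_distance(traj, chain, box))
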