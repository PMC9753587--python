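"""High-level composition: reference trajectory -> fitted CG topology."""

from __future__ import annotations

from .fitting import (
    extract_distributions,
    fit_angle,
    fit_bond,
    fit_dihedral,
    generate_synthetic_reference,
)
from .graph import GlycanGraph, parse_glycan
from .mapping import build_mapping_index, cg_array, map_trajectory
from .topology import (
    CGTopology,
    ExclusionPolicy,
    ScalingPolicy,
    assemble_topology,
    build_beads,
    derive_ring_geometry,
    enumerate_bonded_terms,
)

__all__ = ["parametrize", "build_ideal_topology"]


def parametrize(
    g: GlycanGraph,
    traj,
    box=None,
    temperature: float = 298.15,
    scaling: ScalingPolicy = ScalingPolicy(),
    exclusion: ExclusionPolicy | None = None,
    name: str = "MOL",
    triad_dihedrals: bool = True,
    min_frames: int = 10,
) -> CGTopology:
    """Map an atomistic reference trajectory and fit every bonded term.

    Ring constraints come from scaled COG distance means; glycosidic bonds,
    angles and dihedrals from single-pass Boltzmann inversion of the mapped
    distributions.
    """
    idx = build_mapping_index(g)
    xyz = cg_array(map_trajectory(traj, idx, box=box))
    beads, info = build_beads(g, idx)
    skeletons = enumerate_bonded_terms(g, info)
    if not triad_dihedrals:
        skeletons = [t for t in skeletons if t.kind != "dihedral_triad"]

    fitted: dict = {}
    constraints = [t for t in skeletons if t.kind == "constraint"]
    fitted.update(derive_ring_geometry(xyz, constraints, beads, scaling, min_frames=min_frames))

    others = [t for t in skeletons if t.kind != "constraint"]
    dists = extract_distributions(xyz, others, box=box, temperature=temperature)
    for t, d in zip(others, dists):
        if t.kind == "bond":
            fitted[t.key()] = fit_bond(d)
        elif t.kind in ("angle", "angle_restricted"):
            fitted[t.key()] = fit_angle(d, covered_by_dihedral=(t.kind == "angle_restricted"))
        else:
            fitted[t.key()] = fit_dihedral(d)
    return assemble_topology(
        g,
        fitted,
        scaling=scaling,
        exclusion=exclusion,
        name=name,
        triad_dihedrals=triad_dihedrals,
    )


def build_ideal_topology(
    descriptor: str,
    temperature: float = 298.15,
    n_frames: int = 2000,
    seed: int = 7,
    scaling: ScalingPolicy = ScalingPolicy(),
    exclusion: ExclusionPolicy | None = None,
    name: str | None = None,
    triad_dihedrals: bool = True,
) -> CGTopology:
    """Topology from a synthetic idealized reference (no external data needed).

    Monosaccharides use a single rigid frame (their geometry is fully
    constrained); linked glycans sample the generator's Boltzmann
    distributions over ``n_frames`` frames.
    """
    g = parse_glycan(descriptor)
    rigid = not g.linkages
    frames = 1 if rigid else n_frames
    ref = generate_synthetic_reference(g, temperature=temperature, n_frames=frames, seed=seed, rigid=rigid)
    return parametrize(
        g,
        ref.coords,
        temperature=temperature,
        scaling=scaling,
        exclusion=exclusion,
        name=name or (g.residues[0] if g.n_residues == 1 else "MOL"),
        triad_dihedrals=triad_dihedrals,
        min_frames=1 if rigid else 10,
    )
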