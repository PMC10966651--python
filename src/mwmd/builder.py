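"""System construction: water boxes, solvation, ion placement and toy solutes.

The builders produce complete :class:`~mwmd.system.SimulationSystem`
objects with the fixed atom layout (solute, water triplets, ions) and a
composed :class:`~mwmd.forcefield.Topology`.  Everything is
deterministic given the seed.

Toy solutes stand in for curated protein structures at desk scale: a
united-atom chain with N, CA, C, O backbone sites plus one side-chain
bead per residue, built by internal-coordinate chain extension with
per-conformation (phi, psi) backbone dihedrals.  The helix-like
conformation uses ideal alpha-helical angles so that i -> i+4 backbone
hydrogen bonds are present by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from . import params as P
from .forcefield import Topology
from .system import SimulationSystem

__all__ = [
    "SolvationSpec",
    "IonSpec",
    "RestraintSpec",
    "build_water_box",
    "solvate",
    "add_ions",
    "make_toy_solute",
    "position_restraint_energy_forces",
]


class BuildError(ValueError):
    pass


@dataclass(frozen=True)
class SolvationSpec:
    wall_distance: float = 1.2        # nm, solute to box wall
    min_solvent_distance: float = 0.23  # nm, solute atom to water centre
    target_density: float = 997.0     # kg/m^3

    def __post_init__(self) -> None:
        if self.wall_distance <= 0 or self.min_solvent_distance <= 0:
            raise ValueError("solvation distances must be positive")


@dataclass(frozen=True)
class IonSpec:
    concentration: float = 0.15   # mol/L per species
    exclusion_distance: float = 0.4  # nm from any solute atom
    neutralize: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")


@dataclass(frozen=True)
class RestraintSpec:
    force_constant: float = 25.0  # MJ/(mol nm^2)
    reference: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.force_constant < 0:
            raise ValueError("force constant must be >= 0")

    @property
    def k_kj(self) -> float:
        """Force constant in kJ/(mol nm^2)."""
        return self.force_constant * 1000.0


# ---------------------------------------------------------------------------
# Water geometry helpers
# ---------------------------------------------------------------------------

def _canonical_water() -> np.ndarray:
    """(3, 3) sites O, H, H with O at the origin."""
    half = math.radians(P.WATER_ANGLE_HOH) / 2.0
    return np.array([
        [0.0, 0.0, 0.0],
        [P.WATER_D_OH * math.sin(half), P.WATER_D_OH * math.cos(half), 0.0],
        [-P.WATER_D_OH * math.sin(half), P.WATER_D_OH * math.cos(half), 0.0],
    ])


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix)."""
    a = rng.standard_normal((3, 3))
    q, r = np.linalg.qr(a)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def _water_masses(n_waters: int) -> np.ndarray:
    return np.tile([P.WATER_O_MASS, P.WATER_H_MASS, P.WATER_H_MASS], n_waters)


def _water_box_edge(n_waters: int, density: float) -> float:
    """Cubic box edge (nm) holding n_waters at the given density (kg/m^3)."""
    mass_kg = n_waters * P.WATER_MOLAR_MASS_G * 1e-3 / P.AVOGADRO
    volume_nm3 = mass_kg / density * 1e27
    return volume_nm3 ** (1.0 / 3.0)


# ---------------------------------------------------------------------------
# Topology composition
# ---------------------------------------------------------------------------

def _lj_tables(per_type_c6: np.ndarray, per_type_c12: np.ndarray):
    s6 = np.sqrt(per_type_c6)
    s12 = np.sqrt(per_type_c12)
    return np.outer(s6, s6), np.outer(s12, s12)


def _water_exclusions(n_solute: int, n_waters: int) -> np.ndarray:
    base = n_solute + 3 * np.arange(n_waters)
    trip = np.array([[0, 1], [0, 2], [1, 2]])
    return (base[:, None, None] + trip[None, :, :]).reshape(-1, 2)


def compose_topology(
    solute_top: Optional[Topology],
    n_waters: int,
    ion_names: list[str],
) -> Topology:
    """Compose the full-system topology: solute + waters + ions."""
    n_sol = solute_top.n_atoms if solute_top is not None else 0
    n_ions = len(ion_names)
    n = n_sol + 3 * n_waters + n_ions

    # type table: solute types first, then OW, HW, NA, CL
    if solute_top is not None:
        sol_diag6 = np.diag(solute_top.c6_table)
        sol_diag12 = np.diag(solute_top.c12_table)
    else:
        sol_diag6 = np.zeros(0)
        sol_diag12 = np.zeros(0)
    extra6 = [P.WATER_C6_O, 0.0, P.ION_PARAMS["NA"]["c6"], P.ION_PARAMS["CL"]["c6"]]
    extra12 = [P.WATER_C12_O, 0.0, P.ION_PARAMS["NA"]["c12"], P.ION_PARAMS["CL"]["c12"]]
    diag6 = np.concatenate([sol_diag6, extra6])
    diag12 = np.concatenate([sol_diag12, extra12])
    c6_tab, c12_tab = _lj_tables(diag6, diag12)
    t_ow = len(sol_diag6)
    t_hw = t_ow + 1
    t_na = t_ow + 2
    t_cl = t_ow + 3

    charges = np.zeros(n)
    types = np.zeros(n, dtype=np.int64)
    names: list[str] = []
    elements: list[str] = []
    resids = np.zeros(n, dtype=np.int32)
    resnames: list[str] = []
    mol_index = np.zeros(n, dtype=np.int32)

    if solute_top is not None:
        charges[:n_sol] = solute_top.charges
        types[:n_sol] = solute_top.lj_types
        names += solute_top.atom_names
        elements += solute_top.elements
        resids[:n_sol] = solute_top.resids
        resnames += solute_top.resnames
    next_resid = int(resids[:n_sol].max()) + 1 if n_sol else 0
    next_mol = 1 if n_sol else 0

    w0 = n_sol
    for w in range(n_waters):
        sl = slice(w0 + 3 * w, w0 + 3 * w + 3)
        charges[sl] = [P.WATER_Q_O, P.WATER_Q_H, P.WATER_Q_H]
        types[sl] = [t_ow, t_hw, t_hw]
        names += ["OW", "HW1", "HW2"]
        elements += ["O", "H", "H"]
        resids[sl] = next_resid + w
        resnames += ["SOL"] * 3
        mol_index[sl] = next_mol + w
    next_resid += n_waters
    next_mol += n_waters

    i0 = n_sol + 3 * n_waters
    for k, name in enumerate(ion_names):
        p = P.ION_PARAMS[name]
        charges[i0 + k] = p["charge"]
        types[i0 + k] = t_na if name == "NA" else t_cl
        names.append(name)
        elements.append(name)
        resids[i0 + k] = next_resid + k
        resnames.append(name)
        mol_index[i0 + k] = next_mol + k

    excl_parts = []
    if solute_top is not None and len(solute_top.exclusions):
        excl_parts.append(solute_top.exclusions)
    if n_waters:
        excl_parts.append(_water_exclusions(n_sol, n_waters))
    exclusions = np.concatenate(excl_parts) if excl_parts else np.zeros((0, 2), int)

    empty_i = np.zeros((0, 2), dtype=np.int64)
    return Topology(
        charges=charges,
        lj_types=types,
        c6_table=c6_tab,
        c12_table=c12_tab,
        bonds=solute_top.bonds if solute_top is not None else empty_i,
        bond_r0=solute_top.bond_r0 if solute_top is not None else np.zeros(0),
        bond_k=solute_top.bond_k if solute_top is not None else np.zeros(0),
        angles=solute_top.angles if solute_top is not None else np.zeros((0, 3), int),
        angle_theta0=solute_top.angle_theta0 if solute_top is not None else np.zeros(0),
        angle_k=solute_top.angle_k if solute_top is not None else np.zeros(0),
        dihedrals=solute_top.dihedrals if solute_top is not None else np.zeros((0, 4), int),
        dihedral_mult=solute_top.dihedral_mult if solute_top is not None else np.zeros(0, int),
        dihedral_phase=solute_top.dihedral_phase if solute_top is not None else np.zeros(0),
        dihedral_k=solute_top.dihedral_k if solute_top is not None else np.zeros(0),
        exclusions=exclusions,
        atom_names=names,
        elements=elements,
        resids=resids,
        resnames=resnames,
        mol_index=mol_index,
        head_atom=solute_top.head_atom if solute_top is not None else None,
        tail_atom=solute_top.tail_atom if solute_top is not None else None,
    )


# ---------------------------------------------------------------------------
# Water boxes and solvation
# ---------------------------------------------------------------------------

def _place_waters(
    centres: np.ndarray,
    rng: np.random.Generator,
    box: Optional[np.ndarray] = None,
    min_contact: float = 0.16,
    max_tries: int = 50,
) -> np.ndarray:
    """(n, 3, 3) water site coordinates with random rigid orientations.

    Orientations that put any site within ``min_contact`` nm of an
    already-placed molecule are resampled (SPC hydrogens carry no
    Lennard-Jones repulsion, so close H contacts must be avoided at
    build time)."""
    centres = np.asarray(centres, dtype=np.float64)
    template = _canonical_water()
    coords = np.empty((len(centres), 3, 3))
    # neighbouring molecules (centre distance < 0.7 nm can yield site
    # contacts); centres are fixed, so the neighbour map is static
    reach = 0.7
    if box is not None:
        wrapped = np.mod(centres, box)
        wrapped = np.where(wrapped >= box, 0.0, wrapped)
        tree = cKDTree(wrapped, boxsize=box)
        neighbours = tree.query_ball_point(wrapped, reach)
    else:
        tree = cKDTree(centres)
        neighbours = tree.query_ball_point(centres, reach)

    def min_dist(mol: np.ndarray, others: np.ndarray) -> float:
        disp = mol[:, None, :] - others[None, :, :]
        if box is not None:
            disp -= box * np.rint(disp / box)
        return float(np.linalg.norm(disp, axis=2).min())

    for i, c in enumerate(centres):
        prev = [j for j in neighbours[i] if j < i]
        others = coords[prev].reshape(-1, 3) if prev else None
        best = None
        best_d = -1.0
        for _ in range(max_tries):
            rot = _random_rotation(rng)
            mol = template @ rot.T + c
            if others is None:
                best = mol
                break
            d = min_dist(mol, others)
            if d >= min_contact:
                best = mol
                break
            if d > best_d:
                best, best_d = mol, d
        coords[i] = best
    return coords


def build_water_box(
    n_waters: int,
    target_density: float = 997.0,
    seed: int = 0,
) -> SimulationSystem:
    """Box of rigid three-site waters on a jittered lattice.

    The box volume follows from the target density (cubic for perfect-cube
    molecule counts, mildly rectangular otherwise); molecules sit on a
    simple lattice with a small seeded jitter and random rigid
    orientations.  Oxygen-oxygen distances below 0.24 nm are impossible
    by construction (jitter amplitude bounded by the lattice spacing).
    """
    if n_waters < 1:
        raise BuildError("need at least one water molecule")
    # three near-equal grid dimensions with nx*ny*nz >= n; the box is
    # cubic for perfect cubes and mildly rectangular otherwise, always
    # at exactly the target density
    nx = math.ceil(n_waters ** (1.0 / 3.0))
    ny = math.ceil(math.sqrt(n_waters / nx))
    nz = math.ceil(n_waters / (nx * ny))
    n_sites = nx * ny * nz
    volume = _water_box_edge(n_waters, target_density) ** 3
    spacing = (volume / n_sites) ** (1.0 / 3.0)
    if spacing < 0.24:
        raise BuildError(
            f"density {target_density} kg/m^3 infeasible for a lattice: "
            f"spacing {spacing:.3f} nm < 0.24 nm"
        )
    box = spacing * np.array([nx, ny, nz], dtype=np.float64)
    rng = np.random.default_rng(seed)
    grids = [np.arange(m) * spacing + 0.5 * spacing for m in (nx, ny, nz)]
    pts = np.stack(np.meshgrid(*grids, indexing="ij"), axis=-1).reshape(-1, 3)
    centres = pts[:n_waters]
    jitter = max(min(0.05 * spacing, 0.25 * (spacing - 0.24)), 0.0)
    centres = centres + rng.uniform(-jitter, jitter, centres.shape)
    coords = _place_waters(centres, rng, box=box)
    positions = coords.reshape(-1, 3)
    top = compose_topology(None, n_waters, [])
    return SimulationSystem(
        positions=positions,
        velocities=np.zeros_like(positions),
        box=box,
        masses=_water_masses(n_waters),
        n_solute=0,
        n_waters=n_waters,
        topology=top,
    )


def solvate(
    solute_top: Topology,
    solute_positions: np.ndarray,
    spec: SolvationSpec = SolvationSpec(),
    seed: int = 0,
) -> SimulationSystem:
    """Solvate a solute in a rectangular box of rigid water.

    The box extends ``wall_distance`` beyond the solute extent in each
    dimension; candidate waters fill the box on a jittered lattice at
    the target density, and any water whose geometric centre lies within
    ``min_solvent_distance`` of a solute atom is discarded.
    """
    solute_positions = np.asarray(solute_positions, dtype=np.float64)
    extent = solute_positions.max(axis=0) - solute_positions.min(axis=0)
    box = extent + 2.0 * spec.wall_distance
    # centre the solute in the box
    shift = 0.5 * box - 0.5 * (solute_positions.max(axis=0) + solute_positions.min(axis=0))
    solute_positions = solute_positions + shift

    volume = float(np.prod(box))
    mass_per_water_kg = P.WATER_MOLAR_MASS_G * 1e-3 / P.AVOGADRO
    n_target = int(volume * spec.target_density / (mass_per_water_kg * 1e27))
    spacing = (volume / max(n_target, 1)) ** (1.0 / 3.0)
    rng = np.random.default_rng(seed)
    grids = [np.arange(0.5 * spacing, b, spacing) for b in box]
    pts = np.stack(np.meshgrid(*grids, indexing="ij"), axis=-1).reshape(-1, 3)
    jitter = 0.04 * spacing
    pts = pts + rng.uniform(-jitter, jitter, pts.shape)

    coords = _place_waters(pts, rng, box=box)
    centres = coords.mean(axis=1)  # geometric centre of the 3 sites
    tree = cKDTree(solute_positions)
    d, _ = tree.query(centres, k=1)
    keep = d >= spec.min_solvent_distance
    coords = coords[keep]
    if len(coords) == 0:
        raise BuildError("no waters retained after solvation")
    n_waters = len(coords)

    positions = np.concatenate([solute_positions, coords.reshape(-1, 3)])
    masses = np.concatenate([
        _solute_masses(solute_top), _water_masses(n_waters)
    ])
    top = compose_topology(solute_top, n_waters, [])
    return SimulationSystem(
        positions=positions,
        velocities=np.zeros_like(positions),
        box=box,
        masses=masses,
        n_solute=solute_top.n_atoms,
        n_waters=n_waters,
        topology=top,
    )


def add_ions(
    system: SimulationSystem,
    spec: IonSpec,
    solute_net_charge: Optional[float] = None,
) -> SimulationSystem:
    """Replace eligible waters by Na+/Cl- ions and enforce neutrality.

    The pair count is ``round(c N_water / 55.345)`` — the salt
    concentration converted through the molarity of pure water.  Only
    waters whose oxygen lies more than ``exclusion_distance`` from every
    solute atom are eligible.  Neutralization removes counter-ions
    first and adds ions only when none are removable.
    """
    top = system.topology
    if solute_net_charge is None:
        solute_net_charge = float(top.charges[system.solute_slice].sum()) if top else 0.0
    n_pairs = int(round(spec.concentration * system.n_waters / P.WATER_MOLARITY))

    ions: list[str] = ["NA"] * n_pairs + ["CL"] * n_pairs
    # neutralize: remove counter-ions first, add only if none removable
    excess = int(round(solute_net_charge + sum(P.ION_PARAMS[i]["charge"] for i in ions)))
    while excess > 0:
        if "NA" in ions:
            ions.remove("NA")
        else:
            ions.append("CL")
        excess -= 1
    while excess < 0:
        if "CL" in ions:
            ions.remove("CL")
        else:
            ions.append("NA")
        excess += 1

    n_ions = len(ions)
    if n_ions == 0:
        return system

    nw = system.n_waters
    waters = system.positions[system.water_slice].reshape(nw, 3, 3)
    if system.n_solute:
        tree = cKDTree(system.positions[system.solute_slice])
        d, _ = tree.query(waters[:, 0, :], k=1)
        eligible = np.nonzero(d > spec.exclusion_distance)[0]
    else:
        eligible = np.arange(nw)
    if len(eligible) < n_ions:
        raise BuildError(
            f"insufficient eligible waters for ion placement: need {n_ions}, "
            f"have {len(eligible)} (deficit {n_ions - len(eligible)})"
        )
    rng = np.random.default_rng(spec.seed)
    chosen = rng.choice(eligible, size=n_ions, replace=False)
    chosen_set = set(int(c) for c in chosen)
    keep = np.array([w for w in range(nw) if w not in chosen_set], dtype=int)
    ion_positions = waters[chosen, 0, :]  # oxygen site becomes the ion site

    n_sol = system.n_solute
    new_waters = waters[keep]
    positions = np.concatenate([
        system.positions[system.solute_slice],
        new_waters.reshape(-1, 3),
        ion_positions,
    ])
    sol_top = _extract_solute_topology(system)
    new_top = compose_topology(sol_top, len(keep), ions)
    masses = np.concatenate([
        system.masses[system.solute_slice],
        _water_masses(len(keep)),
        np.array([P.ION_PARAMS[i]["mass"] for i in ions]),
    ])
    out = SimulationSystem(
        positions=positions,
        velocities=np.zeros_like(positions),
        box=system.box.copy(),
        masses=masses,
        n_solute=n_sol,
        n_waters=len(keep),
        n_ions=n_ions,
        topology=new_top,
    )
    total_charge = float(new_top.charges.sum())
    if spec.neutralize and abs(total_charge) > 1e-9:
        raise BuildError(f"system not neutral after ion placement: {total_charge}")
    return out


def _solute_masses(top: Topology) -> np.ndarray:
    mass_by_element = {"N": 14.0067, "C": 12.011, "O": 15.9994, "H": 1.008}
    # united-atom CA/CB beads carry their hydrogens implicitly
    out = np.empty(top.n_atoms)
    for i, name in enumerate(top.atom_names):
        if name == "CA":
            out[i] = 13.019
        elif name == "CB":
            out[i] = 15.035
        else:
            out[i] = mass_by_element[top.elements[i]]
    return out


def _extract_solute_topology(system: SimulationSystem) -> Optional[Topology]:
    """Rebuild the solute-only topology slice from a composed system."""
    if system.n_solute == 0:
        return None
    top = system.topology
    n = system.n_solute
    sol_types = top.lj_types[:n]
    n_types = int(sol_types.max()) + 1 if n else 0
    sel_b = (top.bonds < n).all(axis=1) if len(top.bonds) else np.zeros(0, bool)
    sel_e = (top.exclusions < n).all(axis=1) if len(top.exclusions) else np.zeros(0, bool)
    return Topology(
        charges=top.charges[:n],
        lj_types=sol_types,
        c6_table=top.c6_table[:n_types, :n_types],
        c12_table=top.c12_table[:n_types, :n_types],
        bonds=top.bonds[sel_b] if len(top.bonds) else top.bonds,
        bond_r0=top.bond_r0[sel_b] if len(top.bonds) else top.bond_r0,
        bond_k=top.bond_k[sel_b] if len(top.bonds) else top.bond_k,
        angles=top.angles,
        angle_theta0=top.angle_theta0,
        angle_k=top.angle_k,
        dihedrals=top.dihedrals,
        dihedral_mult=top.dihedral_mult,
        dihedral_phase=top.dihedral_phase,
        dihedral_k=top.dihedral_k,
        exclusions=top.exclusions[sel_e] if len(top.exclusions) else top.exclusions,
        atom_names=top.atom_names[:n],
        elements=top.elements[:n],
        resids=top.resids[:n],
        resnames=top.resnames[:n],
        mol_index=top.mol_index[:n],
        head_atom=top.head_atom,
        tail_atom=top.tail_atom,
    )


# ---------------------------------------------------------------------------
# Toy solutes
# ---------------------------------------------------------------------------

_BACKBONE_ANGLES = {
    "helix_like": (-57.0, -47.0),
    "extended": (-180.0, 180.0),
    "hairpin_like": (-120.0, 120.0),
}


def _nerf(a, b, c, bond, angle_deg, dihedral_deg):
    """Place atom D from A, B, C with given C-D bond, B-C-D angle and
    A-B-C-D dihedral (natural extension reference frame)."""
    theta = math.radians(angle_deg)
    phi = math.radians(dihedral_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-10:
        # collinear support atoms: pick any perpendicular
        helper = np.array([1.0, 0.0, 0.0])
        if abs(bc[0]) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        n = np.cross(bc, helper)
        nn = np.linalg.norm(n)
    n = n / nn
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * math.cos(theta),
        bond * math.sin(theta) * math.cos(phi),
        bond * math.sin(theta) * math.sin(phi),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def make_toy_solute(
    kind: str = "helix_like",
    n_residues: int = 10,
    seed: int = 0,
) -> tuple[Topology, np.ndarray]:
    """Generate a united-atom toy peptide: (Topology, coordinates in nm).

    Five sites per residue (N, CA, C, O, CB); bonds, angles and backbone
    dihedrals are generated from the bead geometry, exclusions are 1-2
    and 1-3, and the chain's head (first N) and tail (last C) atoms are
    tagged for head-to-tail analysis.  The seed controls which residues
    carry a charged (+-1 e) side-chain bead.
    """
    if kind not in _BACKBONE_ANGLES:
        raise BuildError(f"unknown solute kind {kind!r}")
    if not 3 <= n_residues <= 60:
        raise BuildError("n_residues must be in [3, 60]")
    rng = np.random.default_rng(seed)
    phi0, psi0 = _BACKBONE_ANGLES[kind]
    omega = 180.0

    # per-residue (phi, psi); the hairpin gets a type-I-like turn mid-chain
    phis = np.full(n_residues, phi0)
    psis = np.full(n_residues, psi0)
    if kind == "hairpin_like" and n_residues >= 6:
        mid = n_residues // 2
        phis[mid - 1], psis[mid - 1] = -60.0, -30.0
        phis[mid], psis[mid] = -90.0, 0.0

    B = P.BOND_LENGTHS
    coords: dict[tuple[int, str], np.ndarray] = {}
    # seed the first three backbone atoms in the xy-plane
    coords[(0, "N")] = np.array([0.0, 0.0, 0.0])
    coords[(0, "CA")] = np.array([B[("N", "CA")], 0.0, 0.0])
    th = math.radians(P.ANGLE_THETA0[("N", "CA", "C")])
    coords[(0, "C")] = coords[(0, "CA")] + B[("CA", "C")] * np.array(
        [-math.cos(th), math.sin(th), 0.0]
    )
    for i in range(n_residues):
        n_i, ca_i, c_i = coords[(i, "N")], coords[(i, "CA")], coords[(i, "C")]
        # carbonyl O: dihedral N-CA-C-O = psi + 180
        coords[(i, "O")] = _nerf(
            n_i, ca_i, c_i, B[("C", "O")],
            P.ANGLE_THETA0[("CA", "C", "O")], psis[i] + 180.0,
        )
        # side-chain bead: dihedral C-N-CA-CB ~ -120
        coords[(i, "CB")] = _nerf(
            c_i, n_i, ca_i, B[("CA", "CB")],
            P.ANGLE_THETA0[("N", "CA", "CB")], -120.0,
        )
        if i + 1 < n_residues:
            coords[(i + 1, "N")] = _nerf(
                n_i, ca_i, c_i, B[("C", "N")],
                P.ANGLE_THETA0[("CA", "C", "N")], psis[i],
            )
            coords[(i + 1, "CA")] = _nerf(
                ca_i, c_i, coords[(i + 1, "N")], B[("N", "CA")],
                P.ANGLE_THETA0[("C", "N", "CA")], omega,
            )
            coords[(i + 1, "C")] = _nerf(
                c_i, coords[(i + 1, "N")], coords[(i + 1, "CA")], B[("N", "CA")],
                P.ANGLE_THETA0[("N", "CA", "C")], phis[i + 1],
            )
            # fix the CA-C bond length (the NeRF call above used N-CA)
            v = coords[(i + 1, "C")] - coords[(i + 1, "CA")]
            coords[(i + 1, "C")] = coords[(i + 1, "CA")] + v / np.linalg.norm(v) * B[("CA", "C")]

    site_order = ["N", "CA", "C", "O", "CB"]
    index = {(i, s): i * 5 + k for i in range(n_residues) for k, s in enumerate(site_order)}
    n_atoms = 5 * n_residues
    positions = np.zeros((n_atoms, 3))
    for key, idx in index.items():
        positions[idx] = coords[key]

    # LJ types: N, C (CA/C), O, CB
    type_names = ["N", "C", "O", "CB"]
    tmap = {"N": 0, "CA": 1, "C": 1, "O": 2, "CB": 3}
    diag6 = np.array([P.SOLUTE_LJ[t]["c6"] for t in type_names])
    diag12 = np.array([P.SOLUTE_LJ[t]["c12"] for t in type_names])
    c6_tab, c12_tab = _lj_tables(diag6, diag12)

    charges = np.zeros(n_atoms)
    atom_names, elements, resnames = [], [], []
    resids = np.zeros(n_atoms, dtype=np.int32)
    lj_types = np.zeros(n_atoms, dtype=np.int64)
    charged = rng.random(n_residues) < P.SIDECHAIN_CHARGED_FRACTION
    signs = np.where(rng.random(n_residues) < 0.5, 1.0, -1.0)
    nonpolar_names = sorted(P.NONPOLAR_RESIDUES)
    for i in range(n_residues):
        if charged[i]:
            resname = "LYS" if signs[i] > 0 else "ASP"
        else:
            resname = nonpolar_names[int(rng.integers(len(nonpolar_names)))]
        for s in site_order:
            idx = index[(i, s)]
            atom_names.append(s)
            elements.append({"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C"}[s])
            resids[idx] = i
            resnames.append(resname)
            lj_types[idx] = tmap[s]
            charges[idx] = P.SOLUTE_CHARGES.get(s, 0.0)
        if charged[i]:
            charges[index[(i, "CB")]] = signs[i]

    bonds, r0s = [], []
    for i in range(n_residues):
        for a, b in (("N", "CA"), ("CA", "C"), ("C", "O"), ("CA", "CB")):
            bonds.append((index[(i, a)], index[(i, b)]))
            r0s.append(B[(a, b)] if (a, b) in B else B[(b, a)])
        if i + 1 < n_residues:
            bonds.append((index[(i, "C")], index[(i + 1, "N")]))
            r0s.append(B[("C", "N")])
    bonds = np.array(bonds)
    bond_r0 = np.array(r0s)
    bond_k = np.full(len(bonds), P.BOND_K)

    # angles from the bond graph
    adj: dict[int, list[int]] = {a: [] for a in range(n_atoms)}
    for a, b in bonds:
        adj[int(a)].append(int(b))
        adj[int(b)].append(int(a))
    angles = []
    for j in range(n_atoms):
        nb = sorted(adj[j])
        for x in range(len(nb)):
            for y in range(x + 1, len(nb)):
                angles.append((nb[x], j, nb[y]))
    angles = np.array(angles)
    name_of = {v: k[1] for k, v in index.items()}
    theta0 = []
    for a, j, c in angles:
        key = (name_of[int(a)], name_of[int(j)], name_of[int(c)])
        th = P.ANGLE_THETA0.get(key) or P.ANGLE_THETA0.get(key[::-1]) or 111.0
        theta0.append(math.radians(th))
    angle_theta0 = np.array(theta0)
    angle_k = np.full(len(angles), P.ANGLE_K)

    # backbone dihedrals: phi, psi (soft threefold) and omega (stiff trans)
    dihedrals, mults, phases, ks = [], [], [], []
    for i in range(n_residues):
        if i > 0:
            dihedrals.append((index[(i - 1, "C")], index[(i, "N")],
                              index[(i, "CA")], index[(i, "C")]))  # phi
            mults.append(P.DIHEDRAL_SOFT["multiplicity"])
            phases.append(math.radians(P.DIHEDRAL_SOFT["phase_deg"]))
            ks.append(P.DIHEDRAL_SOFT["k"])
            dihedrals.append((index[(i - 1, "CA")], index[(i - 1, "C")],
                              index[(i, "N")], index[(i, "CA")]))  # omega
            mults.append(P.DIHEDRAL_OMEGA["multiplicity"])
            phases.append(math.radians(P.DIHEDRAL_OMEGA["phase_deg"]))
            ks.append(P.DIHEDRAL_OMEGA["k"])
        if i + 1 < n_residues:
            dihedrals.append((index[(i, "N")], index[(i, "CA")],
                              index[(i, "C")], index[(i + 1, "N")]))  # psi
            mults.append(P.DIHEDRAL_SOFT["multiplicity"])
            phases.append(math.radians(P.DIHEDRAL_SOFT["phase_deg"]))
            ks.append(P.DIHEDRAL_SOFT["k"])
    dihedrals = np.array(dihedrals) if dihedrals else np.zeros((0, 4), int)

    # exclusions: 1-2 and 1-3 pairs
    excl = set()
    for a, b in bonds:
        excl.add((min(a, b), max(a, b)))
    for a, j, c in angles:
        excl.add((min(a, c), max(a, c)))
    exclusions = np.array(sorted(excl))

    top = Topology(
        charges=charges,
        lj_types=lj_types,
        c6_table=c6_tab,
        c12_table=c12_tab,
        bonds=bonds,
        bond_r0=bond_r0,
        bond_k=bond_k,
        angles=angles,
        angle_theta0=angle_theta0,
        angle_k=angle_k,
        dihedrals=dihedrals,
        dihedral_mult=np.array(mults, dtype=np.int64),
        dihedral_phase=np.array(phases),
        dihedral_k=np.array(ks),
        exclusions=exclusions,
        atom_names=atom_names,
        elements=elements,
        resids=resids,
        resnames=resnames,
        mol_index=np.zeros(n_atoms, dtype=np.int32),
        head_atom=index[(0, "N")],
        tail_atom=index[(n_residues - 1, "C")],
    )
    return top, positions


# ---------------------------------------------------------------------------
# Position restraints
# ---------------------------------------------------------------------------

def position_restraint_energy_forces(
    positions: np.ndarray,
    reference: np.ndarray,
    force_constant_mj: float,
    mask: Optional[np.ndarray] = None,
) -> tuple[float, np.ndarray]:
    """Harmonic position restraints  E = sum 1/2 k |x - x_ref|^2.

    ``force_constant_mj`` is in MJ/(mol nm^2) — the unit the restraint
    protocol is specified in — and is converted to kJ/(mol nm^2)
    internally.  Returns (energy kJ/mol, forces).
    """
    positions = np.asarray(positions, dtype=np.float64)
    reference = np.asarray(reference, dtype=np.float64)
    if positions.shape != reference.shape:
        raise BuildError("restraint reference must match atom count")
    k = force_constant_mj * 1000.0
    disp = positions - reference
    if mask is not None:
        disp = disp * mask[:, None]
    energy = 0.5 * k * float((disp**2).sum())
    forces = -k * disp
    return energy, forces
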