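"""Simulation state, degree-of-freedom accounting and the kinetic-energy
partition of rigid water.

The central object is :class:`SimulationSystem`, which stores positions,
velocities and a rectangular periodic box together with a fixed atom
layout: solute atoms first, then water molecules as contiguous (O, H, H)
triplets, then monatomic ions.  That layout is what makes the
translational/rotational kinetic-energy split of the solvent — the basis
of the three-bath "microwave" thermostat — a cheap reshape instead of a
gather.

For a rigid three-site water the nine Cartesian degrees of freedom are
reduced to six by the two bond constraints and the angle constraint;
those six split into three translational (centre-of-mass) and three
rotational degrees of freedom.  The rotational kinetic energy is
computed as the residual (total molecular KE minus centre-of-mass KE),
which is exact for rigid molecules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Optional

import numpy as np

from .params import KB

if TYPE_CHECKING:  # pragma: no cover
    from .forcefield import Topology

__all__ = [
    "SimulationSystem",
    "BathSpec",
    "DofAccount",
    "partition_water_kinetic",
    "solute_kinetic_energy",
    "instantaneous_temperature",
    "count_dof",
]


class SystemError(ValueError):
    """Raised for invalid simulation-system states."""


BATH_SELECTORS = ("solute", "solvent_translational", "solvent_rotational")


@dataclass(frozen=True)
class BathSpec:
    """One weak-coupling heat bath.

    Parameters
    ----------
    selector:
        Which degrees of freedom the bath governs: ``"solute"``,
        ``"solvent_translational"`` or ``"solvent_rotational"``.
    target_temperature:
        Bath setpoint in K.
    coupling_time:
        Weak-coupling relaxation time tau in ps.
    """

    selector: str
    target_temperature: float
    coupling_time: float

    def __post_init__(self) -> None:
        if self.selector not in BATH_SELECTORS:
            raise ValueError(f"unknown bath selector {self.selector!r}")
        if not self.target_temperature > 0:
            raise ValueError("bath target temperature must be > 0")
        if not self.coupling_time > 0:
            raise ValueError("bath coupling time must be > 0")


@dataclass(frozen=True)
class DofAccount:
    """Degree-of-freedom bookkeeping for the three baths."""

    n_dof_solute: int
    n_dof_solvent_trans: int
    n_dof_solvent_rot: int


@dataclass
class SimulationSystem:
    """In-memory MD system with a fixed solute/water/ion atom layout.

    Atom order is ``[solute atoms][water triplets (O,H,H)...][ions]``.
    Positions are in nm, velocities in nm/ps, masses in u; the box is
    rectangular with edge lengths in nm.
    """

    positions: np.ndarray
    velocities: np.ndarray
    box: np.ndarray
    masses: np.ndarray
    n_solute: int
    n_waters: int
    n_ions: int = 0
    topology: Optional["Topology"] = None

    def __post_init__(self) -> None:
        self.positions = np.ascontiguousarray(self.positions, dtype=np.float64)
        self.velocities = np.ascontiguousarray(self.velocities, dtype=np.float64)
        self.box = np.asarray(self.box, dtype=np.float64).reshape(3)
        self.masses = np.asarray(self.masses, dtype=np.float64)
        self.validate()

    # -- layout helpers ---------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return self.positions.shape[0]

    @property
    def solute_slice(self) -> slice:
        return slice(0, self.n_solute)

    @property
    def water_slice(self) -> slice:
        return slice(self.n_solute, self.n_solute + 3 * self.n_waters)

    @property
    def ion_slice(self) -> slice:
        start = self.n_solute + 3 * self.n_waters
        return slice(start, start + self.n_ions)

    def molecule_kinds(self) -> np.ndarray:
        """Per-atom kind labels: 0 solute, 1 water, 2 ion."""
        kinds = np.empty(self.n_atoms, dtype=np.int8)
        kinds[self.solute_slice] = 0
        kinds[self.water_slice] = 1
        kinds[self.ion_slice] = 2
        return kinds

    def validate(self) -> None:
        n = self.positions.shape[0]
        if self.positions.shape != (n, 3) or self.velocities.shape != (n, 3):
            raise SystemError("positions and velocities must both be (n, 3)")
        if self.masses.shape != (n,):
            raise SystemError("masses must have one entry per atom")
        expected = self.n_solute + 3 * self.n_waters + self.n_ions
        if expected != n:
            raise SystemError(
                f"atom layout mismatch: {self.n_solute} solute + "
                f"3*{self.n_waters} water + {self.n_ions} ion != {n}"
            )
        if not np.all(self.box > 0):
            raise SystemError("box edges must be strictly positive")
        if not np.all(np.isfinite(self.positions)):
            raise SystemError("non-finite positions")

    def copy(self) -> "SimulationSystem":
        return SimulationSystem(
            positions=self.positions.copy(),
            velocities=self.velocities.copy(),
            box=self.box.copy(),
            masses=self.masses,
            n_solute=self.n_solute,
            n_waters=self.n_waters,
            n_ions=self.n_ions,
            topology=self.topology,
        )

    def wrapped_positions(self) -> np.ndarray:
        """Positions wrapped into [0, box) along each axis."""
        return np.mod(self.positions, self.box)


# ---------------------------------------------------------------------------
# Kinetic-energy partition
# ---------------------------------------------------------------------------

def _water_views(system: SimulationSystem):
    nw = system.n_waters
    v = system.velocities[system.water_slice].reshape(nw, 3, 3)
    m = system.masses[system.water_slice].reshape(nw, 3)
    return v, m


def partition_water_kinetic(system: SimulationSystem) -> tuple[float, float]:
    """Split the water kinetic energy into translational and rotational parts.

    Returns ``(ke_trans, ke_rot)`` in kJ/mol, where ``ke_trans`` is the
    centre-of-mass kinetic energy summed over water molecules and
    ``ke_rot`` the residual internal (rotational) kinetic energy.  For
    rigid molecules the residual is purely rotational, so this equals
    ``1/2 w^T I w`` without ever forming an inertia tensor.
    """
    if system.n_waters == 0:
        raise SystemError("system contains no water molecules")
    v, m = _water_views(system)
    mol_mass = m.sum(axis=1)
    if not np.all(mol_mass > 0):
        raise SystemError("non-positive water molecule mass")
    v_com = (m[:, :, None] * v).sum(axis=1) / mol_mass[:, None]
    ke_total = 0.5 * float((m * (v * v).sum(axis=2)).sum())
    ke_trans = 0.5 * float((mol_mass * (v_com * v_com).sum(axis=1)).sum())
    return ke_trans, ke_total - ke_trans


def solute_kinetic_energy(system: SimulationSystem) -> float:
    """Total kinetic energy of the solute atoms, kJ/mol."""
    v = system.velocities[system.solute_slice]
    m = system.masses[system.solute_slice]
    return 0.5 * float((m * (v * v).sum(axis=1)).sum())


def instantaneous_temperature(kinetic_energy: float, n_dof: int) -> float:
    """Equipartition temperature  T = 2 KE / (n_dof k_B)  in K."""
    if n_dof < 1:
        raise SystemError("temperature undefined for zero degrees of freedom")
    return 2.0 * kinetic_energy / (n_dof * KB)


def count_dof(
    system: SimulationSystem,
    n_solute_bond_constraints: int = 0,
    global_constraint_mode: str = "none",
) -> DofAccount:
    """Count the degrees of freedom governed by each heat bath.

    Each rigid three-site water contributes exactly six kinetic degrees
    of freedom, split 3 translational + 3 rotational.  The solute
    contributes ``3 N_solute`` minus its bond constraints minus the
    global constraints: 6 when roto-translational constraints are
    active, 3 when only centre-of-mass removal is active, 0 otherwise.
    Monatomic ions are counted with the translational solvent bath.
    """
    if global_constraint_mode not in ("none", "com", "rototranslational"):
        raise ValueError(f"unknown constraint mode {global_constraint_mode!r}")
    n_global = {"none": 0, "com": 3, "rototranslational": 6}[global_constraint_mode]
    n_dof_solute = 0
    n_trans = 3 * system.n_waters + 3 * system.n_ions
    if system.n_solute:
        n_dof_solute = 3 * system.n_solute - n_solute_bond_constraints - n_global
        if n_dof_solute < 0:
            raise SystemError("over-constrained solute: negative dof count")
    elif global_constraint_mode == "com":
        # no solute: centre-of-mass removal takes its 3 dof from the
        # translational motion of the solvent instead
        n_trans = max(n_trans - 3, 0)
    return DofAccount(
        n_dof_solute=n_dof_solute,
        n_dof_solvent_trans=n_trans,
        n_dof_solvent_rot=3 * system.n_waters,
    )
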