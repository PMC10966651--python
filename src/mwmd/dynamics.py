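"""Time propagation, constraints, and the three-bath weak-coupling thermostat.

The propagator is the leapfrog scheme

    v(t+dt/2) = v(t-dt/2) + F(t)/m dt
    x(t+dt)   = x(t) + v(t+dt/2) dt

with constraints applied to the updated positions (SETTLE for rigid
three-site water, SHAKE for solute bonds) and constrained velocities
recovered as (x_new - x_old)/dt.

Thermostatting follows the weak-coupling (Berendsen) scheme with three
independent baths: solute, solvent translation and solvent rotation.
Each bath rescales its velocities by

    lambda = sqrt(1 + (dt/tau) (T_target/T_inst - 1))

capped at 1.25 per step for stability with the short tau = 0.01 ps used
to pump the rotational bath.  Every water velocity is decomposed into
its centre-of-mass part and the internal (rotational) remainder, which
are scaled by the translational and rotational lambdas respectively and
recombined — this is what lets the model hold solvent rotation at 700 K
while translation stays at 300 K.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numba
import numpy as np

from .params import ATM_PER_KJ_MOL_NM3, KB, WATER_D_HH, WATER_D_OH
from .system import (
    BathSpec,
    DofAccount,
    SimulationSystem,
    instantaneous_temperature,
    partition_water_kinetic,
    solute_kinetic_energy,
)

__all__ = [
    "IntegratorParams",
    "BarostatParams",
    "leapfrog_step",
    "shake_constrain",
    "settle_water",
    "three_bath_thermostat",
    "remove_global_motion",
    "berendsen_barostat",
    "initialize_velocities",
    "steepest_descent_minimize",
    "run_md",
]

LAMBDA_MAX = 1.25


class DynamicsError(RuntimeError):
    pass


class ConstraintError(DynamicsError):
    pass


@dataclass(frozen=True)
class IntegratorParams:
    timestep: float = 0.002            # ps
    shake_tolerance: float = 1e-4      # relative geometric tolerance
    com_removal_interval: int = 1000   # steps; 0 disables
    rototranslational_constraints: bool = False

    def __post_init__(self) -> None:
        if not self.timestep > 0:
            raise ValueError("timestep must be positive")
        if not self.shake_tolerance > 0:
            raise ValueError("shake tolerance must be positive")


@dataclass(frozen=True)
class BarostatParams:
    target_pressure: float = 1.0               # atm
    coupling_time: float = 0.5                 # ps
    isothermal_compressibility: float = 4.5e-5  # 1/atm (water-like)

    def __post_init__(self) -> None:
        if min(self.target_pressure, self.coupling_time,
               self.isothermal_compressibility) <= 0:
            raise ValueError("barostat parameters must all be positive")


# ---------------------------------------------------------------------------
# SHAKE
# ---------------------------------------------------------------------------

@numba.njit(cache=True)
def _shake_kernel(ref, new, bonds, r0, invmass, tol, max_iter):
    nb = bonds.shape[0]
    for it in range(max_iter):
        converged = True
        for k in range(nb):
            i = bonds[k, 0]
            j = bonds[k, 1]
            dx = new[i, 0] - new[j, 0]
            dy = new[i, 1] - new[j, 1]
            dz = new[i, 2] - new[j, 2]
            d2 = dx * dx + dy * dy + dz * dz
            target2 = r0[k] * r0[k]
            diff = d2 - target2
            # |r - r0|/r0 <= tol  <=>  |d2 - r0^2| <= r0^2 (2 tol + tol^2)
            if abs(diff) > target2 * (2.0 * tol + tol * tol):
                converged = False
                rx = ref[i, 0] - ref[j, 0]
                ry = ref[i, 1] - ref[j, 1]
                rz = ref[i, 2] - ref[j, 2]
                dot = dx * rx + dy * ry + dz * rz
                if abs(dot) < 1e-12:
                    return -(k + 1)  # pathological geometry
                g = diff / (2.0 * (invmass[i] + invmass[j]) * dot)
                new[i, 0] -= g * invmass[i] * rx
                new[i, 1] -= g * invmass[i] * ry
                new[i, 2] -= g * invmass[i] * rz
                new[j, 0] += g * invmass[j] * rx
                new[j, 1] += g * invmass[j] * ry
                new[j, 2] += g * invmass[j] * rz
        if converged:
            return it + 1
    return 0  # not converged


def shake_constrain(
    positions_ref: np.ndarray,
    positions_new: np.ndarray,
    bonds: np.ndarray,
    bond_r0: np.ndarray,
    masses: np.ndarray,
    tolerance: float = 1e-4,
    max_iterations: int = 500,
) -> np.ndarray:
    """Iteratively project ``positions_new`` onto the bond-length manifold.

    ``positions_ref`` must satisfy the constraints; corrections act along
    the reference bond directions weighted by inverse masses, which is
    the classic SHAKE update.  Returns the corrected positions (modified
    in place).  Raises :class:`ConstraintError` on non-convergence.
    """
    bonds = np.ascontiguousarray(bonds, dtype=np.int64).reshape(-1, 2)
    if bonds.shape[0] == 0:
        return positions_new
    status = _shake_kernel(
        np.ascontiguousarray(positions_ref),
        positions_new,
        bonds,
        np.ascontiguousarray(bond_r0, dtype=np.float64),
        np.ascontiguousarray(1.0 / masses),
        tolerance,
        max_iterations,
    )
    if status == 0:
        raise ConstraintError(
            f"SHAKE failed to converge in {max_iterations} iterations"
        )
    if status < 0:
        k = -status - 1
        raise ConstraintError(
            f"SHAKE degenerate geometry for bond {bonds[k, 0]}-{bonds[k, 1]}"
        )
    return positions_new


# ---------------------------------------------------------------------------
# SETTLE
# ---------------------------------------------------------------------------

@numba.njit(cache=True)
def _settle_kernel(ref, new, m_o, m_h, ra, rb, rc):
    """Analytic SETTLE for rigid three-site water (O, H, H per molecule).

    ref/new have shape (n_waters, 3, 3).  Returns the number of
    molecules routed to the degenerate-geometry fallback (handled by
    the caller with SHAKE).
    """
    n = ref.shape[0]
    inv_m = 1.0 / (m_o + 2.0 * m_h)
    n_fallback = 0
    for w in range(n):
        # reference in-plane vectors
        b0x = ref[w, 1, 0] - ref[w, 0, 0]
        b0y = ref[w, 1, 1] - ref[w, 0, 1]
        b0z = ref[w, 1, 2] - ref[w, 0, 2]
        c0x = ref[w, 2, 0] - ref[w, 0, 0]
        c0y = ref[w, 2, 1] - ref[w, 0, 1]
        c0z = ref[w, 2, 2] - ref[w, 0, 2]
        # centre of mass of the unconstrained new positions
        dx = (m_o * new[w, 0, 0] + m_h * (new[w, 1, 0] + new[w, 2, 0])) * inv_m
        dy = (m_o * new[w, 0, 1] + m_h * (new[w, 1, 1] + new[w, 2, 1])) * inv_m
        dz = (m_o * new[w, 0, 2] + m_h * (new[w, 1, 2] + new[w, 2, 2])) * inv_m
        a1x = new[w, 0, 0] - dx
        a1y = new[w, 0, 1] - dy
        a1z = new[w, 0, 2] - dz
        b1x = new[w, 1, 0] - dx
        b1y = new[w, 1, 1] - dy
        b1z = new[w, 1, 2] - dz
        c1x = new[w, 2, 0] - dx
        c1y = new[w, 2, 1] - dy
        c1z = new[w, 2, 2] - dz
        # orthonormal primed frame: n0 normal to ref plane, a1 in n2-n0 plane
        n0x = b0y * c0z - b0z * c0y
        n0y = b0z * c0x - b0x * c0z
        n0z = b0x * c0y - b0y * c0x
        n1x = a1y * n0z - a1z * n0y
        n1y = a1z * n0x - a1x * n0z
        n1z = a1x * n0y - a1y * n0x
        n2x = n0y * n1z - n0z * n1y
        n2y = n0z * n1x - n0x * n1z
        n2z = n0x * n1y - n0y * n1x
        n0n = np.sqrt(n0x * n0x + n0y * n0y + n0z * n0z)
        n1n = np.sqrt(n1x * n1x + n1y * n1y + n1z * n1z)
        n2n = np.sqrt(n2x * n2x + n2y * n2y + n2z * n2z)
        if n0n < 1e-12 or n1n < 1e-12 or n2n < 1e-12:
            n_fallback += 1
            new[w, 0, 0] = np.nan  # flag for caller
            continue
        n0x /= n0n; n0y /= n0n; n0z /= n0n
        n1x /= n1n; n1y /= n1n; n1z /= n1n
        n2x /= n2n; n2y /= n2n; n2z /= n2n
        # transform into the primed frame (x' = n1, y' = n2, z' = n0)
        b0px = n1x * b0x + n1y * b0y + n1z * b0z
        b0py = n2x * b0x + n2y * b0y + n2z * b0z
        c0px = n1x * c0x + n1y * c0y + n1z * c0z
        c0py = n2x * c0x + n2y * c0y + n2z * c0z
        a1pz = n0x * a1x + n0y * a1y + n0z * a1z
        b1px = n1x * b1x + n1y * b1y + n1z * b1z
        b1py = n2x * b1x + n2y * b1y + n2z * b1z
        b1pz = n0x * b1x + n0y * b1y + n0z * b1z
        c1px = n1x * c1x + n1y * c1y + n1z * c1z
        c1py = n2x * c1x + n2y * c1y + n2z * c1z
        c1pz = n0x * c1x + n0y * c1y + n0z * c1z
        # canonical water after the phi/psi tilts
        sinphi = a1pz / ra
        t = 1.0 - sinphi * sinphi
        if t < 0.0:
            t = 0.0
        cosphi = np.sqrt(t)
        sinpsi = (b1pz - c1pz) / (2.0 * rc * cosphi) if cosphi > 1e-12 else 0.0
        t = 1.0 - sinpsi * sinpsi
        if t < 0.0:
            t = 0.0
        cospsi = np.sqrt(t)
        ya2 = ra * cosphi
        xb2 = -rc * cospsi
        t1 = -rb * cosphi
        t2 = rc * sinpsi * sinphi
        t3 = rc * sinpsi * cosphi
        yb2 = t1 - t2
        yc2 = t1 + t2
        # rotation theta about the primed z-axis
        alpha = xb2 * (b0px - c0px) + b0py * yb2 + c0py * yc2
        beta = xb2 * (c0py - b0py) + b0px * yb2 + c0px * yc2
        gamma = b0px * b1py - b1px * b0py + c0px * c1py - c1px * c0py
        a2b2 = alpha * alpha + beta * beta
        under = a2b2 - gamma * gamma
        if under < 0.0:
            under = 0.0
        sintheta = (alpha * gamma - beta * np.sqrt(under)) / a2b2
        t = 1.0 - sintheta * sintheta
        if t < 0.0:
            t = 0.0
        costheta = np.sqrt(t)
        a3x = -ya2 * sintheta
        a3y = ya2 * costheta
        a3z = a1pz
        b3x = xb2 * costheta - yb2 * sintheta
        b3y = xb2 * sintheta + yb2 * costheta
        b3z = b1pz
        c3x = -xb2 * costheta - yc2 * sintheta
        c3y = -xb2 * sintheta + yc2 * costheta
        c3z = c1pz
        # back-transform and restore the centre of mass
        new[w, 0, 0] = n1x * a3x + n2x * a3y + n0x * a3z + dx
        new[w, 0, 1] = n1y * a3x + n2y * a3y + n0y * a3z + dy
        new[w, 0, 2] = n1z * a3x + n2z * a3y + n0z * a3z + dz
        new[w, 1, 0] = n1x * b3x + n2x * b3y + n0x * b3z + dx
        new[w, 1, 1] = n1y * b3x + n2y * b3y + n0y * b3z + dy
        new[w, 1, 2] = n1z * b3x + n2z * b3y + n0z * b3z + dz
        new[w, 2, 0] = n1x * c3x + n2x * c3y + n0x * c3z + dx
        new[w, 2, 1] = n1y * c3x + n2y * c3y + n0y * c3z + dy
        new[w, 2, 2] = n1z * c3x + n2z * c3y + n0z * c3z + dz
    return n_fallback


def water_canonical_radii(
    m_o: float, m_h: float, d_oh: float = WATER_D_OH, d_hh: float = WATER_D_HH
) -> tuple[float, float, float]:
    """(ra, rb, rc): O and H distances from the molecular COM in the
    canonical frame, and half the H-H separation."""
    rc = 0.5 * d_hh
    t = np.sqrt(d_oh**2 - rc**2)  # O to H-midpoint distance
    ra = 2.0 * m_h * t / (m_o + 2.0 * m_h)
    rb = t - ra
    return float(ra), float(rb), rc


def settle_water(
    positions_ref: np.ndarray,
    positions_new: np.ndarray,
    m_o: float,
    m_h: float,
    d_oh: float = WATER_D_OH,
    d_hh: float = WATER_D_HH,
) -> np.ndarray:
    """Analytic constraint projection for rigid three-site waters.

    Both inputs have shape (n_waters, 3, 3) with site order (O, H, H);
    the reference frames must satisfy the rigid geometry.  Degenerate
    trial geometries (new O aligned with the reference-plane normal)
    fall back to converged SHAKE on the three distance constraints.
    """
    ref = np.ascontiguousarray(positions_ref, dtype=np.float64)
    new = np.ascontiguousarray(positions_new, dtype=np.float64)
    ra, rb, rc = water_canonical_radii(m_o, m_h, d_oh, d_hh)
    n_fallback = _settle_kernel(ref, new, m_o, m_h, ra, rb, rc)
    if n_fallback:
        bad = np.nonzero(np.isnan(new[:, 0, 0]))[0]
        bonds = np.array([[0, 1], [0, 2], [1, 2]])
        r0 = np.array([d_oh, d_oh, d_hh])
        masses = np.array([m_o, m_h, m_h])
        for w in bad:
            new[w] = positions_new[w]
            shake_constrain(ref[w], new[w], bonds, r0, masses,
                            tolerance=1e-10, max_iterations=5000)
    return new


# ---------------------------------------------------------------------------
# Leapfrog with constraints
# ---------------------------------------------------------------------------

def _apply_constraints(
    system: SimulationSystem,
    old_positions: np.ndarray,
    params: IntegratorParams,
    constrain_solute: bool,
) -> None:
    """Project updated positions onto the constraint manifold and repair
    the velocities of constrained atoms as (x_new - x_old)/dt."""
    dt = params.timestep
    if system.n_waters:
        ws = system.water_slice
        nw = system.n_waters
        m = system.masses[ws]
        ref = old_positions[ws].reshape(nw, 3, 3)
        trial = system.positions[ws].reshape(nw, 3, 3)
        fixed = settle_water(ref, trial, float(m[0]), float(m[1]))
        system.positions[ws] = fixed.reshape(-1, 3)
        system.velocities[ws] = (system.positions[ws] - old_positions[ws]) / dt
    if constrain_solute and system.n_solute and system.topology is not None:
        top = system.topology
        sol = np.nonzero(
            (top.bonds[:, 0] < system.n_solute) & (top.bonds[:, 1] < system.n_solute)
        )[0]
        if len(sol):
            shake_constrain(
                old_positions,
                system.positions,
                top.bonds[sol],
                top.bond_r0[sol],
                system.masses,
                tolerance=params.shake_tolerance,
            )
            ss = system.solute_slice
            system.velocities[ss] = (system.positions[ss] - old_positions[ss]) / dt


def leapfrog_step(
    system: SimulationSystem,
    forces: np.ndarray,
    params: IntegratorParams,
    constrain_solute: bool = True,
) -> SimulationSystem:
    """One leapfrog step (in place): velocity half-kick convention with
    constraints applied after the position update."""
    if not np.all(np.isfinite(forces)):
        raise DynamicsError("non-finite force encountered")
    dt = params.timestep
    old = system.positions.copy()
    system.velocities += forces / system.masses[:, None] * dt
    system.positions += system.velocities * dt
    _apply_constraints(system, old, params, constrain_solute)
    return system


# ---------------------------------------------------------------------------
# Thermostat and global-motion removal
# ---------------------------------------------------------------------------

def _bath_lambda(t_inst: float, t_target: float, dt: float, tau: float,
                 lambda_max: float = LAMBDA_MAX) -> float:
    """Weak-coupling scale factor; capped (default 1.25/step) so that a
    cold or empty bath cannot blow the velocities up."""
    if t_inst <= 0.0:
        return lambda_max
    lam2 = 1.0 + (dt / tau) * (t_target / t_inst - 1.0)
    if lam2 <= 0.0:
        return 0.0
    return min(np.sqrt(lam2), lambda_max)


def three_bath_thermostat(
    system: SimulationSystem,
    baths: dict[str, BathSpec],
    dof: DofAccount,
    timestep: float,
) -> tuple[float, float, float]:
    """Weak-coupling velocity scaling toward the three bath setpoints.

    Returns the instantaneous (pre-scaling) temperatures
    ``(T_solute, T_trans, T_rot)``; entries are 0.0 for absent baths.
    Solute velocities are scaled directly; each water velocity is split
    into COM + internal parts which are scaled independently.
    """
    dt = timestep
    t_sol = t_tr = t_rot = 0.0
    if system.n_solute and dof.n_dof_solute > 0 and "solute" in baths:
        ke = solute_kinetic_energy(system)
        t_sol = instantaneous_temperature(ke, dof.n_dof_solute)
        b = baths["solute"]
        lam = _bath_lambda(t_sol, b.target_temperature, dt, b.coupling_time)
        system.velocities[system.solute_slice] *= lam
    if system.n_waters:
        ke_tr, ke_rot = partition_water_kinetic(system)
        t_tr = instantaneous_temperature(ke_tr, dof.n_dof_solvent_trans)
        t_rot = instantaneous_temperature(ke_rot, dof.n_dof_solvent_rot)
        b_tr = baths["solvent_translational"]
        b_rot = baths["solvent_rotational"]
        lam_tr = _bath_lambda(t_tr, b_tr.target_temperature, dt, b_tr.coupling_time)
        lam_rot = _bath_lambda(t_rot, b_rot.target_temperature, dt, b_rot.coupling_time)
        ws = system.water_slice
        nw = system.n_waters
        v = system.velocities[ws].reshape(nw, 3, 3)
        m = system.masses[ws].reshape(nw, 3)
        mol_mass = m.sum(axis=1)
        v_com = (m[:, :, None] * v).sum(axis=1) / mol_mass[:, None]
        v_int = v - v_com[:, None, :]
        system.velocities[ws] = (
            lam_tr * v_com[:, None, :] + lam_rot * v_int
        ).reshape(-1, 3)
        if system.n_ions:
            system.velocities[system.ion_slice] *= lam_tr
    return t_sol, t_tr, t_rot


def remove_global_motion(
    system: SimulationSystem,
    mode: str = "com_only",
    scope: str = "all",
) -> SimulationSystem:
    """Remove net linear (and for ``roto_translational`` also angular)
    momentum from the chosen scope (``"all"`` atoms or the ``"solute"``)."""
    if mode not in ("com_only", "roto_translational"):
        raise ValueError(f"unknown mode {mode!r}")
    sel = slice(0, system.n_atoms) if scope == "all" else system.solute_slice
    m = system.masses[sel]
    if m.size == 0:
        return system
    v = system.velocities[sel]
    x = system.positions[sel]
    total_m = m.sum()
    v_com = (m[:, None] * v).sum(axis=0) / total_m
    v -= v_com
    if mode == "roto_translational":
        x_com = (m[:, None] * x).sum(axis=0) / total_m
        r = x - x_com
        ang_mom = (m[:, None] * np.cross(r, v)).sum(axis=0)
        r2 = (r * r).sum(axis=1)
        inertia = np.diag((m * r2).sum() * np.ones(3)) - np.einsum(
            "i,ij,ik->jk", m, r, r
        )
        # guard against singular inertia (collinear scope)
        try:
            omega = np.linalg.solve(inertia, ang_mom)
        except np.linalg.LinAlgError:
            omega = np.linalg.lstsq(inertia, ang_mom, rcond=None)[0]
        v -= np.cross(omega, r)
    system.velocities[sel] = v
    return system


def berendsen_barostat(
    system: SimulationSystem,
    pressure_inst: float,
    params: BarostatParams,
    timestep: float,
) -> float:
    """Isotropic weak-coupling pressure scaling.

    ``pressure_inst`` is in atm.  Box edges are scaled by mu and
    coordinates are scaled per molecule centre of mass (internal
    geometries, including rigid waters, are preserved so constraints
    stay satisfied).  Returns the applied mu.
    """
    mu3 = 1.0 - (timestep / params.coupling_time) * \
        params.isothermal_compressibility * (params.target_pressure - pressure_inst)
    mu = np.cbrt(max(mu3, 1e-12))
    mu = min(max(mu, 0.95), 1.05)
    system.box *= mu
    # molecule-COM scaling: solute as one unit, each water as one unit, ions per atom
    if system.n_solute:
        ss = system.solute_slice
        m = system.masses[ss]
        com = (m[:, None] * system.positions[ss]).sum(axis=0) / m.sum()
        system.positions[ss] += (mu - 1.0) * com
    if system.n_waters:
        ws = system.water_slice
        nw = system.n_waters
        x = system.positions[ws].reshape(nw, 3, 3)
        m = system.masses[ws].reshape(nw, 3)
        com = (m[:, :, None] * x).sum(axis=1) / m.sum(axis=1)[:, None]
        x += (mu - 1.0) * com[:, None, :]
        system.positions[ws] = x.reshape(-1, 3)
    if system.n_ions:
        system.positions[system.ion_slice] *= mu
    return float(mu)


# ---------------------------------------------------------------------------
# Velocity initialization
# ---------------------------------------------------------------------------

def _project_rigid_waters(system: SimulationSystem) -> None:
    """Replace each water's velocity by its best-fit rigid-body motion,
    making the time derivative of every constraint exactly zero."""
    if system.n_waters == 0:
        return
    ws = system.water_slice
    nw = system.n_waters
    v = system.velocities[ws].reshape(nw, 3, 3)
    x = system.positions[ws].reshape(nw, 3, 3)
    m = system.masses[ws].reshape(nw, 3)
    mol_mass = m.sum(axis=1)
    v_com = (m[:, :, None] * v).sum(axis=1) / mol_mass[:, None]
    x_com = (m[:, :, None] * x).sum(axis=1) / mol_mass[:, None]
    r = x - x_com[:, None, :]
    ang_mom = (m[:, :, None] * np.cross(r, v - v_com[:, None, :])).sum(axis=1)
    r2 = (r * r).sum(axis=2)
    eye = np.eye(3)
    inertia = (m * r2).sum(axis=1)[:, None, None] * eye - np.einsum(
        "wi,wij,wik->wjk", m, r, r
    )
    # water is planar but never collinear; the inertia tensor is regular
    omega = np.linalg.solve(inertia, ang_mom[:, :, None])[:, :, 0]
    v_rigid = v_com[:, None, :] + np.cross(omega[:, None, :], r)
    system.velocities[ws] = v_rigid.reshape(-1, 3)


def _project_solute_bonds(system: SimulationSystem, n_sweeps: int = 50) -> None:
    """Iteratively remove relative velocity along constrained solute bonds."""
    top = system.topology
    if top is None or system.n_solute == 0 or len(top.bonds) == 0:
        return
    sel = (top.bonds[:, 0] < system.n_solute) & (top.bonds[:, 1] < system.n_solute)
    bonds = top.bonds[sel]
    inv_m = 1.0 / system.masses
    for _ in range(n_sweeps):
        worst = 0.0
        for i, j in bonds:
            d = system.positions[i] - system.positions[j]
            dv = system.velocities[i] - system.velocities[j]
            proj = float(d @ dv)
            worst = max(worst, abs(proj))
            g = proj / (float(d @ d) * (inv_m[i] + inv_m[j]))
            system.velocities[i] -= g * inv_m[i] * d
            system.velocities[j] += g * inv_m[j] * d
        if worst < 1e-12:
            break


def initialize_velocities(
    system: SimulationSystem, temperature: float, seed: int
) -> SimulationSystem:
    """Maxwell-Boltzmann velocities at the given temperature.

    After the draw, water velocities are projected onto rigid-body
    motion, constrained solute bonds get their relative bond-direction
    velocities removed, and the overall centre-of-mass drift is
    subtracted.  The draw is reproducible from the seed.
    """
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(KB * temperature / system.masses)
    system.velocities = rng.standard_normal((system.n_atoms, 3)) * sigma[:, None]
    _project_rigid_waters(system)
    _project_solute_bonds(system)
    remove_global_motion(system, "com_only", "all")
    return system


# ---------------------------------------------------------------------------
# Steepest-descent minimization
# ---------------------------------------------------------------------------

def steepest_descent_minimize(
    system: SimulationSystem,
    evaluator,
    initial_step: float = 0.01,
    max_step: float = 0.05,
    energy_threshold: float = 0.001,
    max_steps: int = 1000,
) -> dict:
    """Adaptive steepest descent: move along the normalized force
    direction (largest per-atom displacement = current step size), grow
    the step by 1.2 on accepted moves, halve it on rejections.

    Rigid waters are re-projected with SETTLE after every trial move, so
    minimization never distorts the constrained solvent geometry.
    Terminates when the energy change of an accepted move falls below
    ``energy_threshold`` (kJ/mol) or the step budget is exhausted.
    Returns an info dict with ``converged``, ``n_steps`` and ``energy``;
    the system is updated in place and the final energy never exceeds
    the initial one.
    """

    def _settle_trial(trial: np.ndarray, current: np.ndarray) -> np.ndarray:
        if system.n_waters == 0:
            return trial
        ws = system.water_slice
        nw = system.n_waters
        m = system.masses[ws]
        fixed = settle_water(
            current[ws].reshape(nw, 3, 3),
            trial[ws].reshape(nw, 3, 3).copy(),
            float(m[0]), float(m[1]),
        )
        trial = trial.copy()
        trial[ws] = fixed.reshape(-1, 3)
        return trial

    energy = evaluator.potential_energy(system)
    if not np.isfinite(energy):
        raise DynamicsError("non-finite initial energy")
    step = initial_step
    n_done = 0
    converged = False
    for n_done in range(1, max_steps + 1):
        _, forces, _ = evaluator.energy_forces(system)
        fmax = np.abs(forces).max()
        if fmax < 1e-8:  # kJ/(mol nm): the configuration is stationary
            converged = True
            break
        trial = system.positions + step * forces / fmax
        trial = _settle_trial(trial, system.positions)
        saved = system.positions
        system.positions = trial
        e_trial = evaluator.potential_energy(system)
        if abs(e_trial - energy) < energy_threshold:
            # converged: keep whichever configuration is lower in energy
            if e_trial >= energy:
                system.positions = saved
            else:
                energy = e_trial
            converged = True
            break
        if e_trial < energy:
            energy = e_trial
            step = min(step * 1.2, max_step)
        else:
            system.positions = saved
            step *= 0.5
            if step < 1e-8:
                break
    return {"converged": converged, "n_steps": n_done, "energy": energy}


# ---------------------------------------------------------------------------
# MD driver
# ---------------------------------------------------------------------------

def run_md(
    system: SimulationSystem,
    evaluator,
    baths: dict[str, BathSpec],
    dof: DofAccount,
    n_steps: int,
    params: IntegratorParams,
    constrain_solute: bool = True,
    barostat: Optional[BarostatParams] = None,
    sample_interval: int = 10,
    on_sample: Optional[Callable] = None,
    start_time: float = 0.0,
) -> dict:
    """Propagate ``n_steps`` of thermostatted leapfrog dynamics in place.

    Per step: forces -> leapfrog + constraints -> scheduled COM removal
    -> roto-translational removal (if enabled) -> three-bath scaling ->
    optional pressure coupling.  Returns a report with sampled time
    series of bath temperatures, energies and (if coupled) pressure.
    The loop is fully deterministic, which is what makes checkpointed
    restarts bit-identical.
    """
    dt = params.timestep
    times, t_sol_s, t_tr_s, t_rot_s, epot_s, ekin_s, press_s = ([] for _ in range(7))
    volume = float(np.prod(system.box))
    for step in range(1, n_steps + 1):
        breakdown, forces, virial = evaluator.energy_forces(system)
        pre_constraint = None
        if barostat is not None:
            pre_constraint = system.positions + \
                (system.velocities + forces / system.masses[:, None] * dt) * dt
        leapfrog_step(system, forces, params, constrain_solute)
        if params.com_removal_interval and step % params.com_removal_interval == 0:
            remove_global_motion(system, "com_only", "all")
        if params.rototranslational_constraints and system.n_solute:
            remove_global_motion(system, "roto_translational", "solute")
        t_sol, t_tr, t_rot = three_bath_thermostat(system, baths, dof, dt)
        if barostat is not None:
            # constraint-force virial from the position corrections
            delta = system.positions - pre_constraint
            fc = system.masses[:, None] * delta / dt**2
            w_constr = _molecular_virial(system, fc)
            ke = 0.5 * float(
                (system.masses * (system.velocities**2).sum(axis=1)).sum()
            )
            volume = float(np.prod(system.box))
            p_inst = (2.0 * ke + virial + w_constr) / (3.0 * volume) \
                * ATM_PER_KJ_MOL_NM3
            berendsen_barostat(system, p_inst, barostat, dt)
        else:
            p_inst = np.nan
        if step % sample_interval == 0:
            times.append(start_time + step * dt)
            t_sol_s.append(t_sol)
            t_tr_s.append(t_tr)
            t_rot_s.append(t_rot)
            epot_s.append(breakdown.total_potential)
            ke = 0.5 * float(
                (system.masses * (system.velocities**2).sum(axis=1)).sum()
            )
            ekin_s.append(ke)
            press_s.append(p_inst)
            if on_sample is not None:
                on_sample(start_time + step * dt, system, breakdown)
    return {
        "time": np.array(times),
        "t_solute": np.array(t_sol_s),
        "t_trans": np.array(t_tr_s),
        "t_rot": np.array(t_rot_s),
        "e_potential": np.array(epot_s),
        "e_kinetic": np.array(ekin_s),
        "pressure": np.array(press_s),
    }


def _molecular_virial(system: SimulationSystem, forces: np.ndarray) -> float:
    """sum_i f_i . (r_i - r_com(mol_i)) for intramolecular (constraint)
    forces; zero for monatomic species."""
    w = 0.0
    if system.n_solute:
        ss = system.solute_slice
        m = system.masses[ss]
        com = (m[:, None] * system.positions[ss]).sum(axis=0) / m.sum()
        w += float((forces[ss] * (system.positions[ss] - com)).sum())
    if system.n_waters:
        ws = system.water_slice
        nw = system.n_waters
        x = system.positions[ws].reshape(nw, 3, 3)
        f = forces[ws].reshape(nw, 3, 3)
        m = system.masses[ws].reshape(nw, 3)
        com = (m[:, :, None] * x).sum(axis=1) / m.sum(axis=1)[:, None]
        w += float((f * (x - com[:, None, :])).sum())
    return w
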