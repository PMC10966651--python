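"""Shared fixtures.

The expensive simulations (thermostat setpoint runs, the paired
equilibrium/microwave condition runs) are session-scoped and shared by
the unit tests and the acceptance tests, so each is run exactly once
per session.  Desk-scale cutoffs are half the smallest box edge, capped
at the protocol's 1.4 nm reference value.
"""

from __future__ import annotations

import numpy as np
import pytest

import mwmd
from mwmd.dynamics import initialize_velocities
from mwmd.forcefield import ForceEvaluator, ReactionFieldParams, Topology
from mwmd.io import Trajectory
from mwmd.protocol import ConditionSpec, run_production
from mwmd.system import SimulationSystem


def desk_cutoff(system: SimulationSystem, preferred: float = 0.9) -> float:
    """Largest admissible cutoff for a small periodic box."""
    return min(1.4, preferred, 0.5 * float(system.box.min()) - 0.01)


def make_point_topology(n_atoms: int = 1, charge: float = 0.0) -> Topology:
    """Minimal topology: n unconnected neutral nitrogen-like beads."""
    z = np.zeros(0)
    return Topology(
        charges=np.full(n_atoms, charge),
        lj_types=np.zeros(n_atoms, dtype=int),
        c6_table=np.array([[2.4e-3]]),
        c12_table=np.array([[2.3e-6]]),
        bonds=np.zeros((0, 2), int), bond_r0=z, bond_k=z,
        angles=np.zeros((0, 3), int), angle_theta0=z, angle_k=z,
        dihedrals=np.zeros((0, 4), int), dihedral_mult=np.zeros(0, int),
        dihedral_phase=z, dihedral_k=z,
        exclusions=np.zeros((0, 2), int),
        atom_names=["N"] * n_atoms, elements=["N"] * n_atoms,
        resids=np.zeros(n_atoms, dtype=np.int32),
        resnames=["GLY"] * n_atoms,
    )


def make_bare_system(positions, box, charges=None) -> SimulationSystem:
    """Solute-only system of unconnected beads, for pair-list tests."""
    positions = np.asarray(positions, dtype=np.float64)
    n = positions.shape[0]
    top = make_point_topology(n)
    if charges is not None:
        top.charges = np.asarray(charges, dtype=np.float64)
    return SimulationSystem(
        positions=positions,
        velocities=np.zeros_like(positions),
        box=np.asarray(box, dtype=np.float64),
        masses=np.full(n, 14.0),
        n_solute=n,
        n_waters=0,
        topology=top,
    )


@pytest.fixture(scope="session")
def water_box_216():
    """Minimized 216-water box with its evaluator; copy before mutating."""
    system = mwmd.build_water_box(216, seed=2)
    ev = ForceEvaluator(
        system.topology, ReactionFieldParams(desk_cutoff(system), 61.0)
    )
    mwmd.steepest_descent_minimize(system, ev, energy_threshold=0.01,
                                   max_steps=300)
    return system, ev


@pytest.fixture(scope="session")
def mw_setpoint_run(water_box_216):
    """Microwave-condition setpoint run: 216 waters, 20 ps settling then
    50 ps of production under baths (300 trans, 700 rot) K."""
    base, ev = water_box_216
    system = base.copy()
    initialize_velocities(system, 300.0, seed=3)
    run_production(system, ConditionSpec.equilibrium(), ev, 10.0,
                   report_interval_ps=1.0)
    run_production(system, ConditionSpec.microwave(), ev, 10.0,
                   report_interval_ps=1.0)
    rep = run_production(system, ConditionSpec.microwave(), ev, 50.0,
                         report_interval_ps=0.02)
    return {
        "t_rot": float(rep["t_rot"].mean()),
        "t_trans": float(rep["t_trans"].mean()),
    }


def _condition_stats(trajectory, system):
    hb = []
    for frame in trajectory.frames[::2]:
        _, _, pw = mwmd.hbond_statistics(
            frame.positions, system.topology, system.n_solute,
            system.n_waters, box=frame.box,
        )
        hb.append(pw)
    return {
        "n_hb_pw": float(np.mean(hb)),
        "e_es_pw": float(np.mean([f.energy.e_es_pw for f in trajectory.frames])),
        "e_vdw_pw": float(np.mean([f.energy.e_vdw_pw for f in trajectory.frames])),
    }


@pytest.fixture(scope="session")
def paired_condition_runs():
    """Toy peptide in >300 waters: equilibrium and microwave production,
    50 ps each, for three velocity seeds sharing one minimized build.

    Both condition legs of a seed branch from the same settled state, so
    any residual slow equilibration of the solute-water interface
    cancels in the paired comparison instead of confounding it.
    Returns per-seed statistics (solute-water hydrogen bonds and
    energies) plus the bath-temperature report of each leg.
    """
    top, pos = mwmd.make_toy_solute("helix_like", 8, seed=11)
    built = mwmd.solvate(top, pos, mwmd.SolvationSpec(wall_distance=0.55),
                         seed=11)
    built = mwmd.add_ions(built, mwmd.IonSpec(0.15, seed=11))
    assert built.n_waters >= 300
    ev = ForceEvaluator(
        built.topology, ReactionFieldParams(desk_cutoff(built), 61.0)
    )
    mwmd.steepest_descent_minimize(built, ev, energy_threshold=0.01,
                                   max_steps=300)
    results = []
    for seed in (21, 22, 23):
        settled = built.copy()
        initialize_velocities(settled, 300.0, seed=seed)
        run_production(settled, ConditionSpec.equilibrium(), ev, 12.0,
                       report_interval_ps=1.0)
        per_seed = {"seed": seed}
        for name, cond in (("eq", ConditionSpec.equilibrium()),
                           ("mw", ConditionSpec.microwave())):
            system = settled.copy()
            run_production(system, cond, ev, 4.0, report_interval_ps=1.0)
            traj = Trajectory()
            rep = run_production(system, cond, ev, 50.0,
                                 report_interval_ps=0.1, trajectory=traj)
            stats = _condition_stats(traj, system)
            stats["t_solute"] = float(rep["t_solute"].mean())
            stats["t_trans"] = float(rep["t_trans"].mean())
            stats["t_rot"] = float(rep["t_rot"].mean())
            per_seed[name] = stats
        results.append(per_seed)
    return {"system": built, "runs": results}
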