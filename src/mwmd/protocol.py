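"""Staged equilibration schedule and production-run driver.

The equilibration protocol heats a freshly built system from 50 to
300 K in 50 K increments, one 20 ps cycle (10,000 steps at 2 fs) per
increment, while a harmonic position restraint on the solute decays by
a factor of ten per cycle from 25 MJ/(mol nm^2).  Under the microwave
condition an extra cycle raising the solvent-rotational bath to 700 K
is inserted after the ladder.  The final two cycles switch on
roto-translational constraints on the solute and pressure coupling to
1 atm, giving 160 ps (equilibrium) or 180 ps (microwave) in total.
Production is constant-volume, constant-bath dynamics with the
condition's three setpoints.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import (
    BarostatParams,
    IntegratorParams,
    remove_global_motion,
    run_md,
)
from .forcefield import EnergyBreakdown, ForceEvaluator
from .system import BathSpec, SimulationSystem, count_dof

__all__ = [
    "ScheduleCycle",
    "ConditionSpec",
    "build_equilibration_schedule",
    "run_schedule",
    "run_production",
    "condition_baths",
]

HEATING_LADDER = (50.0, 100.0, 150.0, 200.0, 250.0, 300.0)
DEFAULT_TAU = 0.01  # ps
MW_ROT_TEMPERATURE = 700.0  # K
RESTRAINT_START = 25.0  # MJ/(mol nm^2)
RESTRAINT_DECAY = 0.1  # multiplicative, per cycle
CYCLE_STEPS = 10_000
COM_REMOVAL_INTERVAL = 1000  # steps


class ProtocolError(RuntimeError):
    pass


@dataclass(frozen=True)
class ConditionSpec:
    """Named simulation condition with its production bath setpoints,
    ordered (solute, solvent translational, solvent rotational) in K."""

    name: str
    production_bath_targets: tuple[float, float, float]

    def __post_init__(self) -> None:
        expected = {
            "equilibrium": (300.0, 300.0, 300.0),
            "microwave": (300.0, 300.0, MW_ROT_TEMPERATURE),
        }
        if self.name not in expected:
            raise ValueError(f"unknown condition {self.name!r}")
        if tuple(self.production_bath_targets) != expected[self.name]:
            raise ValueError(
                f"condition {self.name!r} requires bath targets "
                f"{expected[self.name]}"
            )

    @classmethod
    def equilibrium(cls) -> "ConditionSpec":
        return cls("equilibrium", (300.0, 300.0, 300.0))

    @classmethod
    def microwave(cls) -> "ConditionSpec":
        return cls("microwave", (300.0, 300.0, MW_ROT_TEMPERATURE))


@dataclass(frozen=True)
class ScheduleCycle:
    index: int
    n_steps: int
    timestep: float  # ps
    bath_targets: tuple[float, float, float]
    restraint_force_constant: float  # MJ/(mol nm^2)
    rototranslational_on: bool = False
    pressure_coupling_on: bool = False

    @property
    def duration(self) -> float:
        return self.n_steps * self.timestep


def condition_baths(
    targets: tuple[float, float, float], tau: float = DEFAULT_TAU
) -> dict[str, BathSpec]:
    t_sol, t_tr, t_rot = targets
    return {
        "solute": BathSpec("solute", t_sol, tau),
        "solvent_translational": BathSpec("solvent_translational", t_tr, tau),
        "solvent_rotational": BathSpec("solvent_rotational", t_rot, tau),
    }


def build_equilibration_schedule(
    condition: ConditionSpec,
    timestep: float = 0.002,
    n_steps_per_cycle: int = CYCLE_STEPS,
) -> list[ScheduleCycle]:
    """The staged equilibration schedule for one condition.

    Equilibrium: six heating cycles (50..300 K) + roto-translational
    cycle + pressure cycle = 8 cycles, 160 ps at the default step count.
    Microwave: one extra rotational-heating cycle (solvent rotation at
    700 K) after the ladder = 9 cycles, 180 ps.  The restraint constant
    is 25 x 0.1^i MJ/(mol nm^2) in cycle i.
    """
    targets_list: list[tuple[float, float, float]] = [
        (t, t, t) for t in HEATING_LADDER
    ]
    if condition.name == "microwave":
        targets_list.append((300.0, 300.0, MW_ROT_TEMPERATURE))
    final = condition.production_bath_targets
    targets_list.append(final)  # roto-translational cycle
    targets_list.append(final)  # pressure-coupling cycle

    cycles = []
    for i, targets in enumerate(targets_list):
        cycles.append(
            ScheduleCycle(
                index=i,
                n_steps=n_steps_per_cycle,
                timestep=timestep,
                bath_targets=targets,
                restraint_force_constant=RESTRAINT_START * RESTRAINT_DECAY**i,
                rototranslational_on=(i == len(targets_list) - 2),
                pressure_coupling_on=(i == len(targets_list) - 1),
            )
        )
    return cycles


def run_schedule(
    system: SimulationSystem,
    schedule: list[ScheduleCycle],
    evaluator: ForceEvaluator,
    tau: float = DEFAULT_TAU,
    shake_tolerance: float = 1e-4,
    sample_interval: int = 50,
) -> tuple[SimulationSystem, list[dict]]:
    """Execute every cycle of an equilibration schedule in place.

    The solute restraint reference is the entering solute conformation;
    the restraint constant follows the schedule.  Returns the system and
    a per-cycle report with mean bath temperatures and restraint energy.
    """
    reports = []
    restraint_ref = system.positions.copy() if system.n_solute else None
    n_constraints = _n_solute_bond_constraints(system)
    for cycle in schedule:
        params = IntegratorParams(
            timestep=cycle.timestep,
            shake_tolerance=shake_tolerance,
            com_removal_interval=COM_REMOVAL_INTERVAL,
            rototranslational_constraints=cycle.rototranslational_on,
        )
        mode = "rototranslational" if cycle.rototranslational_on else "com"
        dof = count_dof(system, n_constraints, mode)
        baths = condition_baths(cycle.bath_targets, tau)
        if restraint_ref is not None and cycle.restraint_force_constant > 0:
            solute_mask = np.zeros(system.n_atoms, dtype=bool)
            solute_mask[system.solute_slice] = True
            evaluator.set_restraints(
                restraint_ref,
                cycle.restraint_force_constant * 1000.0,
                mask=solute_mask,
            )
        else:
            evaluator.set_restraints(None, 0.0)
        barostat = BarostatParams() if cycle.pressure_coupling_on else None
        if cycle.rototranslational_on and system.n_solute:
            remove_global_motion(system, "roto_translational", "solute")
        try:
            report = run_md(
                system,
                evaluator,
                baths,
                dof,
                n_steps=cycle.n_steps,
                params=params,
                constrain_solute=True,
                barostat=barostat,
                sample_interval=sample_interval,
            )
        except Exception as exc:  # noqa: BLE001 - annotate with cycle index
            raise ProtocolError(f"equilibration aborted in cycle {cycle.index}: {exc}") from exc
        restraint_energy = 0.0
        if restraint_ref is not None and cycle.restraint_force_constant > 0:
            disp = system.positions[system.solute_slice] - restraint_ref[system.solute_slice]
            restraint_energy = 0.5 * cycle.restraint_force_constant * 1000.0 * float(
                (disp**2).sum()
            )
        reports.append({
            "cycle": cycle.index,
            "bath_targets": cycle.bath_targets,
            "mean_t_solute": float(np.mean(report["t_solute"])) if len(report["t_solute"]) else 0.0,
            "mean_t_trans": float(np.mean(report["t_trans"])),
            "mean_t_rot": float(np.mean(report["t_rot"])),
            "restraint_force_constant": cycle.restraint_force_constant,
            "restraint_energy": restraint_energy,
        })
    evaluator.set_restraints(None, 0.0)
    return system, reports


def _n_solute_bond_constraints(system: SimulationSystem) -> int:
    top = system.topology
    if top is None or system.n_solute == 0 or len(top.bonds) == 0:
        return 0
    sel = (top.bonds[:, 0] < system.n_solute) & (top.bonds[:, 1] < system.n_solute)
    return int(sel.sum())


def run_production(
    system: SimulationSystem,
    condition: ConditionSpec,
    evaluator: ForceEvaluator,
    duration_ps: float,
    report_interval_ps: float = 0.1,
    tau: float = DEFAULT_TAU,
    timestep: float = 0.002,
    shake_tolerance: float = 1e-4,
    trajectory=None,
    start_time: float = 0.0,
    rototranslational: bool = True,
) -> dict:
    """Constant-volume production run under one condition's three baths.

    Frames (positions, box, energy breakdown) are appended to
    ``trajectory`` (a :class:`mwmd.io.Trajectory` or anything with an
    ``append(frame)`` method) every ``report_interval_ps``.  Returns the
    sampled report from the MD loop.  The run is deterministic, so a
    restart from a checkpointed state continues bit-identically.
    """
    from .io import TrajectoryFrame  # local import to avoid a cycle

    n_steps = int(round(duration_ps / timestep))
    if n_steps == 0:
        return {"time": np.zeros(0), "t_solute": np.zeros(0),
                "t_trans": np.zeros(0), "t_rot": np.zeros(0),
                "e_potential": np.zeros(0), "e_kinetic": np.zeros(0),
                "pressure": np.zeros(0)}
    sample_interval = max(1, int(round(report_interval_ps / timestep)))
    dof = count_dof(
        system,
        _n_solute_bond_constraints(system),
        "rototranslational" if (rototranslational and system.n_solute) else "com",
    )
    baths = condition_baths(condition.production_bath_targets, tau)
    params = IntegratorParams(
        timestep=timestep,
        shake_tolerance=shake_tolerance,
        com_removal_interval=COM_REMOVAL_INTERVAL,
        rototranslational_constraints=rototranslational and system.n_solute > 0,
    )

    def on_sample(t: float, sys_: SimulationSystem, breakdown: EnergyBreakdown):
        if trajectory is not None:
            trajectory.append(
                TrajectoryFrame(
                    time=t,
                    positions=sys_.positions.copy(),
                    box=sys_.box.copy(),
                    velocities=None,
                    energy=EnergyBreakdown(*breakdown.as_array()),
                )
            )

    return run_md(
        system,
        evaluator,
        baths,
        dof,
        n_steps=n_steps,
        params=params,
        constrain_solute=True,
        barostat=None,  # constant volume: pressure coupling is equilibration-only
        sample_interval=sample_interval,
        on_sample=on_sample,
        start_time=start_time,
    )
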