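"""File formats and run configuration.

* PDB subset reader/writer (ATOM/HETATM records, first MODEL only,
  angstrom <-> nm conversion at the boundary).
* A versioned flat-binary trajectory format (magic bytes, little-endian
  doubles, fixed frame records) chosen so that checkpointed restarts
  concatenate bit-identically; a plain-text exporter is provided for
  inspection.
* Flat key-value run configuration with units embedded in the key names
  (cutoff_nm, timestep_ps, ...) and mandatory seeds; unknown keys are
  rejected and every run can echo its resolved configuration and hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional

import numpy as np

from .forcefield import EnergyBreakdown

logger = logging.getLogger("mwmd")

__all__ = [
    "read_pdb",
    "write_pdb",
    "read_topology",
    "write_topology",
    "TrajectoryFrame",
    "Trajectory",
    "RunConfig",
]


class IOError_(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# PDB subset
# ---------------------------------------------------------------------------

@dataclass
class PdbAtom:
    name: str
    resname: str
    chain: str
    resid: int
    element: str


def read_pdb(path) -> tuple[list[PdbAtom], np.ndarray]:
    """Read ATOM/HETATM records from a PDB file (first MODEL only).

    Coordinates are converted from angstrom to nm.  Malformed records
    raise with the offending line number.
    """
    atoms: list[PdbAtom] = []
    coords: list[list[float]] = []
    n_models = 0
    first_model_done = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "MODEL":
                n_models += 1
                if n_models > 1:
                    logger.warning(
                        "%s: multiple MODELs, reading the first only", path
                    )
                    break
            elif rec == "ENDMDL" and n_models >= 1:
                first_model_done = True
            elif rec in ("ATOM", "HETATM") and not first_model_done:
                try:
                    name = line[12:16].strip()
                    resname = line[17:20].strip()
                    chain = line[21].strip()
                    resid = int(line[22:26])
                    x = float(line[30:38])
                    y = float(line[38:46])
                    z = float(line[46:54])
                    element = line[76:78].strip() or name[:1]
                except (ValueError, IndexError) as exc:
                    raise IOError_(
                        f"{path}: malformed {rec} record at line {lineno}: {exc}"
                    ) from exc
                atoms.append(PdbAtom(name, resname, chain, resid, element))
                coords.append([x / 10.0, y / 10.0, z / 10.0])
    return atoms, np.asarray(coords, dtype=np.float64).reshape(-1, 3)


def write_pdb(path, atoms: list[PdbAtom], coords_nm: np.ndarray) -> None:
    """Write a minimal PDB file; coordinates converted nm -> angstrom."""
    coords = np.asarray(coords_nm, dtype=np.float64)
    with open(path, "w") as fh:
        for i, (atom, xyz) in enumerate(zip(atoms, coords), start=1):
            fh.write(
                "ATOM  {serial:>5d} {name:<4s}{resname:>4s} {chain:1s}"
                "{resid:>4d}    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}"
                "          {el:>2s}\n".format(
                    serial=i, name=atom.name[:4], resname=atom.resname[:3],
                    chain=atom.chain or "A", resid=atom.resid,
                    x=xyz[0] * 10, y=xyz[1] * 10, z=xyz[2] * 10,
                    occ=1.0, b=0.0, el=atom.element[:2],
                )
            )
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Flat text topology format
# ---------------------------------------------------------------------------
# Whitespace-delimited blocks with 1-based atom indices:
#   ATOMS:      index name element resid resname charge lj_type mol_index
#   LJTYPES:    type_index C6 C12          (per-type; pairs combine
#                                           geometrically)
#   BONDS:      i j r0 k_b
#   ANGLES:     i j k theta0_deg k_theta
#   DIHEDRALS:  i j k l multiplicity phase_deg k_phi
#   EXCLUSIONS: i j
#   HEADTAIL:   head tail   (atom indices or "- -")

def write_topology(path, topology) -> None:
    top = topology
    with open(path, "w") as fh:
        fh.write("MWTOP 1\n")
        fh.write("ATOMS\n")
        for i in range(top.n_atoms):
            fh.write(
                f"{i + 1} {top.atom_names[i]} {top.elements[i]} "
                f"{int(top.resids[i])} {top.resnames[i]} "
                f"{top.charges[i]:.17g} {int(top.lj_types[i])} "
                f"{int(top.mol_index[i]) if len(top.mol_index) else 0}\n"
            )
        fh.write("LJTYPES\n")
        for t in range(top.c6_table.shape[0]):
            fh.write(f"{t} {top.c6_table[t, t]:.17g} {top.c12_table[t, t]:.17g}\n")
        fh.write("BONDS\n")
        for (i, j), r0, k in zip(top.bonds, top.bond_r0, top.bond_k):
            fh.write(f"{i + 1} {j + 1} {r0:.17g} {k:.17g}\n")
        fh.write("ANGLES\n")
        for (i, j, k), t0, kt in zip(top.angles, top.angle_theta0, top.angle_k):
            fh.write(f"{i + 1} {j + 1} {k + 1} {np.degrees(t0):.17g} {kt:.17g}\n")
        fh.write("DIHEDRALS\n")
        for (i, j, k, l), m, ph, kp in zip(top.dihedrals, top.dihedral_mult,
                                           top.dihedral_phase, top.dihedral_k):
            fh.write(f"{i + 1} {j + 1} {k + 1} {l + 1} {int(m)} "
                     f"{np.degrees(ph):.17g} {kp:.17g}\n")
        fh.write("EXCLUSIONS\n")
        for i, j in top.exclusions:
            fh.write(f"{i + 1} {j + 1}\n")
        fh.write("HEADTAIL\n")
        head = "-" if top.head_atom is None else str(top.head_atom + 1)
        tail = "-" if top.tail_atom is None else str(top.tail_atom + 1)
        fh.write(f"{head} {tail}\n")
        fh.write("END\n")


def read_topology(path):
    from .forcefield import Topology

    blocks: dict[str, list[list[str]]] = {}
    current = None
    with open(path) as fh:
        header = fh.readline().split()
        if not header or header[0] != "MWTOP":
            raise IOError_(f"{path}: not a topology file")
        for lineno, line in enumerate(fh, start=2):
            tok = line.split()
            if not tok:
                continue
            if len(tok) == 1 and tok[0].isupper():
                if tok[0] == "END":
                    break
                current = tok[0]
                blocks[current] = []
                continue
            if current is None:
                raise IOError_(f"{path}:{lineno}: data outside a block")
            blocks[current].append(tok)

    atoms = blocks.get("ATOMS", [])
    n = len(atoms)
    charges = np.array([float(a[5]) for a in atoms])
    lj_types = np.array([int(a[6]) for a in atoms], dtype=np.int64)
    lj = blocks.get("LJTYPES", [])
    diag6 = np.array([float(r[1]) for r in lj])
    diag12 = np.array([float(r[2]) for r in lj])
    s6 = np.sqrt(diag6)
    s12 = np.sqrt(diag12)
    bonds = blocks.get("BONDS", [])
    angles = blocks.get("ANGLES", [])
    dihedrals = blocks.get("DIHEDRALS", [])
    excl = blocks.get("EXCLUSIONS", [])
    head_tail = blocks.get("HEADTAIL", [["-", "-"]])[0]
    return Topology(
        charges=charges,
        lj_types=lj_types,
        c6_table=np.outer(s6, s6),
        c12_table=np.outer(s12, s12),
        bonds=np.array([[int(b[0]) - 1, int(b[1]) - 1] for b in bonds],
                       dtype=np.int64).reshape(-1, 2),
        bond_r0=np.array([float(b[2]) for b in bonds]),
        bond_k=np.array([float(b[3]) for b in bonds]),
        angles=np.array([[int(a[0]) - 1, int(a[1]) - 1, int(a[2]) - 1]
                         for a in angles], dtype=np.int64).reshape(-1, 3),
        angle_theta0=np.radians([float(a[3]) for a in angles]),
        angle_k=np.array([float(a[4]) for a in angles]),
        dihedrals=np.array([[int(d[0]) - 1, int(d[1]) - 1, int(d[2]) - 1,
                             int(d[3]) - 1] for d in dihedrals],
                           dtype=np.int64).reshape(-1, 4),
        dihedral_mult=np.array([int(d[4]) for d in dihedrals], dtype=np.int64),
        dihedral_phase=np.radians([float(d[5]) for d in dihedrals]),
        dihedral_k=np.array([float(d[6]) for d in dihedrals]),
        exclusions=np.array([[int(e[0]) - 1, int(e[1]) - 1] for e in excl],
                            dtype=np.int64).reshape(-1, 2),
        atom_names=[a[1] for a in atoms],
        elements=[a[2] for a in atoms],
        resids=np.array([int(a[3]) for a in atoms], dtype=np.int32),
        resnames=[a[4] for a in atoms],
        mol_index=np.array([int(a[7]) for a in atoms], dtype=np.int32),
        head_atom=None if head_tail[0] == "-" else int(head_tail[0]) - 1,
        tail_atom=None if head_tail[1] == "-" else int(head_tail[1]) - 1,
    )


# ---------------------------------------------------------------------------
# Trajectory format
# ---------------------------------------------------------------------------

MAGIC = b"MWTRJ001"


@dataclass
class TrajectoryFrame:
    time: float                       # ps
    positions: np.ndarray             # (n, 3) nm
    box: np.ndarray                   # (3,) nm
    velocities: Optional[np.ndarray] = None  # (n, 3) nm/ps
    energy: Optional[EnergyBreakdown] = None


class Trajectory:
    """In-memory list of frames with a versioned flat-binary file format.

    Layout: 8 magic bytes, 16-byte config-hash field, uint32 atom count;
    then per frame: uint8 has-velocities flag, float64 time, 3 float64
    box, 6 float64 energy terms, 3n float64 positions (and 3n float64
    velocities when flagged).  Everything little-endian; appending
    frames to an existing file of the same system is safe, which gives
    bit-identical concatenation of checkpointed segments.
    """

    def __init__(self, frames: Optional[list[TrajectoryFrame]] = None,
                 config_hash: str = ""):
        self.frames: list[TrajectoryFrame] = list(frames) if frames else []
        self.config_hash = config_hash

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[TrajectoryFrame]:
        return iter(self.frames)

    def __getitem__(self, idx):
        return self.frames[idx]

    def append(self, frame: TrajectoryFrame) -> None:
        if self.frames and frame.time <= self.frames[-1].time:
            raise IOError_(
                f"non-monotonic frame time {frame.time} after "
                f"{self.frames[-1].time}"
            )
        self.frames.append(frame)

    # -- file I/O ---------------------------------------------------------
    def write(self, path) -> None:
        path = Path(path)
        n_atoms = self.frames[0].positions.shape[0] if self.frames else 0
        with open(path, "wb") as fh:
            fh.write(MAGIC)
            fh.write(self.config_hash[:16].ljust(16, "\0").encode())
            fh.write(struct.pack("<I", n_atoms))
            for frame in self.frames:
                self._write_frame(fh, frame)

    def append_to_file(self, path) -> None:
        """Append all in-memory frames to an existing trajectory file."""
        path = Path(path)
        if not path.exists():
            self.write(path)
            return
        with open(path, "ab") as fh:
            for frame in self.frames:
                self._write_frame(fh, frame)

    @staticmethod
    def _write_frame(fh, frame: TrajectoryFrame) -> None:
        has_v = frame.velocities is not None
        fh.write(struct.pack("<B", 1 if has_v else 0))
        fh.write(struct.pack("<d", frame.time))
        fh.write(np.asarray(frame.box, dtype="<f8").tobytes())
        energy = frame.energy.as_array() if frame.energy is not None \
            else np.zeros(6)
        fh.write(np.asarray(energy, dtype="<f8").tobytes())
        fh.write(np.ascontiguousarray(frame.positions, dtype="<f8").tobytes())
        if has_v:
            fh.write(np.ascontiguousarray(frame.velocities, dtype="<f8").tobytes())

    @classmethod
    def read(cls, path) -> "Trajectory":
        path = Path(path)
        raw = path.read_bytes()
        if raw[:8] != MAGIC:
            raise IOError_(f"{path}: not a trajectory file (bad magic)")
        config_hash = raw[8:24].rstrip(b"\0").decode()
        (n_atoms,) = struct.unpack("<I", raw[24:28])
        offset = 28
        frames: list[TrajectoryFrame] = []
        frame_idx = 0
        total = len(raw)
        while offset < total:
            base = 1 + 8 + 24 + 48 + 24 * n_atoms
            try:
                has_v = raw[offset]
                need = base + (24 * n_atoms if has_v else 0)
                if offset + need > total:
                    raise IOError_("truncated")
                (time,) = struct.unpack_from("<d", raw, offset + 1)
                box = np.frombuffer(raw, "<f8", 3, offset + 9).copy()
                energy = np.frombuffer(raw, "<f8", 6, offset + 33).copy()
                pos = np.frombuffer(raw, "<f8", 3 * n_atoms, offset + 81)
                pos = pos.reshape(n_atoms, 3).copy()
                vel = None
                if has_v:
                    vel = np.frombuffer(
                        raw, "<f8", 3 * n_atoms, offset + 81 + 24 * n_atoms
                    ).reshape(n_atoms, 3).copy()
                offset += need
            except (IOError_, struct.error) as exc:
                raise IOError_(
                    f"{path}: truncated after frame {frame_idx - 1} "
                    f"(last valid frame index {frame_idx - 1})"
                ) from exc
            frames.append(TrajectoryFrame(
                time=time, positions=pos, box=box, velocities=vel,
                energy=EnergyBreakdown.from_array(energy),
            ))
            frame_idx += 1
        return cls(frames, config_hash)

    def export_text(self, path) -> None:
        """Human-readable dump: one block per frame with positions."""
        with open(path, "w") as fh:
            fh.write(f"# mwmd trajectory export, config {self.config_hash}\n")
            for frame in self.frames:
                fh.write(f"t= {frame.time:.6f} box= "
                         + " ".join(f"{b:.6f}" for b in frame.box) + "\n")
                for xyz in frame.positions:
                    fh.write(" ".join(f"{x:.6f}" for x in xyz) + "\n")


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Flat key-value run configuration.

    Defaults are the protocol's reference values: 2 fs timestep, 1.4 nm
    cutoff, reaction-field permittivity 61, tau = 0.01 ps for all three
    baths, rotational setpoint 700 K under the microwave condition,
    restraint 25 MJ/(mol nm^2), salt 0.15 mol/L.  Seeds are mandatory.
    """

    condition: str = "equilibrium"
    seed_build: int = -1
    seed_velocities: int = -1
    timestep_ps: float = 0.002
    cutoff_nm: float = 1.4
    epsilon_rf: float = 61.0
    tau_solute_ps: float = 0.01
    tau_trans_ps: float = 0.01
    tau_rot_ps: float = 0.01
    bath_solute_k: float = 300.0
    bath_trans_k: float = 300.0
    bath_rot_k: float = 300.0
    mw_rot_target_k: float = 700.0
    restraint_mj_mol_nm2: float = 25.0
    ion_conc_mol_l: float = 0.15
    n_waters: int = 216
    solute_kind: str = "none"          # none | helix_like | hairpin_like | extended
    solute_residues: int = 10
    steps_per_cycle: int = 10000
    duration_ps: float = 50.0
    report_interval_ps: float = 0.1
    trajectory_path: str = "trajectory.mwtrj"
    checkpoint_path: str = "checkpoint.mwtrj"

    _FLOAT_KEYS = {
        "timestep_ps", "cutoff_nm", "epsilon_rf", "tau_solute_ps",
        "tau_trans_ps", "tau_rot_ps", "bath_solute_k", "bath_trans_k",
        "bath_rot_k", "mw_rot_target_k", "restraint_mj_mol_nm2",
        "ion_conc_mol_l", "duration_ps", "report_interval_ps",
    }
    _INT_KEYS = {"seed_build", "seed_velocities", "n_waters",
                 "solute_residues", "steps_per_cycle"}

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        values = {}
        known = {f.name for f in dataclasses.fields(cls)}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise IOError_(f"{path}:{lineno}: expected key = value")
                key, _, value = line.partition("=")
                key = key.strip()
                value = value.strip()
                if key not in known:
                    raise IOError_(f"{path}:{lineno}: unknown config key {key!r}")
                if key in cls._FLOAT_KEYS:
                    values[key] = float(value)
                elif key in cls._INT_KEYS:
                    values[key] = int(value)
                else:
                    values[key] = value
        cfg = cls(**values)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.seed_build < 0 or self.seed_velocities < 0:
            raise IOError_(
                "seed_build and seed_velocities are mandatory config keys"
            )
        if self.condition not in ("equilibrium", "microwave"):
            raise IOError_(f"unknown condition {self.condition!r}")

    def resolved_text(self) -> str:
        lines = [
            f"{f.name} = {getattr(self, f.name)}"
            for f in dataclasses.fields(self)
        ]
        return "\n".join(lines) + "\n"

    def config_hash(self) -> str:
        return hashlib.sha256(self.resolved_text().encode()).hexdigest()[:16]

    def production_targets(self) -> tuple[float, float, float]:
        if self.condition == "microwave":
            return (self.bath_solute_k, self.bath_trans_k, self.mw_rot_target_k)
        return (self.bath_solute_k, self.bath_trans_k, self.bath_rot_k)
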