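"""Trajectory analysis: structure, hydrogen bonds, surface area, energies.

Implements the quantities used to characterize solute structure under
the two thermostat conditions: least-squares superposition RMSD and its
size-normalized variant RMSD100, per-atom RMSF, radius of gyration,
head-to-tail distance, geometric hydrogen-bond counts (intra-solute,
backbone-backbone, solute-water), Shrake-Rupley accessible surface area
with a polar/nonpolar residue split, a simplified backbone-H-bond
secondary-structure assignment, block-averaged uncertainties
(Flyvbjerg-Petersen) and the per-system condition-ratio statistic.

The RMSD100 normalization is the Carugo-Pongor size correction

    RMSD100 = RMSD / (1 + ln sqrt(N/100))

which maps the RMSD of an N-residue structure onto the equivalent value
for a 100-residue structure; it has not been validated below 40
residues, so smaller selections trigger a warning.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from . import params as P
from .forcefield import EnergyBreakdown, Topology

__all__ = [
    "HBondCriteria",
    "AnalysisSummary",
    "ConditionComparison",
    "superpose_rmsd",
    "rmsd100",
    "rmsf",
    "radius_of_gyration",
    "head_to_tail",
    "hbond_statistics",
    "sasa",
    "secondary_structure_frequencies",
    "block_average",
    "condition_comparison",
    "summarize_trajectory",
]


class AnalysisError(ValueError):
    pass


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric hydrogen-bond criterion: H...acceptor distance cutoff
    (nm) and minimum donor-H...acceptor angle (degrees)."""

    max_h_acceptor_distance: float = P.HBOND_MAX_HA_DISTANCE
    min_donor_angle: float = P.HBOND_MIN_ANGLE

    def __post_init__(self) -> None:
        if self.max_h_acceptor_distance <= 0:
            raise ValueError("distance cutoff must be positive")
        if not 0 < self.min_donor_angle <= 180:
            raise ValueError("angle must be in (0, 180]")


@dataclass
class Measurement:
    mean: float
    sem: float


@dataclass
class AnalysisSummary:
    """Per-trajectory means with block-averaged SEMs."""

    rmsd: Measurement
    rmsd100: Measurement
    rmsf: float                      # mean over atoms of per-atom RMSF, nm
    rgyr: Measurement
    head_to_tail: Measurement
    n_hb_pp_backbone: Measurement
    n_hb_pp: Measurement
    n_hb_pw: Measurement
    sasa_total: Measurement
    sasa_polar: Measurement
    sasa_nonpolar: Measurement
    helix_frequency: float
    sheet_frequency: float
    coil_frequency: float
    energy: dict = dc_field(default_factory=dict)  # per-term Measurement


@dataclass
class ConditionComparison:
    """Per-quantity relative change between conditions:
    (mean_MW / mean_eq) - 1 averaged over paired systems, with the SEM
    of the per-system ratios."""

    changes: dict  # name -> Measurement
    sign_convention: str = "mw_over_eq_minus_1"


# ---------------------------------------------------------------------------
# Superposition / RMSD
# ---------------------------------------------------------------------------

def superpose_rmsd(
    frame: np.ndarray,
    reference: np.ndarray,
    atom_selection: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, float]:
    """Optimal (Kabsch) superposition of ``frame`` onto ``reference``.

    Returns ``(rotation_matrix, rmsd)`` where the RMSD (nm) is evaluated
    after removing the optimal rigid translation and proper rotation
    (reflections excluded).  Requires at least three non-collinear
    atoms in the selection.
    """
    frame = np.asarray(frame, dtype=np.float64)
    reference = np.asarray(reference, dtype=np.float64)
    if atom_selection is not None:
        frame = frame[atom_selection]
        reference = reference[atom_selection]
    if frame.shape[0] < 3:
        raise AnalysisError("need at least 3 atoms for superposition")
    x = frame - frame.mean(axis=0)
    y = reference - reference.mean(axis=0)
    # collinearity check via the second singular value
    if np.linalg.svd(y, compute_uv=False)[1] < 1e-10:
        raise AnalysisError("degenerate (collinear) reference selection")
    rot, _ = Rotation.align_vectors(y, x)
    aligned = rot.apply(x)
    rmsd = float(np.sqrt(((aligned - y) ** 2).sum(axis=1).mean()))
    return rot.as_matrix(), rmsd


def rmsd100(rmsd: float, n_residues: int) -> float:
    """Size-normalized RMSD for an N-residue structure (Carugo-Pongor)."""
    if n_residues < 1:
        raise AnalysisError("n_residues must be >= 1")
    if n_residues < 40:
        warnings.warn(
            "RMSD100 normalization is not validated below 40 residues",
            stacklevel=2,
        )
    denom = 1.0 + math.log(math.sqrt(n_residues / 100.0))
    if denom <= 0:
        raise AnalysisError(
            f"RMSD100 undefined for N = {n_residues}: denominator {denom:.3f} <= 0"
        )
    return rmsd / denom


def rmsf(
    trajectory_positions: Sequence[np.ndarray],
    atom_selection: Optional[np.ndarray] = None,
    fit_reference: Optional[np.ndarray] = None,
    fit: bool = True,
) -> np.ndarray:
    """Per-atom root-mean-square fluctuation about the time-mean position.

    With ``fit=True`` (default) frames are first superposed onto
    ``fit_reference`` (default: the first frame) using the selection,
    removing global rotation and translation so only internal
    fluctuations remain; note that for small selections the six fitted
    degrees of freedom absorb a corresponding share of the apparent
    fluctuation.  ``fit=False`` measures raw per-atom fluctuations.
    """
    frames = [np.asarray(f, dtype=np.float64) for f in trajectory_positions]
    if len(frames) < 2:
        raise AnalysisError("RMSF needs at least two frames")
    if atom_selection is None:
        atom_selection = np.arange(frames[0].shape[0])
    ref = frames[0] if fit_reference is None else np.asarray(fit_reference)
    ref_sel = ref[atom_selection]
    ref_centered = ref_sel - ref_sel.mean(axis=0)
    fitted = []
    for f in frames:
        sel = f[atom_selection]
        if fit:
            x = sel - sel.mean(axis=0)
            rot, _ = Rotation.align_vectors(ref_centered, x)
            fitted.append(rot.apply(x))
        else:
            fitted.append(sel)
    stack = np.stack(fitted)
    mean_pos = stack.mean(axis=0)
    return np.sqrt(((stack - mean_pos) ** 2).sum(axis=2).mean(axis=0))


def radius_of_gyration(
    frame: np.ndarray,
    atom_selection: Optional[np.ndarray] = None,
    masses: Optional[np.ndarray] = None,
) -> float:
    """Root-mean-square (optionally mass-weighted) distance from the
    selection centroid, nm."""
    x = np.asarray(frame, dtype=np.float64)
    if atom_selection is not None:
        x = x[atom_selection]
        if masses is not None:
            masses = masses[atom_selection]
    if x.shape[0] == 0:
        raise AnalysisError("empty selection")
    w = np.ones(x.shape[0]) if masses is None else np.asarray(masses, float)
    centroid = (w[:, None] * x).sum(axis=0) / w.sum()
    return float(np.sqrt((w * ((x - centroid) ** 2).sum(axis=1)).sum() / w.sum()))


def head_to_tail(frame: np.ndarray, head_atom: Optional[int], tail_atom: Optional[int]) -> float:
    """Euclidean head-tail distance (no minimum image: solute kept whole)."""
    if head_atom is None or tail_atom is None:
        raise AnalysisError("head/tail atoms not tagged")
    d = np.asarray(frame[head_atom], float) - np.asarray(frame[tail_atom], float)
    return float(np.linalg.norm(d))


# ---------------------------------------------------------------------------
# Hydrogen bonds
# ---------------------------------------------------------------------------

def _backbone_indices(topology: Topology, n_solute: int) -> dict[int, dict[str, int]]:
    """Map residue id -> backbone site indices for the solute."""
    out: dict[int, dict[str, int]] = {}
    for i in range(n_solute):
        name = topology.atom_names[i]
        if name in ("N", "CA", "C", "O"):
            out.setdefault(int(topology.resids[i]), {})[name] = i
    return out


def reconstruct_amide_hydrogens(
    positions: np.ndarray, topology: Topology, n_solute: int
) -> tuple[np.ndarray, np.ndarray]:
    """Backbone amide H positions inferred from the united-atom geometry.

    The H on residue i's N is placed 0.1 nm from N, anti to the
    preceding carbonyl (the standard reconstruction when amide
    hydrogens are not explicit sites).  Returns (donor N indices,
    H coordinates); the first residue has no preceding carbonyl and
    contributes no donor.
    """
    bb = _backbone_indices(topology, n_solute)
    donors, h_pos = [], []
    for resid in sorted(bb):
        if resid - 1 not in bb:
            continue
        prev = bb[resid - 1]
        cur = bb[resid]
        if "C" not in prev or "O" not in prev or "N" not in cur:
            continue
        n = positions[cur["N"]]
        d = positions[prev["C"]] - positions[prev["O"]]
        norm = np.linalg.norm(d)
        if norm < 1e-10:
            continue
        donors.append(cur["N"])
        h_pos.append(n + 0.1 * d / norm)
    return np.array(donors, dtype=int), (
        np.array(h_pos) if h_pos else np.zeros((0, 3))
    )


def _water_layout(topology: Topology, n_solute: int, n_waters: int):
    o = n_solute + 3 * np.arange(n_waters)
    return o, o + 1, o + 2


def _count_hbonds(
    h_pos: np.ndarray,
    donor_pos: np.ndarray,
    acceptor_pos: np.ndarray,
    criteria: HBondCriteria,
    box: Optional[np.ndarray] = None,
    exclude: Optional[set[tuple[int, int]]] = None,
    donor_ids: Optional[np.ndarray] = None,
    acceptor_ids: Optional[np.ndarray] = None,
) -> int:
    """Count donor-H...acceptor contacts meeting the geometric criterion."""
    if len(h_pos) == 0 or len(acceptor_pos) == 0:
        return 0

    def mi(d):
        return d - box * np.rint(d / box) if box is not None else d

    count = 0
    tree = cKDTree(np.mod(acceptor_pos, box) if box is not None else acceptor_pos,
                   boxsize=box if box is not None else None)
    query = np.mod(h_pos, box) if box is not None else h_pos
    neighbours = tree.query_ball_point(query, criteria.max_h_acceptor_distance)
    cos_min = math.cos(math.radians(criteria.min_donor_angle))
    for k, accs in enumerate(neighbours):
        for a in accs:
            if exclude is not None and donor_ids is not None:
                key = (int(donor_ids[k]), int(acceptor_ids[a]))
                if key in exclude or key[0] == key[1]:
                    continue
            dh = mi(h_pos[k] - donor_pos[k])
            ha = mi(acceptor_pos[a] - h_pos[k])
            nh = np.linalg.norm(dh)
            na = np.linalg.norm(ha)
            if nh < 1e-10 or na < 1e-10:
                continue
            # angle donor-H...acceptor: 180 deg = linear
            cos_ang = float(np.dot(-dh, ha) / (nh * na))
            angle = math.degrees(math.acos(np.clip(cos_ang, -1.0, 1.0)))
            if angle >= criteria.min_donor_angle - 1e-9:
                count += 1
    return count


def hbond_statistics(
    positions: np.ndarray,
    topology: Topology,
    n_solute: int,
    n_waters: int,
    box: Optional[np.ndarray] = None,
    criteria: HBondCriteria = HBondCriteria(),
) -> tuple[int, int, int]:
    """(n_hb_pp, n_hb_pp_backbone, n_hb_pw) for one frame.

    Solute donors are backbone amide N-H groups (H reconstructed from
    the united-atom geometry); solute acceptors are N and O sites.
    Water O-H donate and water O accepts; the solute-water count
    includes both directions.  A warning-free zero is returned when no
    donors or acceptors exist.
    """
    donors_n, h_n = reconstruct_amide_hydrogens(positions, topology, n_solute)
    solute_acc = np.array(
        [i for i in range(n_solute) if topology.elements[i] in ("N", "O")],
        dtype=int,
    )
    excl = topology.exclusion_set()

    n_pp = n_ppbb = n_pw = 0
    if len(donors_n):
        # intra-solute: reconstructed N-H donors vs solute N/O acceptors
        n_pp = _count_hbonds(
            h_n, positions[donors_n], positions[solute_acc], criteria,
            box=None, exclude=excl,
            donor_ids=donors_n, acceptor_ids=solute_acc,
        )
        bb_acc = np.array(
            [i for i in solute_acc if topology.atom_names[i] == "O"], dtype=int
        )
        n_ppbb = _count_hbonds(
            h_n, positions[donors_n], positions[bb_acc], criteria,
            box=None, exclude=excl,
            donor_ids=donors_n, acceptor_ids=bb_acc,
        )
    if n_waters:
        ow, hw1, hw2 = _water_layout(topology, n_solute, n_waters)
        water_o = positions[ow]
        if len(donors_n):
            # solute donor -> water O acceptor
            n_pw += _count_hbonds(h_n, positions[donors_n], water_o,
                                  criteria, box=box)
        if len(solute_acc):
            # water donor -> solute N/O acceptor (both water hydrogens)
            for hw in (hw1, hw2):
                n_pw += _count_hbonds(
                    positions[hw], water_o, positions[solute_acc],
                    criteria, box=box,
                )
    return n_pp, n_ppbb, n_pw


# ---------------------------------------------------------------------------
# Solvent-accessible surface area
# ---------------------------------------------------------------------------

def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden
    spiral)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0**0.5) * k
    return np.stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)],
        axis=1,
    )


def sasa(
    positions: np.ndarray,
    radii: np.ndarray,
    probe_radius: float = P.SASA_PROBE_RADIUS,
    n_points: int = P.SASA_N_POINTS,
) -> np.ndarray:
    """Per-atom Shrake-Rupley solvent-accessible surface area (nm^2).

    Each atom's sphere of radius ``r_i + probe`` is sampled with
    ``n_points`` quasi-uniform points; a point is accessible when it is
    outside every neighbour's inflated sphere.
    """
    if n_points < 100:
        raise AnalysisError("n_points must be >= 100")
    positions = np.asarray(positions, dtype=np.float64)
    radii = np.asarray(radii, dtype=np.float64)
    if radii.shape[0] != positions.shape[0]:
        raise AnalysisError("one radius per atom required")
    inflated = radii + probe_radius
    pts = _sphere_points(n_points)
    tree = cKDTree(positions)
    max_r = inflated.max()
    areas = np.empty(positions.shape[0])
    for i in range(positions.shape[0]):
        sphere = positions[i] + inflated[i] * pts
        neigh = [j for j in tree.query_ball_point(positions[i], inflated[i] + max_r)
                 if j != i]
        if neigh:
            d2 = ((sphere[:, None, :] - positions[neigh][None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (inflated[neigh] ** 2)[None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        areas[i] = frac * 4.0 * np.pi * inflated[i] ** 2
    return areas


def radii_for_topology(topology: Topology, n_solute: int) -> np.ndarray:
    try:
        return np.array(
            [P.SASA_RADII[topology.elements[i]] for i in range(n_solute)]
        )
    except KeyError as exc:
        raise AnalysisError(f"no surface radius for atom type {exc}") from exc


def sasa_polar_split(
    positions: np.ndarray,
    topology: Topology,
    n_solute: int,
    probe_radius: float = P.SASA_PROBE_RADIUS,
    n_points: int = P.SASA_N_POINTS,
    polar_residues: frozenset = P.POLAR_RESIDUES,
    nonpolar_residues: frozenset = P.NONPOLAR_RESIDUES,
) -> tuple[float, float, float]:
    """(total, polar, nonpolar) solute surface area by residue class."""
    areas = sasa(positions[:n_solute], radii_for_topology(topology, n_solute),
                 probe_radius, n_points)
    polar = nonpolar = 0.0
    for i in range(n_solute):
        res = topology.resnames[i]
        if res in polar_residues:
            polar += areas[i]
        elif res in nonpolar_residues:
            nonpolar += areas[i]
        else:
            raise AnalysisError(f"residue {res!r} not in polarity tables")
    return float(areas.sum()), polar, nonpolar


# ---------------------------------------------------------------------------
# Secondary structure (simplified backbone-H-bond assignment)
# ---------------------------------------------------------------------------

def _ss_backbone_hbond_energy(
    positions: np.ndarray, bb: dict[int, dict[str, int]],
    donors: dict[int, np.ndarray],
) -> dict[tuple[int, int], float]:
    """Electrostatic backbone H-bond energies E(donor_res, acceptor_res)
    in kJ/mol using the classic four-distance dipole formula."""
    kcal = 4.184
    q1q2_332 = 0.084 * 0.42 * 0.20 * 332.0  # partial charges and conversion
    energies: dict[tuple[int, int], float] = {}
    for di, h in donors.items():
        n = positions[bb[di]["N"]]
        for ai, sites in bb.items():
            if ai == di or abs(ai - di) < 2:
                continue
            if "C" not in sites or "O" not in sites:
                continue
            c = positions[sites["C"]]
            o = positions[sites["O"]]
            r_on = np.linalg.norm(o - n)
            r_ch = np.linalg.norm(c - h)
            r_oh = np.linalg.norm(o - h)
            r_cn = np.linalg.norm(c - n)
            if min(r_on, r_ch, r_oh, r_cn) < 5e-2:
                energies[(di, ai)] = -9999.0
                continue
            e = 0.42 * 0.20 * 332.0 * (1 / r_on + 1 / r_ch - 1 / r_oh - 1 / r_cn) \
                / 10.0 * kcal  # distances nm -> A via the 1/10 factor
            energies[(di, ai)] = e
    return energies


def secondary_structure_frequencies(
    trajectory_positions: Sequence[np.ndarray],
    topology: Topology,
    n_solute: int,
) -> tuple[float, float, float]:
    """(helix, sheet, coil) residue fractions averaged over frames.

    Assignment is a simplified backbone-H-bond scheme: an H-bond exists
    between donor residue i and acceptor residue j when the classic
    four-distance electrostatic energy is below -2.09 kJ/mol; helix
    from i -> i-4 donor patterns, sheet from non-local bridge partners
    (|i-j| > 4), coil otherwise.  Residues with missing backbone sites
    count as coil.
    """
    n_frames = 0
    totals = np.zeros(3)
    for positions in trajectory_positions:
        bb = _backbone_indices(topology, n_solute)
        resids = sorted(bb)
        donors_idx, h_pos = reconstruct_amide_hydrogens(positions, topology, n_solute)
        donors = {}
        for idx, h in zip(donors_idx, h_pos):
            donors[int(topology.resids[idx])] = h
        energies = _ss_backbone_hbond_energy(positions, bb, donors)
        bonded = {pair for pair, e in energies.items() if e < P.SS_ENERGY_CUTOFF}
        state = {r: "coil" for r in resids}
        # helices: donor i accepts from i-4 (alpha) — mark i-4..i
        for (di, ai) in bonded:
            if di - ai == 4:
                for r in range(ai, di + 1):
                    if r in state:
                        state[r] = "helix"
        for (di, ai) in bonded:
            if abs(di - ai) > 4 and state.get(di) == "coil":
                state[di] = "sheet"
                if state.get(ai) == "coil":
                    state[ai] = "sheet"
        counts = np.array([
            sum(1 for s in state.values() if s == "helix"),
            sum(1 for s in state.values() if s == "sheet"),
            sum(1 for s in state.values() if s == "coil"),
        ], dtype=float)
        totals += counts / max(len(resids), 1)
        n_frames += 1
    if n_frames == 0:
        raise AnalysisError("no frames")
    h, s, c = totals / n_frames
    return float(h), float(s), float(c)


# ---------------------------------------------------------------------------
# Block averaging and condition comparison
# ---------------------------------------------------------------------------

def block_average(series: np.ndarray) -> tuple[float, float]:
    """Mean and blocked SEM of a (possibly correlated) time series.

    Flyvbjerg-Petersen blocking: repeatedly average neighbouring pairs;
    at each level estimate SEM = sqrt(var / (n - 1)).  The reported SEM
    comes from the first plateau (successive estimates changing by less
    than 5%) or, failing that, the deepest level with at least two
    blocks.
    """
    x = np.asarray(series, dtype=np.float64)
    if x.size < 16:
        raise AnalysisError("series too short for block averaging (need >= 16)")
    mean = float(x.mean())
    sems = []
    level = x
    while level.size >= 2:
        n = level.size
        sems.append(math.sqrt(level.var(ddof=1) / n) if n > 1 else 0.0)
        m = n // 2
        level = 0.5 * (level[: 2 * m : 2] + level[1 : 2 * m : 2])
    sem = sems[-1]
    for k in range(1, len(sems) - 1):
        a, b = sems[k], sems[k + 1]
        if a > 0 and abs(b - a) / a < 0.05:
            sem = max(a, b)
            break
    return mean, float(sem)


def condition_comparison(
    summaries_eq: Sequence[dict],
    summaries_mw: Sequence[dict],
    literal_text_order: bool = False,
) -> ConditionComparison:
    """Relative change of each quantity between paired runs.

    Default sign convention: per system, change = (mean_MW / mean_eq) - 1,
    so quantities that shrink under the microwave condition come out
    negative.  ``literal_text_order`` flips to (mean_eq / mean_MW) - 1.
    The SEM is the standard deviation of the per-system changes over
    sqrt(n_systems).  Systems with a zero denominator are excluded with
    a warning.
    """
    if len(summaries_eq) != len(summaries_mw):
        raise AnalysisError("paired condition summaries required")
    keys = set(summaries_eq[0]) & set(summaries_mw[0])
    changes = {}
    for key in sorted(keys):
        ratios = []
        for eq, mw in zip(summaries_eq, summaries_mw):
            denom, num = (mw[key], eq[key]) if literal_text_order else (eq[key], mw[key])
            if denom == 0:
                warnings.warn(f"zero denominator for {key!r}; system excluded",
                              stacklevel=2)
                continue
            ratios.append(num / denom - 1.0)
        if not ratios:
            continue
        arr = np.asarray(ratios)
        sem = float(arr.std(ddof=0) / math.sqrt(len(arr))) if len(arr) > 1 else 0.0
        changes[key] = Measurement(mean=float(arr.mean()), sem=sem)
    return ConditionComparison(
        changes=changes,
        sign_convention="eq_over_mw_minus_1" if literal_text_order
        else "mw_over_eq_minus_1",
    )


# ---------------------------------------------------------------------------
# Whole-trajectory summary
# ---------------------------------------------------------------------------

def summarize_trajectory(
    frames,
    topology: Topology,
    n_solute: int,
    n_waters: int,
    reference_positions: np.ndarray,
    criteria: HBondCriteria = HBondCriteria(),
    sasa_every: int = 10,
) -> AnalysisSummary:
    """Compute every summary quantity over a trajectory's frames.

    ``frames`` is a sequence of objects exposing ``positions``, ``box``
    and optionally ``energy`` (an :class:`EnergyBreakdown`).  The RMSD
    uses backbone atoms after backbone superposition; the surface area
    is evaluated every ``sasa_every``-th frame (it is by far the most
    expensive term).
    """
    backbone = np.array(
        [i for i in range(n_solute)
         if topology.atom_names[i] in ("N", "CA", "C", "O")],
        dtype=int,
    )
    n_residues = int(topology.resids[:n_solute].max()) + 1 if n_solute else 0

    series: dict[str, list] = {k: [] for k in (
        "rmsd", "rgyr", "h2t", "hb_pp", "hb_ppbb", "hb_pw",
        "sasa_total", "sasa_polar", "sasa_nonpolar",
    )}
    energy_series: dict[str, list] = {}
    all_positions = []
    for k, frame in enumerate(frames):
        pos = frame.positions
        all_positions.append(pos)
        _, r = superpose_rmsd(pos, reference_positions, backbone)
        series["rmsd"].append(r)
        series["rgyr"].append(
            radius_of_gyration(pos, np.arange(n_solute))
        )
        series["h2t"].append(
            head_to_tail(pos, topology.head_atom, topology.tail_atom)
        )
        pp, ppbb, pw = hbond_statistics(
            pos, topology, n_solute, n_waters, box=frame.box, criteria=criteria
        )
        series["hb_pp"].append(pp)
        series["hb_ppbb"].append(ppbb)
        series["hb_pw"].append(pw)
        if k % sasa_every == 0:
            tot, pol, npol = sasa_polar_split(pos, topology, n_solute)
            series["sasa_total"].append(tot)
            series["sasa_polar"].append(pol)
            series["sasa_nonpolar"].append(npol)
        energy = getattr(frame, "energy", None)
        if energy is not None:
            for name in ("e_vdw_pp", "e_es_pp", "e_tot_pp",
                         "e_vdw_pw", "e_es_pw", "e_tot_pw"):
                energy_series.setdefault(name, []).append(getattr(energy, name))

    def meas(name: str) -> Measurement:
        arr = np.asarray(series[name], dtype=np.float64)
        if arr.size >= 16:
            m, s = block_average(arr)
        else:
            m = float(arr.mean())
            s = float(arr.std(ddof=1) / math.sqrt(arr.size)) if arr.size > 1 else 0.0
        return Measurement(m, s)

    rmsd_m = meas("rmsd")
    # the size normalization is undefined for very small chains
    # (denominator 1 + ln sqrt(N/100) <= 0 below ~37 residues)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            rmsd100_m = Measurement(
                rmsd100(rmsd_m.mean, max(n_residues, 1)),
                rmsd100(rmsd_m.sem, max(n_residues, 1)) if rmsd_m.sem else 0.0,
            )
        except AnalysisError:
            rmsd100_m = Measurement(float("nan"), float("nan"))
    rmsf_vals = rmsf(all_positions, backbone) if len(all_positions) >= 2 else np.zeros(1)
    helix, sheet, coil = secondary_structure_frequencies(
        all_positions[:: max(1, len(all_positions) // 50)], topology, n_solute
    )
    energy_meas = {}
    for name, vals in energy_series.items():
        arr = np.asarray(vals)
        if arr.size >= 16:
            m, s = block_average(arr)
            energy_meas[name] = Measurement(m, s)
        else:
            energy_meas[name] = Measurement(float(arr.mean()), 0.0)
    return AnalysisSummary(
        rmsd=rmsd_m,
        rmsd100=rmsd100_m,
        rmsf=float(rmsf_vals.mean()),
        rgyr=meas("rgyr"),
        head_to_tail=meas("h2t"),
        n_hb_pp_backbone=meas("hb_ppbb"),
        n_hb_pp=meas("hb_pp"),
        n_hb_pw=meas("hb_pw"),
        sasa_total=meas("sasa_total"),
        sasa_polar=meas("sasa_polar"),
        sasa_nonpolar=meas("sasa_nonpolar"),
        helix_frequency=helix,
        sheet_frequency=sheet,
        coil_frequency=coil,
        energy=energy_meas,
    )
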