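"""Structural and statistical analysis operations against independent
oracles (brute-force rotation search, exhaustive H-bond evaluation,
dense-sampling surface integration, closed forms)."""

import math

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

import mwmd
from mwmd.analysis import (
    AnalysisError,
    HBondCriteria,
    block_average,
    condition_comparison,
    radius_of_gyration,
    rmsd100,
    rmsf,
    sasa,
    secondary_structure_frequencies,
    superpose_rmsd,
)


class TestSuperposeRmsd:
    def test_identical_frames_have_zero_rmsd(self):
        rng = np.random.default_rng(0)
        x = rng.random((10, 3))
        _, r = superpose_rmsd(x, x)
        assert r == pytest.approx(0.0, abs=1e-12)

    def test_pure_rotation_is_removed(self):
        rng = np.random.default_rng(1)
        x = rng.random((12, 3))
        rot = Rotation.from_rotvec([0.3, -1.1, 0.7])
        _, r = superpose_rmsd(rot.apply(x) + 2.0, x)
        assert r == pytest.approx(0.0, abs=1e-10)

    def test_matches_brute_force_rotation_search(self):
        """The closed-form superposition equals a numerical minimum over
        rotation vectors (multi-start local optimization oracle)."""
        rng = np.random.default_rng(2)
        ref = rng.random((10, 3))
        frame = ref + rng.normal(0, 0.05, ref.shape)
        _, r_fit = superpose_rmsd(frame, ref)

        xc = frame - frame.mean(axis=0)
        yc = ref - ref.mean(axis=0)

        def cost(rv):
            return np.sqrt(((Rotation.from_rotvec(rv).apply(xc) - yc) ** 2)
                           .sum(axis=1).mean())

        best = np.inf
        for start in rng.normal(0, 1.5, (12, 3)):
            res = minimize(cost, start, method="Nelder-Mead",
                           options={"xatol": 1e-10, "fatol": 1e-14,
                                    "maxiter": 5000})
            best = min(best, res.fun)
        assert r_fit == pytest.approx(best, abs=1e-6)

    def test_collinear_selection_is_degenerate(self):
        x = np.outer(np.arange(5.0), [1.0, 0.0, 0.0])
        with pytest.raises(AnalysisError):
            superpose_rmsd(x, x)


class TestRmsd100:
    def test_identity_at_100_residues(self):
        assert rmsd100(0.27, 100) == pytest.approx(0.27, rel=1e-14)

    def test_size_normalization_value(self):
        # 0.3 / (1 + ln sqrt(400/100)) = 0.3 / (1 + ln 2)
        assert rmsd100(0.3, 400) == pytest.approx(0.3 / (1 + math.log(2.0)),
                                                  rel=1e-12)

    def test_zero_rmsd_stays_zero(self):
        assert rmsd100(0.0, 250) == 0.0

    def test_small_structures_warn_and_tiny_ones_fail(self):
        with pytest.warns(UserWarning):
            rmsd100(0.2, 39)
        with pytest.warns(UserWarning):
            with pytest.raises(AnalysisError):
                rmsd100(0.2, 10)  # denominator 1 + ln sqrt(0.1) < 0


class TestRmsf:
    def test_static_trajectory_has_zero_fluctuation(self):
        x = np.random.default_rng(3).random((8, 3))
        out = rmsf([x, x, x])
        assert np.abs(out).max() < 1e-12

    def test_two_point_oscillation(self):
        """An atom alternating +-d about its mean with equal occupancy has
        RMSF exactly d (raw estimator: no rigid-body fit to absorb it)."""
        base = np.random.default_rng(4).random((4, 3)) * 5
        d = 0.07
        frames = []
        for sign in (1, -1, 1, -1):
            f = base.copy()
            f[2, 0] += sign * d
            frames.append(f)
        out = rmsf(frames, fit_reference=base, fit=False)
        assert out[2] == pytest.approx(d, rel=1e-6)

    def test_gaussian_jitter_converges_to_sigma_sqrt3(self):
        rng = np.random.default_rng(5)
        base = rng.random((6, 3)) * 4
        sigma = 0.01
        frames = base[None] + rng.normal(0, sigma, (10_000, 6, 3))
        out = rmsf(list(frames), fit_reference=base, fit=False)
        assert np.mean(out) == pytest.approx(sigma * np.sqrt(3), rel=0.05)

    def test_superposition_never_increases_apparent_fluctuation(self):
        rng = np.random.default_rng(12)
        base = rng.random((6, 3)) * 4
        frames = list(base[None] + rng.normal(0, 0.01, (200, 6, 3)))
        fitted = rmsf(frames, fit_reference=base, fit=True)
        raw = rmsf(frames, fit_reference=base, fit=False)
        assert fitted.mean() <= raw.mean() + 1e-12

    def test_single_frame_is_an_error(self):
        with pytest.raises(AnalysisError):
            rmsf([np.zeros((4, 3))])


class TestRadiusOfGyration:
    def test_single_atom_is_zero(self):
        assert radius_of_gyration(np.array([[1.0, 2.0, 3.0]])) == 0.0

    def test_two_unit_masses_two_nm_apart(self):
        x = np.array([[0.0, 0.0, 0.0], [2.0, 0.0, 0.0]])
        assert radius_of_gyration(x) == pytest.approx(1.0, rel=1e-12)

    def test_uniform_ring_converges_to_its_radius(self):
        t = np.linspace(0, 2 * np.pi, 10_000, endpoint=False)
        ring = np.stack([1.7 * np.cos(t), 1.7 * np.sin(t), np.zeros_like(t)],
                        axis=1)
        assert radius_of_gyration(ring) == pytest.approx(1.7, rel=1e-6)


class TestHeadToTail:
    def test_pythagorean_distance(self):
        x = np.array([[0.0, 0.0, 0.0], [3.0, 4.0, 0.0]])
        assert mwmd.head_to_tail(x, 0, 1) == pytest.approx(5.0)
        assert mwmd.head_to_tail(x, 0, 0) == 0.0

    def test_untagged_atoms_raise(self):
        with pytest.raises(AnalysisError):
            mwmd.head_to_tail(np.zeros((2, 3)), None, 1)

    def test_helix_is_shorter_than_extended_chain(self):
        th, ph = mwmd.make_toy_solute("helix_like", 12, seed=1)
        te, pe = mwmd.make_toy_solute("extended", 12, seed=1)
        assert mwmd.head_to_tail(ph, th.head_atom, th.tail_atom) < \
            mwmd.head_to_tail(pe, te.head_atom, te.tail_atom)


class TestHbonds:
    def test_ideal_linear_bond_is_counted_and_long_contact_is_not(self):
        crit = HBondCriteria()
        from mwmd.analysis import _count_hbonds

        donor = np.array([[0.0, 0.0, 0.0]])
        h = np.array([[0.1, 0.0, 0.0]])
        acceptor_close = np.array([[0.3, 0.0, 0.0]])   # H...A = 0.20, 180 deg
        acceptor_far = np.array([[0.4, 0.0, 0.0]])     # H...A = 0.30
        assert _count_hbonds(h, donor, acceptor_close, crit) == 1
        assert _count_hbonds(h, donor, acceptor_far, crit) == 0

    def test_bent_geometry_is_rejected(self):
        from mwmd.analysis import _count_hbonds

        crit = HBondCriteria()
        donor = np.array([[0.0, 0.0, 0.0]])
        h = np.array([[0.1, 0.0, 0.0]])
        # 90-degree donor-H...acceptor angle at admissible distance
        acceptor = np.array([[0.1, 0.2, 0.0]])
        assert _count_hbonds(h, donor, acceptor, crit) == 0

    def test_counts_match_exhaustive_evaluation(self):
        """KD-tree-accelerated counting equals a plain double loop over
        every donor/acceptor pair."""
        from mwmd.analysis import _count_hbonds

        rng = np.random.default_rng(6)
        crit = HBondCriteria()
        donors = rng.random((20, 3)) * 1.2
        hs = donors + rng.normal(0, 0.05, donors.shape)
        hs = donors + 0.1 * (hs - donors) / np.linalg.norm(
            hs - donors, axis=1, keepdims=True
        )
        acceptors = rng.random((20, 3)) * 1.2

        fast = _count_hbonds(hs, donors, acceptors, crit)
        brute = 0
        for k in range(20):
            for a in range(20):
                ha = acceptors[a] - hs[k]
                if np.linalg.norm(ha) > crit.max_h_acceptor_distance:
                    continue
                dh = hs[k] - donors[k]
                cos_ang = np.dot(-dh, ha) / (
                    np.linalg.norm(dh) * np.linalg.norm(ha)
                )
                ang = math.degrees(math.acos(np.clip(cos_ang, -1, 1)))
                if ang >= crit.min_donor_angle:
                    brute += 1
        assert fast == brute

    def test_counts_invariant_under_rigid_motion(self):
        top, pos = mwmd.make_toy_solute("helix_like", 10, seed=2)
        before = mwmd.hbond_statistics(pos, top, top.n_atoms, 0)
        rot = Rotation.from_rotvec([0.5, 0.2, -0.9])
        after = mwmd.hbond_statistics(rot.apply(pos) + 3.0, top, top.n_atoms, 0)
        assert before == after


class TestSasa:
    def test_isolated_sphere_matches_analytic_area(self):
        area = sasa(np.zeros((1, 3)), np.array([0.15]), probe_radius=0.14,
                    n_points=960)
        assert area[0] == pytest.approx(4 * np.pi * 0.29**2, rel=0.01)

    def test_distant_spheres_are_additive(self):
        pos = np.array([[0.0, 0.0, 0.0], [5.0, 0.0, 0.0]])
        radii = np.array([0.15, 0.18])
        areas = sasa(pos, radii)
        iso0 = sasa(pos[:1], radii[:1])[0]
        iso1 = sasa(pos[1:], radii[1:])[0]
        assert areas.sum() == pytest.approx(iso0 + iso1, rel=1e-12)

    def test_overlapping_spheres_match_dense_sampling_oracle(self):
        pos = np.array([[0.0, 0.0, 0.0], [0.25, 0.05, 0.0]])
        radii = np.array([0.15, 0.16])
        fast = sasa(pos, radii, n_points=960).sum()
        dense = sasa(pos, radii, n_points=100_000).sum()
        assert fast == pytest.approx(dense, rel=0.01)

    def test_polar_split_partitions_the_total(self):
        top, pos = mwmd.make_toy_solute("hairpin_like", 8, seed=3)
        total, polar, nonpolar = mwmd.analysis.sasa_polar_split(
            pos, top, top.n_atoms
        )
        assert polar + nonpolar == pytest.approx(total, rel=1e-6)

    def test_too_few_points_rejected(self):
        with pytest.raises(AnalysisError):
            sasa(np.zeros((1, 3)), np.array([0.15]), n_points=50)


class TestSecondaryStructure:
    def test_ideal_helix_is_mostly_helical(self):
        top, pos = mwmd.make_toy_solute("helix_like", 12, seed=1)
        helix, sheet, coil = secondary_structure_frequencies([pos], top,
                                                             top.n_atoms)
        assert helix >= 0.6

    def test_extended_chain_has_no_helix(self):
        top, pos = mwmd.make_toy_solute("extended", 12, seed=1)
        helix, _, _ = secondary_structure_frequencies([pos], top, top.n_atoms)
        assert helix == 0.0

    def test_frequencies_sum_to_one(self):
        for kind in ("helix_like", "extended", "hairpin_like"):
            top, pos = mwmd.make_toy_solute(kind, 9, seed=2)
            h, s, c = secondary_structure_frequencies([pos], top, top.n_atoms)
            assert h + s + c == pytest.approx(1.0, rel=1e-12)


class TestBlockAverage:
    def test_constant_series_has_zero_sem(self):
        mean, sem = block_average(np.full(64, 3.7))
        assert mean == pytest.approx(3.7)
        assert sem == pytest.approx(0.0, abs=1e-12)

    def test_iid_noise_recovers_sigma_over_sqrt_n(self):
        rng = np.random.default_rng(7)
        n = 2**14
        x = rng.standard_normal(n)
        _, sem = block_average(x)
        assert sem == pytest.approx(1.0 / np.sqrt(n), rel=0.15)

    def test_correlated_series_inflates_the_naive_sem(self):
        """AR(1) with rho = 0.9: the blocked SEM must exceed the naive
        (uncorrelated) estimate by at least a factor of two."""
        rng = np.random.default_rng(8)
        n = 2**14
        rho = 0.9
        x = np.empty(n)
        x[0] = rng.standard_normal()
        eps = rng.standard_normal(n) * np.sqrt(1 - rho**2)
        for i in range(1, n):
            x[i] = rho * x[i - 1] + eps[i]
        naive = x.std(ddof=1) / np.sqrt(n)
        _, sem = block_average(x)
        assert sem >= 2.0 * naive

    def test_short_series_rejected(self):
        with pytest.raises(AnalysisError):
            block_average(np.arange(10.0))


class TestConditionComparison:
    def test_identical_conditions_give_zero_change(self):
        s = [{"rgyr": 1.2}, {"rgyr": 1.3}]
        comp = condition_comparison(s, s)
        assert comp.changes["rgyr"].mean == pytest.approx(0.0)
        assert comp.changes["rgyr"].sem == pytest.approx(0.0)

    def test_single_system_ratio_convention(self):
        """eq = 0.270, mw = 0.240 -> change = 0.240/0.270 - 1 ~ -11.1%."""
        comp = condition_comparison([{"rmsd": 0.270}], [{"rmsd": 0.240}])
        assert comp.changes["rmsd"].mean == pytest.approx(0.240 / 0.270 - 1,
                                                          rel=1e-12)
        literal = condition_comparison([{"rmsd": 0.270}], [{"rmsd": 0.240}],
                                       literal_text_order=True)
        assert literal.changes["rmsd"].mean == pytest.approx(
            0.270 / 0.240 - 1, rel=1e-12
        )

    def test_identical_per_system_changes_have_zero_sem(self):
        eq = [{"x": 1.0}, {"x": 2.0}, {"x": 4.0}]
        mw = [{"x": 1.1}, {"x": 2.2}, {"x": 4.4}]
        comp = condition_comparison(eq, mw)
        assert comp.changes["x"].mean == pytest.approx(0.1)
        assert comp.changes["x"].sem == pytest.approx(0.0, abs=1e-12)

    def test_zero_denominator_excludes_the_system(self):
        with pytest.warns(UserWarning):
            comp = condition_comparison([{"x": 0.0}, {"x": 1.0}],
                                        [{"x": 0.5}, {"x": 1.5}])
        assert comp.changes["x"].mean == pytest.approx(0.5)


class TestSummarizeTrajectory:
    def test_full_summary_from_a_short_solvated_run(self):
        """All summary quantities are populated with finite values and
        internally consistent (surface split partitions the total,
        secondary-structure fractions sum to one)."""
        from mwmd.dynamics import initialize_velocities
        from mwmd.forcefield import ForceEvaluator, ReactionFieldParams
        from mwmd.io import Trajectory
        from mwmd.protocol import ConditionSpec, run_production
        from mwmd.analysis import summarize_trajectory
        from conftest import desk_cutoff

        top, pos = mwmd.make_toy_solute("helix_like", 5, seed=6)
        system = mwmd.solvate(top, pos, mwmd.SolvationSpec(wall_distance=0.45),
                              seed=6)
        ev = ForceEvaluator(system.topology,
                            ReactionFieldParams(desk_cutoff(system), 61.0))
        mwmd.steepest_descent_minimize(system, ev, energy_threshold=0.01,
                                       max_steps=150)
        reference = system.positions.copy()
        initialize_velocities(system, 300.0, seed=7)
        traj = Trajectory()
        run_production(system, ConditionSpec.equilibrium(), ev, 2.0,
                       report_interval_ps=0.1, trajectory=traj)
        summary = summarize_trajectory(
            traj, system.topology, system.n_solute, system.n_waters,
            reference,
        )
        assert summary.rmsd.mean > 0
        # the 100-residue normalization is out of domain for a 5-residue
        # chain and must degrade to NaN rather than fail
        assert np.isnan(summary.rmsd100.mean)
        assert summary.rgyr.mean > 0
        assert summary.head_to_tail.mean > 0
        assert summary.n_hb_pw.mean >= 0
        assert summary.sasa_polar.mean + summary.sasa_nonpolar.mean == \
            pytest.approx(summary.sasa_total.mean, rel=1e-6)
        assert summary.helix_frequency + summary.sheet_frequency + \
            summary.coil_frequency == pytest.approx(1.0, rel=1e-9)
        assert "e_es_pw" in summary.energy
        assert np.isfinite(summary.energy["e_es_pw"].mean)
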