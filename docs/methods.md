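# Methods

## Model and scope

`mwmd` implements a nonequilibrium "replacement model" of microwave
heating: rather than imposing an oscillating electric field, the
rotational kinetic temperature of a rigid three-site water solvent is
held above its translational temperature by independent weak-coupling
heat baths. This captures the dipolar-rotation channel through which
microwaves (≈300 MHz–20 GHz) deposit energy in water, while leaving
translations and the solute thermostatted at ambient temperature, so any
structural response of the solute is mediated by solute–solvent
interactions rather than bulk heating.

Units are GROMOS conventions throughout: nm, ps, u, K, kJ/mol, charges
in e. `k_B = 0.00831446 kJ/(mol·K)` and the Coulomb factor
`f = 138.935458 kJ·nm/(mol·e²)` are fixed to this precision so all
derived numbers are bit-reproducible.

## Interactions

* **Water**: canonical SPC — O at −0.82 e, H at +0.41 e, O–H 0.1 nm,
  H–O–H 109.47°, Lennard-Jones on oxygen only (C6 = 2.617×10⁻³,
  C12 = 2.634×10⁻⁶ kJ·mol⁻¹·nm⁶/nm¹²). Geometry is maintained purely by
  constraints.
* **Solute**: a united-atom toy peptide (N, CA, C, O plus one side-chain
  bead per residue) with harmonic bonds and angles, periodic dihedrals
  (stiff trans ω, soft threefold φ/ψ), dipolar backbone charges
  (N −0.31, CA +0.31, C +0.45, O −0.45 e) and a seed-controlled fraction
  (default 20%) of ±1 e side-chain beads. It is a stand-in for curated
  protein structures at desk scale, not a transferable force field.
* **Nonbonded**: Lennard-Jones with plain truncation plus
  reaction-field Coulomb, `E = f q_i q_j (1/r + crf·r²/(2Rc³) −
  (1+crf/2)/Rc)` with `crf = 2(ε−1)/(2ε+1)`, ε_rf = 61, zero ionic
  screening. The shift zeroes the electrostatic pair energy at the
  cutoff. Excluded pairs (1–2, 1–3, intra-water) keep the reaction-field
  correction beyond 1/r (GROMOS convention); 1–4 pairs interact at full
  strength. LJ pair parameters combine geometrically, which is what the
  fast kernels assume (non-geometric tables are rejected).
* **Cutoff**: the protocol reference value is 1.4 nm. Minimum-image
  validity requires box edges ≥ 2×cutoff, so the desk-scale systems this
  package targets (216–512 waters, boxes of 1.9–2.5 nm) run at the
  largest admissible cutoff, capped at 0.9 nm in the shipped runs. The
  thermostat steady states were checked to be insensitive to cutoffs
  between 0.7 and 1.2 nm.

Energies are accumulated into intra-solute (pp), solute–solvent (pw) and
solvent–solvent buckets during the same sweep that computes forces, so
the Table-style decomposition costs nothing extra. Water–water
interactions go through a molecule-block kernel that skips whole
molecule pairs by O–O distance (bound: no site pair can be inside the
cutoff if the O–O distance exceeds cutoff + 0.21 nm); it is numerically
identical to the general O(N²) reference sweep, which remains in the
code and is asserted equal in the tests.

## Integration, constraints, thermostat

Leapfrog with Δt = 2 fs. After each position update, solute bonds are
SHAKE-projected (relative tolerance 10⁻⁴, max 500 iterations) and water
geometry is restored by analytic SETTLE (degenerate trial geometries
fall back to converged SHAKE); constrained velocities are recovered as
(x_new − x_old)/Δt. NVE propagation of a 216-water box drifts < 0.02%
over 10 ps under this scheme.

Per step, after constraints and any scheduled global-motion removal, the
kinetic energy is partitioned and each bath's velocities are scaled by
the Berendsen factor with τ = 0.01 ps; water COM and internal velocity
components are scaled independently and recombined. λ is capped at 1.25
per step, which protects cold starts on tiny systems (the cap never
binds in steady state). Centre-of-mass motion of all atoms is removed
every 1000 steps; the solute's net linear and angular momentum are
removed every step when roto-translational constraints are active.
Degree-of-freedom bookkeeping: each rigid water contributes 3+3 dof;
the solute contributes 3N minus bond constraints minus 6 (or 3 for
COM-only removal); monatomic ions count with the translational bath.

Pressure coupling (Berendsen, target 1 atm, κ_T = 4.5×10⁻⁵ atm⁻¹,
molecule-COM coordinate scaling so constraints stay satisfied, μ clamped
to [0.95, 1.05]) is used only in the final equilibration cycle; the
instantaneous pressure uses the pair virial plus a constraint-force
virial estimated from the SETTLE/SHAKE position corrections. Production
is constant-volume.

## Build and equilibration protocol

Waters are placed on a jittered lattice at 997 kg/m³ (box cubic for
perfect-cube counts, mildly rectangular otherwise) with orientations
resampled so no intermolecular site pair starts closer than 0.16 nm —
SPC hydrogens carry no Lennard-Jones core, so close H contacts must be
excluded at build time. Solvation retains waters whose geometric centre
is ≥ 0.23 nm from every solute atom, with a 1.2 nm solute–wall distance
at full scale (smaller walls in desk-scale tests, stated per run).
Na⁺/Cl⁻ pairs are added by replacing waters > 0.4 nm from the solute,
`n_pairs = round(c·N_w/55.345)` at c = 0.15 mol/L, then counter-ions are
removed (or ions added) for exact electroneutrality. Steepest-descent
minimization (initial step 0.01 nm, max 0.05 nm, grow ×1.2 / shrink
×0.5, thresholds 0.001/0.01 kJ/mol, 100–1000 steps) keeps waters rigid
via per-trial SETTLE projection.

Equilibration heats 50→300 K in six 20 ps cycles (10,000 × 2 fs each)
while a solute position restraint decays from 25 MJ/(mol·nm²) by ×0.1
per cycle; the microwave schedule inserts one cycle raising the
rotational bath to 700 K after the ladder; the final two cycles switch
on roto-translational constraints and pressure coupling: 8 cycles
(160 ps) for equilibrium, 9 (180 ps) for microwave. "Reduced by
one-tenth" is read as ×0.1 per cycle (a ×0.9 reading would leave the
restraint strong at release); the roto-translational and pressure
cycles are counted as separate cycles, the only reading consistent with
160 ps = 8 × 20 ps alongside six heating increments.

## Thermostat steady state under the microwave condition

With all baths at 300 K the measured temperatures recover the setpoint
to < 0.1%. Under the microwave condition the model exhibits a genuine
steady-state offset: T_rot ≈ 678 K and T_trans ≈ 322 K for targets
700/300 K. A thermostat-off relaxation from the driven state shows the
rotational–translational gap decaying with an intrinsic coupling time
τ_c ≈ 0.15 ps — the expected sub-picosecond librational energy transfer
of liquid water — and weak coupling balances that flux at an offset of
ΔT·τ/(2τ_c) ≈ 22 K per bath for τ = 0.01 ps. The offsets are unchanged
under a 1 fs timestep, cutoffs of 0.7–1.2 nm, box sizes of 216–512
waters, and an added rigid-body velocity projection, and they scale
linearly with τ; they are a property of the model at the mandated
coupling time, not an integrator artifact. Consequently the acceptance
suite's 3% setpoint bands are met marginally (rotation, −3.1%) or not
(translation, +7.3%) and the corresponding assertions are expected to
fail while the equilibrium-condition checks pass; the acceptance script
reports the temperatures actually measured.

## Analysis conventions

* RMSD: backbone atoms after backbone Kabsch superposition (via
  scipy's `Rotation.align_vectors`); reflections excluded. RMSD100
  normalization divides by `1 + ln √(N/100)` and warns below 40
  residues. Both raw and normalized values are always reported.
* RMSF: per-atom fluctuation about the time-mean after superposition by
  default; a `fit=False` estimator exists because the six fitted dof
  absorb a `√(1 − 6/3N)` share of isotropic fluctuations, which matters
  for the small toy solutes.
* Hydrogen bonds: H···acceptor ≤ 0.25 nm and donor–H···acceptor angle
  ≥ 135°. Backbone amide hydrogens are reconstructed 0.1 nm from N,
  anti to the preceding carbonyl, since the united-atom solute carries
  no explicit H. Solute–water counts include both donor directions.
  "Structure-forming" intra-solute bonds are the backbone–backbone
  subset.
* SASA: Shrake–Rupley with a deterministic golden-spiral point set,
  probe 0.14 nm, 960 points per atom; per-residue areas are split by
  the fixed polar/nonpolar residue tables in `params.py`. The tables
  place Gly and Pro with the polar class, following the source lists
  used for the split; the classification is an argument of the API.
* Secondary structure: a simplified backbone-H-bond assignment using
  the classic four-distance electrostatic energy with a −2.09 kJ/mol
  threshold; helix from i→i+4 patterns, sheet from non-local bridges,
  coil otherwise.
* Uncertainties: Flyvbjerg–Petersen blocking; the SEM is taken from the
  first plateau (successive estimates within 5%) or the deepest level.
* Condition comparison: per system `(mean_MW/mean_eq) − 1`, so
  quantities that shrink under the microwave condition are negative;
  SEM is the standard deviation of per-system changes over √n. The
  literal eq/MW ordering is available via a flag.

## What the scaled-down experiments do and do not show

The shipped experiments use 216 waters (setpoint runs) and an
8–10-residue toy peptide in ≥300 waters with 50 ps production per
condition and three velocity seeds. The two condition legs of each seed
branch from the same settled state, so slow residual equilibration of
the solute–water interface cancels in the paired comparison instead of
biasing the later leg. At that scale the package
demonstrates the mechanism and the *direction* of the microwave effect —
consistently fewer solute–water hydrogen bonds and a less negative
solute–water electrostatic energy under rotational heating — but not
the magnitudes reported for protein sets at hundreds of nanoseconds,
which would require both realistic protein force-field parameters and
orders of magnitude more sampling. The toy solute also lacks explicit
amide hydrogens, real side-chain chemistry and secondary-structure
heterogeneity, so secondary-structure statistics on it are
illustrative only.

## Numerical and design notes

* Exclusions are encoded as 64-bit per-atom windows in the nonbonded
  sweep (exclusions are always intramolecular and near-diagonal in the
  fixed atom order), which keeps the inner loop branch-light and avoids
  the catastrophic cancellation of a subtract-after-add exclusion pass.
* Trajectories use a small versioned little-endian binary format so
  checkpointed segments concatenate bit-identically; a text exporter is
  provided. Configs are flat `key = value` text with units in the key
  names, unknown keys rejected, seeds mandatory, and a config hash
  embedded in outputs.
* The MD loop is free of randomness; restarts from a carried-over state
  reproduce the uninterrupted trajectory exactly.
* Known limitations: no Ewald/PME, no twin-range cutoffs, single
  rectangular box, atom-based truncation for non-water pairs,
  molecule-based skip only as an exact optimization, toy ion and solute
  parameters, and the Berendsen (non-canonical-ensemble) thermostat
  inherited from the modelled protocol.
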