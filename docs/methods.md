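# Methods

## Model

The quantum center (QC) is represented by `n_states` gas-phase electronic
states (default 7: ground plus six excited states, the usual size for a
nucleobase treated at the TD-DFT level): energies `E_i`, per-state atomic
partial charges `q_{N,i}` summing to the species total charge, permanent
dipoles and a real symmetric transition-dipole matrix `μ_ij`. Per
classical frame the perturbed Hamiltonian is assembled as

* diagonal: `H_ii = E_i + Σ_N q_{N,i} 𝒱(R_N)` — the perturbation operator
  expanded separately within each atomic region and truncated at the
  atomic monopole. The atomic regions never materialize because the
  charges are pre-assigned per atom; an optional per-state atomic-dipole
  block is reserved in the schema but not read by the engine (a possible
  future higher-order term).
* off-diagonal: `H_ij = −E(r_0)·μ_ij` — the dipolar approximation of the
  QC-based multipolar expansion, with the field evaluated at the
  *frame-instantaneous* center of mass (built from the state set's masses
  and the frame's QC coordinates, not the gas-phase geometry — the
  expansion should be centered where the QC actually is).

The constant `q_T 𝒱(r_0)` term of the QC-based expansion contributes only
to the diagonal (unperturbed states are orthonormal) and is superseded
there by the atom-based expansion.

Assumptions inherited from this construction: the environment is purely
electrostatic (fixed point charges, no polarization, no exchange
repulsion toward the QC states); the unperturbed basis is complete enough
that the perturbed ground state is captured by mixing within it; nuclear
dynamics are classical and sampled independently of the electronic
perturbation.

## Redox estimators

Vertical vs adiabatic is a property of the *state set*, not of the
frames: the vertical cation carries the neutral's geometry (electron
removed at fixed nuclei), the adiabatic cation its own relaxed geometry
and charges. QC atom positions always come from the trajectory frame, so
a vertical and an adiabatic gap are evaluated on identical configurations
and share one skip set.

* `VIE = ⟨Δℰ_vert⟩_red`; `AIE = ⟨Δℰ_adia⟩_red`.
* `ΔA = (⟨Δℰ_adia⟩_red + ⟨Δℰ_adia⟩_ox)/2` — the mean of the two free-
  energy bounds, exact under equal-variance Gaussian gap statistics
  (linear response). Mixing vertical gaps into `ΔA` raises an error.
* Ionic-relaxation free energies of the two end states are represented by
  an immutable flag recording the cancellation assumption
  (`ΔA_red^ion ≈ ΔA_ox^ion`, contribution 0).
* `V_red = ΔA/n − V_SHE`. The sign convention is pinned by two published
  constraints: the absolute SHE potential (4.281 V) is *subtracted*, and
  physically positive oxidation free energies must reproduce the known
  ordering of nucleoside reduction potentials (guanosine < adenosine <
  thymidine). Per-electron eV equals volts, so no Faraday constant
  appears.
* Reorganization energy `λ = (⟨Δℰ⟩_red − ⟨Δℰ⟩_ox)/2` is reported as a
  diagnostic; a negative value on user data triggers a warning, not an
  error (it is guaranteed non-negative only for equilibrium sampling).
* Gas-shift correction: computed aqueous energies can be shifted by
  `gas_exp − gas_calc` of the bare chromophore's VIE; the same shift is
  applied to VIE, AIE and ΔA (the published procedure approximates the
  adiabatic shift by the vertical one).
* Errors: block averaging with 3 contiguous equal blocks (remainder
  frames at the end dropped, for determinism); the standard deviation of
  the block means over √3 is the SEM. The error of `V_red` is
  `err(ΔA)/n`; `V_SHE` is treated as exact.

## Electrostatics and periodic boundaries

Bare Coulomb sums with `k_e = 1.439964 eV·nm/e²` over all environment
points, minimum-image wrapping into `(−L/2, L/2]` per component for cubic
boxes. No Ewald summation, reaction field or cutoff: the perturbation is
whatever the simulated box's charges exert, which is the simplest
well-defined convention; the truncation scan quantifies the sensitivity
to the solvent count. Raw coordinates are never wrapped on read — images
enter only inside displacement evaluation. An environment charge closer
than `d_min = 0.05 nm` to any evaluation point raises a loud
near-singularity error naming the frame and charge (classical
configurations occasionally clash; a silent 1/r spike would corrupt the
ensemble averages). Per-frame policy is configurable: skip-with-log
(default; skipped counts are reported and the same skip set applies to
both species of a gap) or hard error.

## Numerical choices

* Hamiltonians are symmetrized exactly (`(H+Hᵀ)/2`) after assembly;
  `diagonalize` requires symmetry within 1e-10 eV.
* Eigenvalues ascend with a stable sort; each eigenvector's largest-
  magnitude coefficient is made positive, so signs are deterministic
  across BLAS implementations. The engine is invariant to flipping the
  phase of any state's transition-dipole row/column pair (tested).
* The per-frame ground state is the lowest eigenvalue — no adiabatic
  state tracking across frames. The minimum ground/first-excited gap per
  frame is written to the per-frame tables as a crossing diagnostic.
* Units package-wide: nm, e, e·nm (1 D = 0.0208194 e·nm accepted on
  input), eV, V. Output tables print 4 decimals.

## Synthetic data

The generator replaces the two external inputs (quantum-chemical state
sets; MD trajectories) with fabrications whose answers are known:

* `make_synthetic_pair` builds a valid reduced/oxidized pair with exact
  unperturbed vertical gap `gap0` (default 8.97 eV, a realistic
  gas-phase nucleobase value), adiabatic ground energy exactly
  `relaxation` (default 0.30 eV) below the vertical one, and a permanent
  dipole magnitude increase upon oxidation of `dipole_shift` (default
  1.8 D — the feature that drives the anomalously large solvent
  stabilization of thymine-like cations). Excited-state spacings,
  per-state charges and transition dipoles are seeded random but always
  satisfy every schema invariant.
* Solvent: rigid three-site water-like groups with SPC charges
  (−0.82/+0.41/+0.41 e), OH 0.1 nm, HOH 109.47°. Defaults mirror the
  study conditions the package emulates: cubic box of 3.1 nm side,
  1050 groups, 300 K (the convergence analysis uses 1044, the reference
  water count of the solvent-count scan). No Lennard-Jones — excluded
  volume is a hard-core rejection (0.26 nm between group centers,
  0.30 nm exclusion radius around QC atoms), since electrostatics is the
  only channel the PMM reads.
* `iid` mode places groups uniformly with uniform orientations (fast;
  the two redox ensembles are then statistically identical — good for
  unit tests and for per-frame properties like the truncation scan).
* `metropolis` mode runs single-group-move Markov-chain Monte Carlo on
  the point-charge Coulomb energy at the spec temperature, with the QC's
  ground-state charges of the sampled species fixed. Defaults: burn-in
  50 sweeps, stride 10 sweeps between frames, translation step 0.012 nm,
  rotation up to 0.5 rad; acceptance rates land in the 0.2–0.4 range on
  the toy systems and are recorded in the ensemble metadata. This
  produces genuinely responsive ensembles — the oxidized run polarizes
  the solvent toward the cation — which is what the free-energy bound
  structure needs. It is used at toy scale (tens of groups); a pure-
  Python sampler at ~1000 groups would be wastefully slow, and the
  bound-ordering analyses do not need it.
* `gaussian_gap_series` emits two seeded Gaussian ensembles with an
  analytic mean-of-bounds answer, for estimator tests.

What the generator does **not** emulate: real force-field structure
(hydrogen-bond networks, Lennard-Jones packing, counterion chemistry),
long trajectories with correlated frames, intramolecular QC flexibility,
and realistic per-state charge redistributions. Passing tests therefore
demonstrate the correctness of the PMM/estimator machinery under
controlled statistics, not the accuracy of any force field or DFT input
on real nucleosides. The published nucleoside numbers enter only through
the reporting layer (`pmmredox.reference`), which derives corrected
columns and differences from the literature tables.

## Problem sizes

Default analysis sizes were chosen so the whole study runs in minutes on
one CPU: 120 frames per Metropolis ensemble of 20 groups for the
bound-ordering analysis, 200 iid frames of 1044 groups for the
solvent-count scan, 10⁴ samples for Gaussian-estimator checks. All
stochastic stages take an explicit integer seed and are bitwise
reproducible.

## Known limitations

* Monopole-only atomic regions on the diagonal; the atomic-dipole term is
  schema-reserved but unimplemented.
* No environment polarization, no Ewald; minimum image only.
* Ground-state-only observables (excited energies appear only in
  crossing diagnostics).
* The ionic-relaxation cancellation flag is immutable; systems where the
  counterion relaxation differs strongly between end states will bias
  `ΔA`.
* GRO reading is fixed-column and single-box-vector (cubic); binary
  trajectory formats are out of contract.
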