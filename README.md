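# pmmredox

Perturbed-matrix-method (PMM) redox thermodynamics for solvated
chromophores: build and diagonalize the electrostatically perturbed
electronic Hamiltonian of a quantum center along classical point-charge
trajectories, and derive vertical/adiabatic ionization energies,
oxidation free energies and standard reduction potentials from the
resulting energy-gap ensembles.

## The problem

One-electron oxidation of DNA — the initial step of oxidative damage and
of hole transport along the double helix — is characterized by two
observables that are hard to measure and hard to compute: the vertical
ionization energy (VIE) of a solvated nucleoside and its standard
reduction potential `V_red`. Continuum-solvent quantum chemistry misses
the atomistic fluctuations of the environment; brute-force QM/MM cannot
sample enough configurations. The PMM splits the difference: the
chromophore (the quantum center, QC — here a nucleobase) is described by
a basis of gas-phase electronic states computed once, and the
environment of every classical configuration enters as an electrostatic
perturbation of that small Hamiltonian, which is diagonalized per frame
at negligible cost.

## The model

For each frame, in the basis of `n` unperturbed states with energies
`E_i`, per-state atomic charges `q_{N,i}` and transition dipoles
`μ_ij`:

    H_ii = E_i + Σ_N q_{N,i} · 𝒱(R_N)          (atom-based expansion,
                                                 monopole per atomic region)
    H_ij = − E(r_0) · μ_ij      (i ≠ j)         (dipolar approximation at
                                                 the QC center of mass)

where `𝒱(R_N)` is the Coulomb potential of the environment point charges
at QC atom `N` and `E(r_0)` the field at the instantaneous center of
mass (minimum-image periodic wrapping, no cutoff). The lowest eigenvalue
per frame is the perturbed ground-state energy; the oxidized-minus-
reduced difference `Δℰ` forms a gap series per ensemble.

With the two equilibrium ensembles (QC neutral / QC radical cation) the
adiabatic gap averages bracket the oxidation free energy, and assuming
the ionic-relaxation terms of the two end states cancel:

    ⟨Δℰ⟩_ox ≤ ΔA ≤ ⟨Δℰ⟩_red,      ΔA = (⟨Δℰ⟩_red + ⟨Δℰ⟩_ox) / 2

(exact for Gaussian gap statistics of equal variance). Then

    VIE = ⟨Δℰ_vertical⟩_red,       V_red = ΔA / n − V_SHE,

with `V_SHE = 4.281 V` and `n` the number of electrons; per-electron eV
is numerically volts. Statistical errors come from block averaging over
three contiguous trajectory subparts; computed energies can be shifted
by the gas-phase experimental-minus-calculated VIE of the bare base
("corrected" values).

Because the original DFT state sets and 100 ns MD trajectories are not
redistributable, the package ships a first-class synthetic generator: a
fabricated redox species pair with prescribed vertical gap, relaxation
and dipole change upon oxidation, and solvent ensembles of rigid
three-site water-like charge groups (−0.82/+0.41/+0.41 e) sampled either
independently or by Metropolis Monte Carlo, which yields genuinely
responsive reduced/oxidized ensembles.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
inputs, writing tables under `results/`:

```sh
python analysis/01_generate_inputs.py      # species pair + MC solvent ensembles
python analysis/02_perturbed_energies.py   # per-frame PMM gap tables
python analysis/03_redox_summary.py        # VIE, AIE, ΔA, V_red
python analysis/04_solvent_convergence.py  # VIE vs number of waters retained
python analysis/05_literature_tables.py    # corrected nucleoside tables
```

Step 03 prints, for the default synthetic chromophore (unperturbed
vertical gap 8.97 eV, relaxation 0.30 eV, 20-group Metropolis water box):

```
VIE 8.9815 +- 0.1323 eV, AIE 8.7938 eV, dA 8.2368 +- 0.1050 eV, reorganization 0.5570 eV
V_red 3.9558 +- 0.1050 V vs SHE (gas shift applied: 0.1700 eV)
```

Reading: the solvent barely moves the ensemble-averaged VIE here (small
box, neutral solute) but the oxidized ensemble stabilizes the cation by
about 1.1 eV relative to the reduced one, giving a reorganization energy
of 0.56 eV; the mean-of-bounds free energy sits between the two gap
averages, and subtracting `V_SHE` converts it to a reduction potential.
Step 05 reproduces the published nucleoside reporting arithmetic, e.g.
guanosine aqueous VIE 7.66 eV → 7.98 eV corrected, and reduction-
potential differences vs adenosine of −0.21 / +0.47 / +0.61 V for
guanosine / thymidine / cytidine.

A `pmmredox` console command exposes the same stages
(`generate`, `energies`, `redox`, `scan`, `report`, `run`); `run` drives
everything from a YAML config (see `pmmredox.config.RunConfig`).

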