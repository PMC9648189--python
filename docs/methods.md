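# Methods

## Model

The dispersion interaction between a solute A (explicit wavefunction) and
a solvent B (dielectric continuum) is treated at second order in the
dipole coupling.  The solvent molecule is modeled as a single-pole
(Drude) polarizable center; summing over a continuum of such centers with
number density n_B and using the Clausius–Mossotti relation
n_B α_B = (3/4π)·(η²−1)/(η²+2) turns the pairwise −C6/R⁶ interaction into
a volume integral over the cavity exterior of the solute's damped
electric-field fluctuation S²(r).  The chain of identities is:

1. **Field fluctuations.**  For B at r, second-order perturbation theory
   with the Unsöld (average-energy) closure on A gives
   E_disp(r) = −(α_B/2)·[W_B/(W_A+W_B)]·S²(r), where
   S² = σ_L²+σ_T1²+σ_T2² is the trace of the covariance of the electronic
   field of A at r.  The trace is basis-independent; the longitudinal axis
   is taken from the electronic center of charge of the state under study
   and is reported for diagnostics only.
2. **Casimir–Polder with an excited reference.**  With A in excited state
   *a*, de-excitation channels make some transition energies negative.
   Choosing an auxiliary energy Ω with ΔE_A(0→a) < Ω < ΔE_B(0→1) and
   shifting u → u+Ω (solute), v → v−Ω (solvent) keeps every denominator
   positive without changing u+v, so the imaginary-frequency integral
   applies to the shifted polarizabilities.  The effective frequencies
   become W_A = I_A+Ω and W_B = I_B−Ω (note W_A+W_B = I_A+I_B).
3. **Solvent response.**  The shifted static solvent polarizability obeys
   the exact identity 1/(v−Ω) = 2v/(v²−Ω²) − 1/(v+Ω).  The first term is
   the dynamic polarizability at real frequency Ω — kept exact because it
   is resonantly enhanced as Ω approaches the solvent absorption onset —
   while the Unsöld closure is applied only to the regular second term:
   ᾱ_B(0) = 2α_B(Ω) − α_B(0)·I_B/(I_B+Ω).  Applying Clausius–Mossotti to
   both α_B(0) and α_B(Ω) yields the prefactor

       Γ(Ω) = (3/8π)·[2·CM(η(Ω)) − CM(η(0))·I_B/(I_B+Ω)]·W_B/(W_A+W_B),

   which reduces exactly to (3/8π)·CM(η(0))·I_B/(I_A+I_B) at Ω = 0.
4. **Free energy.**  ΔG_disp = −Γ(Ω)·∫_{r∉C_A} S²(r) d³r.  The shift is
   the excited-minus-ground difference; negative = red.

Every closed form above is cross-checked in the test suite against the
`casimir_polder` module's independent machinery: adaptive quadrature of
the Casimir–Polder kernel (1e-10), exact sums over discrete levels
(R⁶-scaling to 1e-10, large-R agreement with the polarizability integral
to 1e-6), and quadrature of the Ω-shifted polarizabilities against the
closed-form C6 (1e-6).

### Asymptotics and the damping function

The variance of the electric field of a bound charge distribution decays
as r⁻⁶: the monopole field is configuration-independent, so the leading
*fluctuating* multipole is the dipole, and S²(r) → 2⟨Δμ²⟩/r⁶ for an
isotropic state (verified numerically to 1% at r = 200 bohr).  The
exterior integral therefore converges with an O(1/r_max³) tail, which is
added analytically from the amplitude S²·r⁶ read off at the truncation
radius.

At short range each electron's Coulomb field is damped by
f₂(x) = 1 − e^(−x)(1+x+x²/2) at x = b·s (s the electron–probe distance),
the order-2 member of the incomplete-gamma (Tang–Toennies) family.  It
cancels the 1/s² singularity (f₂ ~ x³/6), so S² is finite everywhere,
including inside the density.  f₂ is evaluated by its series below
x = 0.05 to avoid cancellation.

### The damping parameter b

For a single atom, b derives from the radius R at which half an electron
lies outside the sphere; for molecules, equal spheres sit on the heavy
atoms and the target escape is 0.5 electrons per sphere, reduced for
sphere overlap by the pairwise lens-volume fraction (capped at N−1, so
fully coincident spheres behave as one).  The radius is found by
bracketed root finding to |fraction − target| < 1e-6, with the radial
mass inside the sphere union computed from closed-form radial CDFs along
exact ray/union intersections (no grid masking).  The final map is
b = κ/R with κ = 3.3: a monotone one-parameter rule of the right
magnitude for the packaged carbonyl values (b ≈ 1.6–1.7 bohr⁻¹),
overridable via `radius_to_b=`.  In routine use b is taken directly from
the packaged per-state table.

## Numerical choices

- **Metropolis sampler**: single-electron Gaussian moves (step 0.8 bohr),
  64 interleaved independent walkers, burn-in 1000 sweeps, stride 10 —
  standard variational-Monte-Carlo practice sized for the ≤2-electron
  model systems.  Identical seeds give bitwise-identical snapshots.
  Divergence (a density that grows without bound) is detected from
  non-finite log-densities or runaway walkers.
- **S² errors**: jackknife over snapshot blocks; all probes of a grid (and
  all quadrature nodes of a ΔG) share one snapshot set, so errors are
  correlated by construction and curve shapes are not noise-dominated.
- **Quadrature oracle**: per-electron spherical quadrature with the radial
  panel split at the probe distance (Gauss–Legendre 160×160 by default,
  relative error ≪ 1e-6 on the packaged models).  The fast evaluator
  tabulates per-marginal moment profiles on 400 log-spaced distances and
  interpolates monotonically (PCHIP in log–log), switching to the exact
  r⁻⁶/r⁻² power laws beyond the profile range.
- **Exterior quadrature**: rays from the cavity centroid on a
  Gauss–Legendre × uniform angular grid; on each ray the exterior
  sub-intervals of [0, r_max] are computed exactly from the sphere
  geometry and receive Gauss–Legendre radial nodes.  No node is ever
  inside a sphere, boundary points count as outside, and the sharp
  boundary costs no radial accuracy (shell and two-sphere complement
  volumes converge to <0.5% at modest orders).  r_max defaults to the
  cavity reach + 25 bohr; an optional order-doubling check fails the
  calculation if the integral moves by more than 2%.
- **Units**: Hartree/bohr internally; eV, cm⁻¹ and nm at the interface
  with frozen CODATA-2018 constants (1 Hartree = 27.211386245988 eV,
  1 eV = 8065.543937 cm⁻¹, hc = 1239.841984 eV·nm).
- **Anchoring**: monotone PCHIP interpolation of the ground curve and
  Brent root finding; no extrapolation outside the sampled factor range.

## The synthetic two-state solute

Real chromophores require correlated multi-electron wavefunctions that
are outside this package's scope; the shipped model is two independent
electrons in isotropic Gaussian orbitals (σ₀ = 1.2 bohr — a typical
valence-cloud extent), whose excited state is the ground state dilated by
a diffuseness ratio of 1.25, with I_ground = 0.38 Ha, ΔE = 4.5 eV
(I_excited = I_ground − ΔE) and b = 1.6 bohr⁻¹ — magnitudes matching the
packaged carbonyl table.  The default solvent is cyclohexane, the one
solvent whose absorption onset (7.44 eV) ships with the package; onsets
for other solvents are user inputs.

The model reproduces the features the method is built on — a more
diffuse, more polarizable excited state, red shifts of a few tens of meV,
near-parallel scaling curves, weak Ω-sensitivity — but it has no nodal
structure, no electron correlation, no anisotropy and no real molecular
geometry.  Passing tests therefore demonstrate the correctness of the
estimator, the quadratures and the prefactor algebra, not the accuracy of
any particular molecular prediction.

## Known limitations

- Product (independent-electron) densities only in the analytic oracles;
  user-supplied correlated densities are sampled by Monte Carlo but have
  no deterministic cross-check.
- The solvent absorption onset is consumed as data; the package does not
  compute solvent spectra, and η(Ω) beyond the transparent region of the
  dispersion fit must be supplied explicitly (`eta_omega_override=`).
- No electrostatic, Pauli-repulsion or cavitation terms, and no
  self-consistent coupling of ΔG_disp into a Hamiltonian: the dispersion
  term is a perturbative correction computed from the isolated-solute
  wavefunction.
- The b-estimator's radius→b map is a documented one-parameter choice;
  where tabulated b values exist they should be preferred.
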