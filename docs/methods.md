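# Methods

This note documents the models, conventions and numerical choices behind
`fmovqe`: a two-body fragment molecular orbital (FMO2) code whose
per-fragment electron-correlation energies are computed by a statevector
variational quantum eigensolver (VQE).

## Scope and model systems

The package treats clusters of hydrogen molecules and ions (total charge
−1, 0 or +1) in the STO-3G and 6-31G basis sets.  Hydrogen carries only
s-type Gaussians in both sets, so every required integral has a closed
form; the AO integral layer is therefore written in-package and validated
against hand-computable limits and published H₂/STO-3G tables.  All
energies are in Hartree (Ha); coordinates are Å in files and Bohr
internally (1 Å = 1.88972612463 Bohr).

## Fragmentation

Each H₂ molecule is one fragment; an excess hydride ion (H⁻) is its own
one-atom fragment; a cationic cluster folds the extra proton-bearing atom
into its nearest H₂, giving an H₃⁺ fragment.  Every fragment is closed
shell by construction.  Automatic fragmentation is a greedy
nearest-neighbour perfect matching with deterministic index tie-breaks, so
it is invariant under atom permutations up to fragment relabelling.  The
H₃⁺-core rule for cations is a design choice (only the whole-molecule and
hydride cases are forced by the physics); an explicit fragment-scheme file
(`atom indices ; charge` per line) overrides it.

## Embedded SCF and the SCC loop

Monomers and dimers are solved by closed-shell Roothaan SCF (DIIS, subspace
8, core-Hamiltonian initial guess; convergence max|ΔD| < 1e−8 and
|ΔE| < 1e−10 Ha, at most 200 cycles).  The embedding operator of a
subsystem is the *exact* electrostatic potential of all other fragments:
environment-nuclei attraction plus the Coulomb field of the environment
densities evaluated with full cross-fragment two-electron integrals — no
point-charge or density-fitting approximation.  The systems here are small
enough that exactness costs little, and it makes the N_f = 2 collapse
identity (below) hold to machine precision.

The self-consistent-charge (SCC) loop starts every monomer from its
isolated SCF and then repeatedly rebuilds all embedding operators from the
previous sweep's densities and re-solves all monomers (synchronous,
Jacobi-style refresh, so the fixed point does not depend on fragment
order).  It stops when no monomer energy moves by more than 1e−7 Ha
(at most 100 sweeps).  Dimers are solved once each in the field of the
N−2 remaining fragments with environment densities frozen at their
SCC-converged values — the standard FMO2 practice; a dimer-level SCC would
change nothing at these separations but would break the clean telescoping
of the pair sum.

## Energy assembly and the two conventions

With monomer energies E_I and dimer energies E_IJ,

    E(FMO2) = Σ_I E_I + Σ_{I>J} (E_IJ − E_I − E_J),

and the same pair form for the correlation energies.  Two readings of
"E_I" are exposed:

* **standard** (default): internal energies E′ (embedding interaction
  subtracted) plus the density-relaxation coupling Tr(ΔD_IJ·U_IJ) per
  pair, ΔD_IJ = D_IJ − (D_I ⊕ D_J).  With this expression the pair sum
  telescopes exactly: for two fragments FMO2 *equals* the conventional
  whole-system calculation (the central correctness oracle of the
  package), and it matches what production FMO codes evaluate.
* **paper**: the embedded totals are used literally.  This double-counts
  environment interactions whenever three or more fragments interact, but
  coincides with "standard" at N_f = 2 and in the non-interacting limit;
  it is retained for pedagogy and comparison.

Both conventions carry intra-subsystem nuclear repulsion and the scalar
environment term (subsystem nuclei against environment nuclei and
densities) inside the embedded total, which is what makes the N_f = 2
identity exact.

## Qubit Hamiltonians

A converged fragment SCF is transformed to MO integrals (the embedding
operator rides inside the one-electron matrix; the scalar terms ride in
E0, so ⟨HF|H|HF⟩ reproduces the embedded RHF energy — asserted at 1e−10 Ha
for every fragment in the tests).  An optional active space folds frozen
orbitals into E0 and an effective one-electron matrix; the benchmark runs
use the full space.  Jordan–Wigner mapping uses one qubit per spin
orbital in *blocked* order (all α then all β, qubit 0 = least significant
statevector bit); Pauli coefficients below 1e−12 are pruned and identical
words merged.  A fragment therefore needs 4/8 qubits (STO-3G
monomer/dimer) and 8/16 qubits (6-31G).

## VQE

**UCCSD.**  The ansatz is exp(T − T†)|RHF⟩ with spin-conserving singles
and doubles.  The summed generator is exponentiated *exactly* on the
statevector (sparse Krylov `expm_multiply`) rather than Trotterized: the
reference results are statevector simulations with no stated Trotter
ordering, and exact exponentiation removes that ambiguity.  Initial double
amplitudes are spin-orbital MP2 values, screened at |t| < 1e−3 (the
screening threshold used by the reference workflow); singles are zero by
Brillouin's theorem and are always kept — screening them would be an
accident of applying the amplitude filter literally.

**QCC.**  A product of single-qubit Bloch states (angles θ_i, φ_i) acted
on by exponentials exp(−iτ_k P_k/2) of Pauli-word entanglers.  The Bloch
angles are pre-optimized from the HF occupation pattern (so the mean field
is at least RHF quality); entanglers are then ranked by the first-order
gradient |Im⟨Ω|H P|Ω⟩| over odd-Y words supported on the Hamiltonian's
off-diagonal terms (a direct-interaction-set construction), keeping the
top *pool-size* words (default: the qubit count), ties broken
lexicographically.  The source workflow states only that "all
entanglements" were considered, without defining the pool or
factorization, so QCC energies are treated as qualitative: the package
asserts the variational bound and pool-nesting monotonicity, not the
published QCC table rows.

**Optimization.**  SLSQP with internal finite-difference gradients,
ftol 1e−9, at most 1000 iterations, fixed initial parameters, no
restarts: the default path contains no randomness and re-runs
bit-reproduce.

**Oracle.**  Every VQE energy is measured against exact diagonalization of
the qubit Hamiltonian restricted to the (N, S_z = 0) determinant sector
(supported to 20 qubits).  That oracle is itself cross-checked, fragment
by fragment, against a determinant-basis Slater–Condon FCI solver that
never touches the qubit route, and CCSD is validated through two-electron
exactness and size extensivity.

## Accuracy metrics

Absolute errors are reported in mHa (3 decimals); chemical accuracy is
1 kcal/mol = 1.594 mHa.  Relative accuracy is *defined* as
100·(1 − |ΔE|/|E_ref|) % — the published error/accuracy column pairs pin
this down only through consistency, which the tests verify on a
back-solved example.  Whether the method or reference energy belongs in
the denominator is indistinguishable at the printed precision.

## Synthetic data and stand-in geometries

The lattice generator places H₂ units (bond 0.7414 Å, along z) on a cubic
lattice and applies a seeded uniform jitter; a 3 Å pitch emulates the
van-der-Waals packing of optimized neutral clusters, 30 Å gives the
non-interacting limit, and an optional extra H atom produces anionic or
cationic fixtures.  It reproduces the *coordination pattern* of real
clusters, not their relaxed geometries: lattice clusters have slightly
different absolute energies than fully optimized ones, so tests built on
them certify structural identities (collapse, additivity, variational
bounds, oracle agreement) and error *magnitudes*, not externally published
totals.

The H₃⁺ (equilateral) and H₅⁺ (D2d shared-proton [H₂–H–H₂]⁺) ion
geometries are relaxed in-package at CCSD/6-31G over their symmetry
parameters — synthetic stand-ins for externally optimized structures.
H₃⁺ benchmarks are insensitive to this (UCCSD and CCSD are exact for two
electrons, so the error is identically zero at any geometry); the H₅⁺
CCSD/UCCSD errors vs FCI (0.145/0.146 mHa here) are geometry-sensitive at
the few-hundredths-of-a-mHa level, which is why the corresponding checks
carry a ±0.05 mHa band.

## Problem sizes

The default test-and-benchmark suite runs whole-system references up to H₆
(12 qubits, 400-determinant FCI sector) and fragments up to STO-3G dimers
(8 qubits); these sizes exercise every code path — multi-fragment SCC,
embedded dimers, all correlation backends and both conventions — while the
whole suite completes in well under a minute of CPU beyond the stand-in
geometry relaxations.  Benchmarks against the originally deposited H₂₀/H₂₄
cluster files run automatically when those XYZ files are placed under
`tests/data/deposited/`.

## Known limitations

* Hydrogen only, s-type bases only, closed-shell fragments only.
* No three-body (FMO3) terms, gradients, or pair-interaction
  decomposition.
* Statevector simulation only: no sampling noise, measurement grouping,
  or hardware noise models.
* The QCC entangler pool is one defensible construction among several;
  published QCC rows are not reproduced quantitatively.
* CCSD slightly overshoots FCI on some interacting clusters (it is not
  variational); the determinant FCI is the arbiter in all such checks.
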