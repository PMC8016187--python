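# Methods

## Model and conventions

cc3kit implements closed-shell CC3 for a canonical restricted Hartree–Fock
reference. Internally everything is spin-adapted over spatial orbitals:
occupied block first (0-based), chemists' `(pq|rs)` integrals, energies in
Hartree with eV only at reporting boundaries (1 Hartree = 27.211386 eV, pinned
in one place). Singles are folded into the Hamiltonian by the T1 similarity
transform: creation operators are dressed with `A = 1 - t1`, annihilation
operators with `B = 1 + t1^T`, so `h~ = A h B^T` and the dressed two-electron
integrals keep only the pair-swap symmetry `(pq|rs) = (rs|pq)`. The
perturbative partitioning assigns order zero to the diagonal occupied/virtual
Fock blocks and order one to the off-diagonal blocks and the fluctuation
potential; singles count as order zero (approximate orbital-rotation
parameters). The triples equation keeps `[F, T3] + [H~, T2]` projected on
triple excitations; with a canonical reference the commutator with the bare
Fock operator reduces to the orbital-energy denominators
`eps3 = eps_a + eps_b + eps_c - eps_i - eps_j - eps_k`. Non-canonical
references are rejected at load (off-diagonal Fock tolerance 1e-8) rather
than silently mishandled.

Residuals live in two related conventions. The *biorthonormal* form is the
working representation (`omega1 = F_ai`, `omega2 = g_aibj` at `t = 0`); the
*covariant* projections `<HF|E_ia H-bar|HF>` and `<HF|E_ia E_jb H-bar|HF>`
follow as `2 omega1` and `4 omega2 - 2 omega2^(ajbi)`, and the inverse map
`(2 Omega + Omega^swap)/6` is the doubles back-transformation used when the
loops accumulate contravariant quantities. Amplitude-space inner products are
always the full unrestricted sums, which makes the transpose of every einsum
its exact adjoint.

### Provenance of the working equations

The spin-adapted contraction lists (dressed CCSD residual, triples
construction, triples couplings, density blocks; `_equations.py`) were
*derived*, not transcribed: every candidate contraction compatible with an
operand family was enumerated and its coefficient determined by sparse
regression (basis pursuit) against an exact determinant-space evaluation of
the same model, then verified on held-out random systems. All fits close at
1e-13 or better, and the recovered forms are the standard closed-shell CC3
equations (e.g. the triples numerator
`W = P^ [ t_ij^ad (bd|ck) - t_il^ab (ck|lj) ]`).

## Blocked algorithms

*Ground state.* A restricted loop over occupied triples `i >= j >= k`
(skipping `i = j = k`, which has no spin-adapted amplitude and provably no
residual image) builds each `(nv, nv, nv)` numerator block from two seeds —
one `nv^4` matrix multiplication against a pre-reordered `(d, b, c)` layout of
the vvvo integrals, one cheap hole contraction against the vooo block —
summed over the six pair permutations with duplicate orderings computed once.
The contravariant combination `(4, -2, -2, +1, +1, -2)` over the virtual
permutations collapses the singles coupling to one small contraction per
ordering; for the dominant doubles coupling a second combination
`(-1, +2, 0, 0, -1, 0)` collapses the three vvvo-type terms into a single
`nv^4` multiplication per ordering. The resulting cost is `4 nV^4 nO^3` FLOP
per residual (half construction, half contraction), which the instrumented
contraction layer reproduces with a measured log–log slope of 4.000 in the
virtual dimension for the triples part.

*Jacobian transformations.* `J(omega) v` is the exact linearization of the
residual, with the response-triples denominators shifted by `omega`. A
preparation sweep contracts the ground-state triples with the ovov integrals
into three `(nv, no^3)` channel intermediates (none larger than doubles),
shared by the right and transpose transformations. Each application then runs
two loops: loop 1 rebuilds the ground-state triples blocks and contracts them
with r1-dressed integral slices (only annihilation axes at occupied values
and creation axes at virtual values respond to the dressing, so each slice is
one cheap contraction); loop 2 builds the response triples by calling the
same constructor twice — once with the trial doubles and ground integrals,
once with the ground doubles and dressed-derivative seeds — and couples them
like the ground-state residual. The CCSD-part linearization expands the
integral derivative axis-by-axis so the trial singles are contracted last and
no dressed-derivative integral tensors are materialized; trial-independent
inner contractions are cached across applications. Measured cost ratio
(right transform)/(ground residual) at `nV = 24, nO = 4`: 1.91.

The transpose transformation is the exact adjoint of every right-side
contraction: the left triples block is assembled covariantly from coupling
adjoints (doubles contractions plus six outer products with the singles),
mapped by the contravariant combination where the right path used it, divided
by the shifted denominators and pushed through the adjoint of the block
constructor. One accumulated gradient is of `nv^3 no` size; its final
contraction against the four-virtual integrals can optionally run through
Cholesky factors of the ERI pair matrix (pivoted incomplete factorization,
default threshold 1e-8, below every convergence threshold used). The generic
term-list adjoint of the CCSD part is not hand-factorized, so a transpose
application counts roughly twice the right transform — a known inefficiency
that does not affect any result.

*Eigensolver.* Because the folded triples carry the excitation energy, each
root solves `J(omega_m) x = omega_m x`. Roots are obtained sequentially: a
non-Hermitian Davidson solve (packed symmetric doubles coordinates, orbital
-energy-difference preconditioning, subspace collapse) at fixed `omega`
alternates with an energy update, homing by proximity to the previous
estimate, until the fixed point is reached; a small buffer of extra roots
guards against degeneracies and roots are tie-broken by energy then singles
weight. Left states are solved at the frozen right-state energies so the
pairs match. Start guesses are unit singles on the lowest orbital-energy
differences (unit doubles supplement them if more roots than singles are
requested); a CCSD-restart guess mode first converges the singles/doubles
Jacobian. Biorthonormality `<L_m, R_n> = delta` holds only when the folded
triples sectors are included in the pairing; `excitation_overlap` evaluates
that contribution blockwise (including the virtual-diagonal blocks, with the
pair-symmetrized left-triples slices obtained from the six-permutation
average). The right-vector reference weight follows from biorthogonality
against the left ground state, `r_m = -<Lambda-vector, R_m>` with the same
triples-sector pairing.

*Densities.* Density matrices are assembled in the dressed frame from the
frozen block formulas and back-transformed with the dressing matrices.
Triples enter through folded tensors built on the fly: contributions whose
occupied indices coincide between left and right triples run in the occupied
triples loop; the occupied-occupied block pairs triples with one mismatched
occupied index and therefore runs an additional triple loop over *virtual*
indices holding `(no, no, no)` blocks; one doubly-mismatched pair of terms is
factorized through a doubles-sized intermediate in two sweeps. Under CVS only
the occupied triples loop is cycled. Closed-shell normalization puts
occupation 2 on the reference diagonal, so `Tr D = n_electrons` exactly.

### EOM versus response ground-state density

The biorthogonal expectation-value form
`<HF|(1 + Lambda) e^{-T} E_pq e^{T}|HF>` is **not** the exact derivative of
the CC3 energy: it contains one extra `<Lambda3|[[A, T2], T2]>` ov-block term,
and its `Lambda3 * tau3` occupied/virtual blocks originate in the bare-Fock
commutator and must enter *undressed* to match `dE/d(alpha)`. The package
ships both: `variant="eom"` (the form used for spectra and reused inside the
left transition density) and `variant="response"`, the exact derivative of
the model in which `[F, T3]` carries the full bare Fock matrix. Finite-field
differentiation against a determinant-space solver that treats the perturbed
(non-diagonal) Fock triples coupling exactly reproduces the response variant
with clean O(alpha^2) Richardson ratios of 4.000. Both variants trace to the
electron count. Transition moments are EOM throughout (length gauge);
response-theory transition moments differ and are out of scope.

## Oracles and what the tests show

The determinant engine realizes states over alpha/beta occupation-string
pairs (S_z = 0) and every operator as string-space matrices, giving exact
energies, linked residuals, folded triples, Jacobian actions and densities
with no tensor algebra to 1e-12 or better — this is the authority behind
every frozen equation. The dense reference is an independently coded
unblocked implementation (full triples tensor, no loop restrictions, no
intermediates, no contravariant trick) used as the equivalence oracle for the
blocked path on synthetic systems up to 4 occupied / 6 virtual orbitals; its
explicit Jacobian matrix is assembled column-by-column from unit vectors.

The synthetic generator draws the ERI tensor as a sum of `3 n_orb` seeded
Gaussian symmetric Cholesky factors scaled by `interaction_scale /
sqrt(n_factors)` (positive semidefinite, full 8-fold symmetry,
basis-size-stable norm), places a diagonal Fock matrix with at least a 0.2
Hartree occupied–virtual gap and back-solves the one-electron part. A
moderate interaction scale (0.3–0.4 in the tests) keeps the perturbative
structure that CC3 assumes. These models exercise every contraction and
symmetry of the method, but they have no spatial structure, no point-group
symmetry, near-uniform denominators and modest correlation — passing tests
demonstrate algebraic correctness and cost structure, not accuracy for real
molecules.

The packaged molecular fixtures (H2 minimal and split-valence, He, H4/H6
hydrogen chains; s-type Gaussian bases) were generated offline from
closed-form s-function integrals with an independent RHF solver; the
H2/STO-3G Hartree–Fock energy reproduces the textbook value (-1.1167
Hartree) to the printed precision, and geometry/basis provenance sits in the
JSON sidecars next to each FCIDUMP. Oxygen-containing fixtures would need
p-function integrals, which are outside the package's scope (no AO integral
evaluation); the hydrogen chains play the multi-electron role instead.

## Numerical choices

- Ground-state convergence 1e-6 (infinity norm of the residual), excited
  states 1e-4, both configurable; the tests and the acceptance script use
  tighter values where oracle comparisons demand it.
- DIIS depth 8 with preconditioned residuals as error vectors, for both the
  amplitude and the multiplier equations.
- Near-degenerate triples denominators (|eps3| < 1e-10) raise by default
  (configurable to a warning); no denominator shifting.
- Davidson: residual threshold as configured, subspace cap 60 with collapse
  onto Ritz vectors, 1e-6 floor on the preconditioner, energy-folding fixed
  point to one tenth of the residual threshold.
- FLOP accounting charges `2 * prod(dims)` per contraction above a
  configurable cutoff; the scaling-exponent check isolates the triples loop
  as the count difference between the CC3 and CCSD residuals at a `2 nv^4`
  per-call cutoff (the dominant block-scale multiplications).
- Spectra: area-normalized Lorentzians (peak height `2 f / (pi Gamma)`),
  default width 0.5 eV, optional rigid shift.
- FCI spin labels use alpha/beta exchange parity — exact for up to two
  unpaired electrons, which covers every fixture used.

## Known limitations

- Spatial point-group symmetry is not exploited; triplet excited states,
  open-shell references and excited-to-excited transition densities are out
  of scope.
- In-core only: integrals, doubles-sized intermediates and one `nv^3 no`
  gradient are held in memory (the file-batching hooks of a production code
  are stubbed behind the same interfaces).
- The transpose transformation and the density assembly are written for
  clarity over constant factors; their counted cost exceeds the minimal
  published factors although the scaling is correct.
- EOM oscillator strengths assume the length gauge; gauge dependence is not
  assessed.
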