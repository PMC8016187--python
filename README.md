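# cc3kit

Closed-shell **CC3** — coupled cluster with singles, doubles and iteratively
perturbative triples — as a reusable engine: ground-state energies, EOM-CC3
excitation energies for valence and core (CVS) states, Lagrange multipliers,
EOM transition densities, oscillator strengths and Lorentzian-broadened
spectra. It is aimed at method developers and spectroscopists who need a
compact, heavily cross-checked CC3 reference implementation on top of
molecular-orbital integrals (FCIDUMP files or packaged fixtures).

## The model

With the cluster operator `T = T1 + T2 + T3` and the T1-similarity-transformed
Hamiltonian `H~ = exp(-T1) H exp(T1)`, CC3 keeps the full CCSD equations and
determines the triples perturbatively in each iteration,

    eps3_ijk^abc * t_ijk^abc = - <mu3| [H~, T2] |HF> ,

where `eps3` is the orbital-energy difference of the triple excitation. The
working equations are spin-adapted (spatial orbitals, chemists' `(pq|rs)`
integrals). Triples amplitudes are never stored: a restricted loop over
occupied triples `i >= j >= k` builds one `(nv, nv, nv)` block at a time from
two matrix-multiplication seeds, applies the six simultaneous permutations of
the index pairs, and contracts the block — via its contravariant combination
`4 W^abc - 2 W^bac - 2 W^acb + W^cab + W^bca - 2 W^cba` — directly into the
residual. One residual costs `4 nV^4 nO^3` FLOP (multiply + add counted
separately), one Jacobian or transpose-Jacobian application `8 nV^4 nO^3`,
with tau3-dependent intermediates prepared once before the iterations.
Excitation energies solve the folded non-Hermitian eigenproblem
`J(omega) R = omega R` (the response-triples denominators carry `omega`); CVS
core states are obtained by projecting the trial vectors onto amplitudes with
a core occupied index and cycling the triples loops accordingly. EOM
transition densities `D^{m0}` and `D~^{0m}` are assembled blockwise, with an
additional triple loop over *virtual* indices for the occupied-occupied
block, and oscillator strengths follow the length-gauge biorthogonal product
`f = (2/3) omega sum_q Tr(D~^{0m} A_q) Tr(D^{m0} A_q)`.

Everything is backed by two independent oracles: an exact determinant-space
engine (full-CI-sector arithmetic, also providing the FCI reference) and an
unblocked dense implementation holding the full triples tensor.

## Worked example

The packaged split-valence H2 fixture, from the shell:

```
$ cc3 spectrum --fixture h2_631g --roots 2 --output-dir out
system: 1 occupied / 3 virtual orbitals, 2 electrons
CC3 total energy: -1.1516790906 Hartree (8 iterations)

root   omega [Hartree]   omega [eV]   %singles   iterations
   1        0.56233244      15.3018      96.4        1
   2        1.04742790      28.5020      92.9        1

state   omega [eV]        f
 1 valence      15.3018    0.632021
 2 valence      28.5020    0.000000
```

The total energy is the CC3 ground state (for two electrons it equals the
full-CI energy of the basis, here to 13 decimal places); the table lists the
EOM-CC3 excitation energies, their singles character and the length-gauge
oscillator strengths. The second root is a dipole-forbidden state, hence
`f = 0`. The run directory receives `results.txt`, `spectrum.dat` (0.5 eV
Lorentzian broadening by default), a machine-readable `run.json` and an HDF5
amplitude checkpoint. The same pipeline is available from Python via
`cc3kit.run_pipeline(RunConfig(...))`, and `cc3 selftest` runs a quick
blocked-versus-dense oracle grid.

Core-excited states use the CVS projection, e.g.
`cc3 excite --fixture h6_sto3g --roots 2 --cvs-core 0`.

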