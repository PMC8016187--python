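{"name": "he_631g", "geometry_bohr": [[0.0, 0.0, 0.0]], "charges": [2], "note": "He atom, split-valence [2s] basis", "scf_energy": -2.8545981931140636, "orbital_energies": [-0.9124704612181693, 1.3722346407571828], "dipole_mo": [[[0.0, 0.0], [0.0, 0.0]], [[0.0, 0.0], [0.0, 0.0]], [[0.0, 0.0], [0.0, 0.0]]], "generator": "scratch/gen_fixtures.py (s-Gaussian closed-form integrals + RHF)"}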