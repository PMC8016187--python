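{"name": "h2_sto3g", "geometry_bohr": [[0.0, 0.0, 0.0], [0.0, 0.0, 1.4]], "charges": [1, 1], "note": "H2, R = 1.4 bohr, STO-3G", "scf_energy": -1.1167143250625697, "orbital_energies": [-0.578202977512458, 0.6702677682736695], "dipole_mo": [[[0.0, 0.0], [0.0, 0.0]], [[0.0, 0.0], [0.0, 0.0]], [[0.6999999999999997, -0.9310194161649117], [-0.9310194161649116, 0.6999999999999995]]], "generator": "scratch/gen_fixtures.py (s-Gaussian closed-form integrals + RHF)"}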