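{"name": "h2_631g", "geometry_bohr": [[0.0, 0.0, 0.0], [0.0, 0.0, 1.4]], "charges": [1, 1], "note": "H2, R = 1.4 bohr, split-valence [2s] hydrogen basis", "scf_energy": -1.1267427044508866, "orbital_energies": [-0.5955599505206662, 0.23824594363335477, 0.7751323121865623, 1.4032929452863074], "dipole_mo": [[[0.0, 0.0, 0.0, 0.0], [0.0, 0.0, 0.0, 0.0], [0.0, 0.0, 0.0, 0.0], [0.0, 0.0, 0.0, 0.0]], [[0.0, 0.0, 0.0, 0.0], [0.0, 0.0, 0.0, 0.0], [0.0, 0.0, 0.0, 0.0], [0.0, 0.0, 0.0, 0.0]], [[0.6999999999999976, -1.0190635304377078, 3.638387085490101e-15, 0.20921406763982908], [-1.0190635304377078, 0.7000000000000023, 1.0079666273914596, -1.7671541211739135e-16], [3.729378607369659e-15, 1.0079666273914594, 0.699999999999999, 0.9559640787181585], [0.20921406763982914, -8.591700935124043e-16, 0.9559640787181584, 0.6999999999999978]]], "generator": "scratch/gen_fixtures.py (s-Gaussian closed-form integrals + RHF)"}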