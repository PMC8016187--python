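{"name": "h4_sto3g", "geometry_bohr": [[0.0, 0.0, 0.0], [0.0, 0.0, 1.8], [0.0, 0.0, 3.6], [0.0, 0.0, 5.4]], "charges": [1, 1, 1, 1], "note": "H4 chain, R = 1.8 bohr spacing, STO-3G", "scf_energy": -2.1134289151257457, "orbital_energies": [-0.6485943091200076, -0.3910276269884389, 0.32293807388010803, 0.9492042544544429], "dipole_mo": [[[0.0, 0.0, 0.0, 0.0], [0.0, 0.0, 0.0, 0.0], [0.0, 0.0, 0.0, 0.0], [0.0, 0.0, 0.0, 0.0]], [[0.0, 0.0, 0.0, 0.0], [0.0, 0.0, 0.0, 0.0], [0.0, 0.0, 0.0, 0.0], [0.0, 0.0, 0.0, 0.0]], [[2.7000000000000006, -1.7221389589556861, -1.641200063224797e-16, 0.21265921842427346], [-1.7221389589556861, 2.700000000000004, 1.7459921566978625, 8.758639401777835e-16], [-4.890852064069943e-16, 1.7459921566978625, 2.699999999999991, -1.7338475572430287], [0.21265921842427368, 3.7763944712532766e-16, -1.733847557243029, 2.7000000000000006]]], "generator": "scratch/gen_fixtures.py (s-Gaussian closed-form integrals + RHF)"}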