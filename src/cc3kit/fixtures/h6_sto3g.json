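{"name": "h6_sto3g", "geometry_bohr": [[0.0, 0.0, 0.0], [0.0, 0.0, 1.8], [0.0, 0.0, 3.6], [0.0, 0.0, 5.4], [0.0, 0.0, 7.2], [0.0, 0.0, 9.0]], "charges": [1, 1, 1, 1, 1, 1], "note": "H6 chain, R = 1.8 bohr spacing, STO-3G", "scf_energy": -3.152316250253003, "orbital_energies": [-0.6941463196617176, -0.5546983994547012, -0.3303178110506308, 0.24734310424475062, 0.6745150925503076, 1.147718619067332], "dipole_mo": [[[0.0, 0.0, 0.0, 0.0, 0.0, 0.0], [0.0, 0.0, 0.0, 0.0, 0.0, 0.0], [0.0, 0.0, 0.0, 0.0, 0.0, 0.0], [0.0, 0.0, 0.0, 0.0, 0.0, 0.0], [0.0, 0.0, 0.0, 0.0, 0.0, 0.0], [0.0, 0.0, 0.0, 0.0, 0.0, 0.0]], [[0.0, 0.0, 0.0, 0.0, 0.0, 0.0], [0.0, 0.0, 0.0, 0.0, 0.0, 0.0], [0.0, 0.0, 0.0, 0.0, 0.0, 0.0], [0.0, 0.0, 0.0, 0.0, 0.0, 0.0], [0.0, 0.0, 0.0, 0.0, 0.0, 0.0], [0.0, 0.0, 0.0, 0.0, 0.0, 0.0]], [[4.499999999999995, 2.291890484215484, -5.765864364555725e-15, 0.11516405190785252, 5.261822196179651e-16, -0.09920060972338801], [2.291890484215484, 4.500000000000022, 2.6247020307797824, -1.6247422380722967e-15, -0.4028563825277595, -2.8648699423368706e-15], [-5.4183873087831234e-15, 2.6247020307797824, 4.499999999999994, 2.356685819569217, -9.636375014562687e-16, -0.14018341302601806], [0.1151640519078524, -1.646103826990932e-15, 2.3566858195692175, 4.499999999999997, -2.61717181199315, 1.5436270554977257e-14], [4.5711516707088915e-17, -0.4028563825277589, -3.693057320345177e-16, -2.6171718119931504, 4.500000000000024, 2.2849805300163086], [-0.0992006097233881, -2.8828846986286327e-15, -0.1401834130260177, 1.527159767111215e-14, 2.284980530016309, 4.4999999999999725]]], "generator": "scratch/gen_fixtures.py (s-Gaussian closed-form integrals + RHF)"}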