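&FCI NORB=2,NELEC=2,MS2=0,
  ORBSYM=1,1,
  ISYM=1,
&END
 1.0296572706316871E+00    1    1    1    1
 3.1360034814569876E-01    2    1    1    1
 2.2204699710371439E-01    2    1    2    1
 8.4980619585012296E-01    2    2    1    1
 2.4577331719300363E-01    2    2    2    1
 7.5095101934316910E-01    2    2    2    2
-1.9421277318733290E+00    1    1    0    0
-3.1360034813885035E-01    2    1    0    0
-1.0533075385731758E-01    2    2    0    0
 0.0000000000000000E+00    0    0    0    0
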