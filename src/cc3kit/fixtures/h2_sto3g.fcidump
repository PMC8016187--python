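&FCI NORB=2,NELEC=2,MS2=0,
  ORBSYM=1,1,
  ISYM=1,
&END
 6.7459408432336787E-01    1    1    1    1
 1.8125791479311310E-01    2    1    2    1
 6.6356399122054299E-01    2    2    1    1
 6.9749534668016744E-01    2    2    2    2
-1.2527970618358260E+00    1    1    0    0
-4.7560229937430382E-01    2    2    0    0
 7.1428571428571430E-01    0    0    0    0
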