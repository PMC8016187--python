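&FCI NORB=4,NELEC=2,MS2=0,
  ORBSYM=1,1,1,1,
  ISYM=1,
&END
 6.4990851736421407E-01    1    1    1    1
 8.0086317405415164E-02    2    1    2    1
 4.3374492151992505E-01    2    2    1    1
 3.8582714658390493E-01    2    2    2    2
 1.6714531422161347E-01    3    1    1    1
 5.0044867160038344E-02    3    1    2    2
 1.0932933749572293E-01    3    1    3    1
-1.9304697792182541E-02    3    2    2    1
 3.5933386907216786E-02    3    2    3    2
 5.3188530752012408E-01    3    3    1    1
 3.8134477812365608E-01    3    3    2    2
 1.1984830918450101E-01    3    3    3    1
 4.6365561461013816E-01    3    3    3    3
-7.9364515608044889E-02    4    1    2    1
-2.1773398460947158E-02    4    1    3    2
 1.3761164872824941E-01    4    1    4    1
-1.4334742054242122E-01    4    2    1    1
-5.4787577733307127E-02    4    2    2    2
-7.3289192013903645E-02    4    2    3    1
-9.8367424341696125E-02    4    2    3    3
 6.7539176652200897E-02    4    2    4    2
-8.3242978532000481E-02    4    3    2    1
-2.6520897341536682E-03    4    3    3    2
 1.2309319859812366E-01    4    3    4    1
 1.2749325359626779E-01    4    3    4    3
 6.6304438218382233E-01    4    4    1    1
 4.4245432183389233E-01    4    4    2    2
 2.0155687312164186E-01    4    4    3    1
 5.5225950928907186E-01    4    4    3    3
-1.6774346421811903E-01    4    4    4    2
 7.4042322954439266E-01    4    4    4    4
-1.2454684680508963E+00    1    1    0    0
-5.4915758211946986E-01    2    2    0    0
-1.6714531412045280E-01    3    1    0    0
-1.7930896547649547E-01    3    3    0    0
 2.0733032557010084E-01    4    2    0    0
 2.1481582936929791E-01    4    4    0    0
 7.1428571428571430E-01    0    0    0    0
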