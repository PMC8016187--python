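&FCI NORB=4,NELEC=4,MS2=0,
  ORBSYM=1,1,1,1,
  ISYM=1,
&END
 5.0886435243239969E-01    1    1    1    1
 1.5719675876534181E-01    2    1    2    1
 4.4587327570764268E-01    2    2    1    1
 4.6362851214763695E-01    2    2    2    2
 8.3453174897655427E-02    3    1    1    1
-8.7349942465109135E-03    3    1    2    2
 1.0755527289117760E-01    3    1    3    1
-9.9463133996613592E-02    3    2    2    1
 1.3730292376897726E-01    3    2    3    2
 4.5706388075866183E-01    3    3    1    1
 4.5733512207571697E-01    3    3    2    2
 9.7327411073337509E-03    3    3    3    1
 4.7818552734042302E-01    3    3    3    3
 4.3959675057772950E-02    4    1    2    1
 5.0249380328347769E-02    4    1    3    2
 9.6149003040942177E-02    4    1    4    1
 8.6258766776874246E-02    4    2    1    1
 6.1893895651682065E-03    4    2    2    2
 9.7301086971796541E-02    4    2    3    1
 5.4372007145965110E-03    4    2    3    3
 1.0372562634465465E-01    4    2    4    2
 1.4953440041516033E-01    4    3    2    1
-1.0032236563495740E-01    4    3    3    2
 4.1698071097412984E-02    4    3    4    1
 1.6154114553879562E-01    4    3    4    3
 5.3620955840117956E-01    4    4    1    1
 4.7563091391433554E-01    4    4    2    2
 8.8251201092234319E-02    4    4    3    1
 4.9337772888091924E-01    4    4    3    3
 9.6372936167524167E-02    4    4    4    2
 5.9855264112912265E-01    4    4    4    4
-1.8920084541210944E+00    1    1    0    0
-1.5892059320858059E+00    2    2    0    0
-1.6544631984021535E-01    3    1    0    0
-1.2610017348147777E+00    3    3    0    0
-1.3474724868982810E-01    4    2    0    0
-8.7460206101110094E-01    4    4    0    0
 2.4074074074074074E+00    0    0    0    0
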