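&FCI NORB=6,NELEC=6,MS2=0,
  ORBSYM=1,1,1,1,1,1,
  ISYM=1,
&END
 4.4131270382393184E-01    1    1    1    1
 1.3421387631431100E-01    2    1    2    1
 3.5705421820449851E-01    2    2    1    1
 3.8695230367782518E-01    2    2    2    2
-8.1319812511974787E-02    3    1    1    1
 2.6496211519367166E-02    3    1    2    2
 1.0228767793644912E-01    3    1    3    1
 1.0190043289677722E-01    3    2    2    1
 1.2776231032253532E-01    3    2    3    2
 3.7350221116563070E-01    3    3    1    1
 3.5636335862055096E-01    3    3    2    2
-2.0892460047120150E-02    3    3    3    1
 3.7990808922876801E-01    3    3    3    3
-5.2078508832921103E-02    4    1    2    1
 1.4588214960217153E-02    4    1    3    2
 7.8947562850224917E-02    4    1    4    1
-8.2164445220091128E-02    4    2    1    1
-1.4630421457629264E-02    4    2    2    2
 6.1129246938636021E-02    4    2    3    1
-3.0514871500399187E-03    4    2    3    3
 8.7304958638744407E-02    4    2    4    2
 8.5218679869703648E-02    4    3    2    1
 8.6930221518630404E-02    4    3    3    2
-9.4448609537782034E-03    4    3    4    1
 1.0912503643741563E-01    4    3    4    3
 3.8077418983706540E-01    4    4    1    1
 3.6152638189772390E-01    4    4    2    2
-2.1861845504183589E-02    4    4    3    1
 3.7395935374940065E-01    4    4    3    3
-1.6416196836350518E-02    4    4    4    2
 3.8924797186546434E-01    4    4    4    4
 3.9812129111057712E-03    5    1    1    1
 3.6905274348804168E-02    5    1    2    2
 3.4081482424914815E-02    5    1    3    1
-1.5867638616156633E-02    5    1    3    3
-2.6736200662271253E-02    5    1    4    2
-5.1581974584297505E-03    5    1    4    4
 5.5659490294882714E-02    5    1    5    1
 4.5103735705265456E-02    5    2    2    1
 2.7582457301147537E-03    5    2    3    2
-5.2092602129313895E-02    5    2    4    1
-3.1750680266187901E-02    5    2    4    3
 8.4554944423884004E-02    5    2    5    2
 8.5509533814363756E-02    5    3    1    1
 1.6352416291494223E-02    5    3    2    2
-6.3966045226086940E-02    5    3    3    1
 1.5190602128131434E-02    5    3    3    3
-8.0075798779961377E-02    5    3    4    2
 1.2255964965817946E-02    5    3    4    4
 1.8066621853629752E-02    5    3    5    1
 8.6722636829255295E-02    5    3    5    3
-1.0585911164285855E-01    5    4    2    1
-1.2066093872487983E-01    5    4    3    2
-2.7963269588349776E-03    5    4    4    1
-8.7865670126933262E-02    5    4    4    3
-7.5105755833873101E-03    5    4    5    2
 1.2997547324903391E-01    5    4    5    4
 3.7826448288720443E-01    5    5    1    1
 3.9543393060199078E-01    5    5    2    2
 1.3567052318847616E-02    5    5    3    1
 3.7290769480623598E-01    5    5    3    3
-2.2104667146654804E-02    5    5    4    2
 3.8206285271233487E-01    5    5    4    4
 3.4410535597521198E-02    5    5    5    1
 2.3968280444490418E-02    5    5    5    3
 4.2441364809734922E-01    5    5    5    5
-1.9408713193141362E-03    6    1    2    1
 2.4766664728159520E-02    6    1    3    2
 2.9595012061175020E-02    6    1    4    1
-3.8349716349583909E-02    6    1    4    3
 3.2814382735936398E-02    6    1    5    2
-2.1842657871020341E-02    6    1    5    4
 6.8357323575503837E-02    6    1    6    1
 5.6985894463686196E-03    6    2    1    1
 3.7288384338659684E-02    6    2    2    2
 3.1981633667101765E-02    6    2    3    1
-7.6824494052171758E-03    6    2    3    3
-2.1211192831135151E-02    6    2    4    2
-9.5881246922512164E-03    6    2    4    4
 4.9616672461939730E-02    6    2    5    1
 2.3084057309463966E-02    6    2    5    3
 3.6766569016087984E-02    6    2    5    5
 5.2087559040418563E-02    6    2    6    2
 5.1706142318760424E-02    6    3    2    1
-7.1121830012144662E-03    6    3    3    2
-7.2193681159388803E-02    6    3    4    1
 1.0891289937003255E-02    6    3    4    3
 5.1277993208979772E-02    6    3    5    2
 6.9397608031848195E-03    6    3    5    4
-2.7898076410652770E-02    6    3    6    1
 7.6940141360565401E-02    6    3    6    3
 8.4407432665584786E-02    6    4    1    1
-1.8558724110282459E-02    6    4    2    2
-9.8136993416567397E-02    6    4    3    1
 2.3875397294118396E-02    6    4    3    3
-6.3022565358451368E-02    6    4    4    2
 2.5997928583775583E-02    6    4    4    4
-3.1256156344759208E-02    6    4    5    1
 6.5659973387696149E-02    6    4    5    3
-1.6450930691104197E-02    6    4    5    5
-3.1859563999379559E-02    6    4    6    2
 1.0759406262770548E-01    6    4    6    4
 1.3737655434638874E-01    6    5    2    1
 1.0744682016390403E-01    6    5    3    2
-5.2524490982613400E-02    6    5    4    1
 9.0903400266409556E-02    6    5    4    3
 4.6963007714751190E-02    6    5    5    2
-1.1423567465773098E-01    6    5    5    4
-2.2920129440357679E-03    6    5    6    1
 5.7153943536071776E-02    6    5    6    3
 1.5644429397383131E-01    6    5    6    5
 4.7266761788658035E-01    6    6    1    1
 3.8414254160506733E-01    6    6    2    2
-8.7800965259831984E-02    6    6    3    1
 4.0427000291214182E-01    6    6    3    3
-9.0406461544194072E-02    6    6    4    2
 4.1583307181855694E-01    6    6    4    4
 4.6441189534100055E-03    6    6    5    1
 9.6790529366349798E-02    6    6    5    3
 4.1783633054964936E-01    6    6    5    5
 7.1211062817820251E-03    6    6    6    2
 9.8003034750633156E-02    6    6    6    4
 5.3681080384195856E-01    6    6    6    6
-2.3600703277465667E+00    1    1    0    0
-2.1065096698283492E+00    2    2    0    0
 1.5112028244670950E-01    3    1    0    0
-1.9399070539918317E+00    3    3    0    0
 2.1991399534931508E-01    4    2    0    0
-1.7097991863201152E+00    4    4    0    0
-6.4918791707642837E-02    5    1    0    0
-1.8207477801736219E-01    5    3    0    0
-1.3917600530067784E+00    5    5    0    0
-4.2373721083805230E-02    6    2    0    0
-1.6017310278668320E-01    6    4    0    0
-1.1770566826009610E+00    6    6    0    0
 4.8333333333333330E+00    0    0    0    0
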