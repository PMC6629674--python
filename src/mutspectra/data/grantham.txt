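H GRAR740104
D Chemical distance (Grantham, 1974)
A Grantham, R.
T Amino acid difference formula to help explain protein evolution
J Science 185, 862-864 (1974)
M rows = ARNDCQEGHILKMFPSTWYV, cols = ARNDCQEGHILKMFPSTWYV
   0
 112    0
 111   86    0
 126   96   23    0
 195  180  139  154    0
  91   43   46   61  154    0
 107   54   42   45  170   29    0
  60  125   80   94  159   87   98    0
  86   29   68   81  174   24   40   98    0
  94   97  149  168  198  109  134  135   94    0
  96  102  153  172  198  113  138  138   99    5    0
 106   26   94  101  202   53   56  127   32  102  107    0
  84   91  142  160  196  101  126  127   87   10   15   95    0
 113   97  158  177  205  116  140  153  100   21   22  102   28    0
  27  103   91  108  169   76   93   42   77   95   98  103   87  114    0
  99  110   46   65  112   68   80   56   89  142  145  121  135  155   74    0
  58   71   65   85  149   42   65   59   47   89   92   78   81  103   38   58    0
 148  101  174  181  215  130  152  184  115   61   61  110   67   40  147  177  128    0
 112   77  143  160  194   99  122  147   83   33   36   85   36   22  110  144   92   37    0
  64   96  133  152  192   96  121  109   84   29   32   97   21   50   68  124   69   88   55    0
//
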