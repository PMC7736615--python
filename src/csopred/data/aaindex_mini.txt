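H KYTJ820101
D Hydropathy index (Kyte-Doolittle, 1982)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
    1.800  -4.500  -3.500  -3.500   2.500  -3.500  -3.500  -0.400  -3.200   4.500
    3.800  -3.900   1.900   2.800  -1.600  -0.800  -0.700  -0.900  -1.300   4.200
//
H HOPT810101
D Hydrophilicity value (Hopp-Woods, 1981)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
   -0.500   3.000   0.200   3.000  -1.000   0.200   3.000   0.000  -0.500  -1.800
   -1.800   3.000  -1.300  -2.500   0.000   0.300  -0.400  -3.400  -2.300  -1.500
//
H FASG760101
D Molecular weight of the residue
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
   89.090 174.200 132.120 133.100 121.150 146.150 147.130  75.070 155.160 131.170
  131.170 146.190 149.210 165.190 115.130 105.090 119.120 204.240 181.190 117.150
//
H ZIMJ680104
D Isoelectric point
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
    6.000  10.760   5.410   2.770   5.050   5.650   3.220   5.970   7.590   6.020
    5.980   9.740   5.740   5.480   6.300   5.680   5.660   5.890   5.660   5.960
//
H GRAR740102
D Polarity (Grantham, 1974)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
    8.100  10.500  11.600  13.000   5.500  10.500  12.300   9.000  10.400   5.200
    4.900  11.300   5.700   5.200   8.000   9.200   8.600   5.400   6.200   5.900
//
H ZAMY800101
D Residue volume
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
   88.600 173.400 114.100 111.100 108.500 143.800 138.400  60.100 153.200 166.700
  166.700 168.600 162.900 189.900 112.700  89.000 116.100 227.800 193.600 140.000
//
H KLEP840101
D Net charge at neutral pH
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
    0.000   1.000   0.000  -1.000   0.000   0.000  -1.000   0.000   0.000   0.000
    0.000   1.000   0.000   0.000   0.000   0.000   0.000   0.000   0.000   0.000
//
H SYNNA0001
D Synthetic incomplete scale (exercises NA handling; not a published index)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
    0.100      NA   0.300   0.400   0.500   0.600   0.700   0.800      NA   1.000
    1.100   1.200   1.300   1.400   1.500   1.600   1.700   1.800   1.900   2.000
//
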