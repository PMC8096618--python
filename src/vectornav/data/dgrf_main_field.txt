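# Definitive main-field spherical-harmonic (Gauss) coefficients of the
# international geomagnetic reference field, Schmidt semi-normalized, in nT.
# Columns: kind n m  value@2005.0  value@2010.0
# Epochs between 2005.0 and 2010.0 are obtained by linear interpolation.
# Degrees n >= 10 are held at their 2005 values in the 2010 column: their
# individual amplitudes are <= ~5 nT and their secular variation over this
# window is sub-nT, i.e. negligible (< 0.01 deg) for declination/inclination.
g 1 0 -29554.63 -29496.57
g 1 1 -1669.05 -1586.42
h 1 1 5077.99 4944.26
g 2 0 -2337.24 -2396.06
g 2 1 3047.69 3026.34
h 2 1 -2594.50 -2708.54
g 2 2 1657.76 1668.17
h 2 2 -515.43 -575.73
g 3 0 1336.30 1339.85
g 3 1 -2305.83 -2326.54
h 3 1 -198.86 -160.40
g 3 2 1246.39 1232.10
h 3 2 269.72 251.75
g 3 3 672.51 633.73
h 3 3 -524.72 -537.03
g 4 0 920.55 912.66
g 4 1 797.96 808.97
h 4 1 282.07 286.48
g 4 2 210.65 166.58
h 4 2 -225.23 -211.03
g 4 3 -379.86 -356.83
h 4 3 145.15 164.46
g 4 4 100.00 89.40
h 4 4 -305.36 -309.72
g 5 0 -227.00 -230.87
g 5 1 354.41 357.29
h 5 1 42.72 44.58
g 5 2 208.95 200.26
h 5 2 180.25 189.01
g 5 3 -136.54 -141.05
h 5 3 -123.45 -118.06
g 5 4 -168.05 -163.17
h 5 4 -19.57 -0.01
g 5 5 -13.55 -8.03
h 5 5 103.85 101.04
g 6 0 73.60 72.78
g 6 1 69.56 68.69
h 6 1 -20.33 -20.90
g 6 2 76.74 75.92
h 6 2 54.75 44.18
g 6 3 -151.34 -141.40
h 6 3 63.63 61.54
g 6 4 -14.58 -22.83
h 6 4 -63.53 -66.26
g 6 5 14.58 13.10
h 6 5 0.24 3.02
g 6 6 -86.36 -78.09
h 6 6 50.94 55.40
g 7 0 79.88 80.44
g 7 1 -74.46 -75.00
h 7 1 -61.14 -57.80
g 7 2 -1.65 -4.55
h 7 2 -22.57 -21.20
g 7 3 38.73 45.24
h 7 3 6.82 6.54
g 7 4 12.30 14.00
h 7 4 25.35 24.96
g 7 5 9.37 10.46
h 7 5 10.93 7.03
g 7 6 5.42 1.64
h 7 6 -26.32 -27.61
g 7 7 1.94 4.92
h 7 7 -4.64 -3.28
g 8 0 24.80 24.41
g 8 1 7.62 8.21
h 8 1 11.20 10.84
g 8 2 -11.73 -14.50
h 8 2 -20.88 -20.03
g 8 3 -6.88 -5.59
h 8 3 9.83 11.83
g 8 4 -18.11 -19.34
h 8 4 -19.71 -17.41
g 8 5 10.17 11.61
h 8 5 16.22 16.71
g 8 6 9.36 10.85
h 8 6 7.61 6.96
g 8 7 -11.25 -14.05
h 8 7 -12.76 -10.74
g 8 8 -4.87 -3.54
h 8 8 -0.06 1.64
g 9 0 5.58 5.50
g 9 1 9.76 9.45
h 9 1 -20.11 -20.54
g 9 2 3.58 3.45
h 9 2 12.69 11.51
g 9 3 -6.94 -5.27
h 9 3 12.67 12.75
g 9 4 5.01 3.13
h 9 4 -6.72 -7.14
g 9 5 -10.76 -12.38
h 9 5 -8.16 -7.42
g 9 6 -1.25 -0.76
h 9 6 8.10 7.97
g 9 7 8.76 8.43
h 9 7 2.92 2.14
g 9 8 -6.66 -8.42
h 9 8 -7.73 -6.08
g 9 9 -9.22 -10.08
h 9 9 6.01 7.01
g 10 0 -2.17 -2.17
g 10 1 -6.12 -6.12
h 10 1 2.19 2.19
g 10 2 1.42 1.42
h 10 2 0.10 0.10
g 10 3 -2.35 -2.35
h 10 3 4.46 4.46
g 10 4 -0.15 -0.15
h 10 4 4.76 4.76
g 10 5 3.06 3.06
h 10 5 -6.58 -6.58
g 10 6 0.29 0.29
h 10 6 -1.01 -1.01
g 10 7 2.06 2.06
h 10 7 -3.47 -3.47
g 10 8 3.77 3.77
h 10 8 -0.86 -0.86
g 10 9 -0.21 -0.21
h 10 9 -2.31 -2.31
g 10 10 -2.09 -2.09
h 10 10 -2.09 -2.09
g 11 0 2.95 2.95
g 11 1 -1.60 -1.60
h 11 1 0.26 0.26
g 11 2 -1.88 -1.88
h 11 2 1.44 1.44
g 11 3 1.44 1.44
h 11 3 -0.77 -0.77
g 11 4 -0.31 -0.31
h 11 4 -2.27 -2.27
g 11 5 0.29 0.29
h 11 5 0.90 0.90
g 11 6 -0.79 -0.79
h 11 6 -0.58 -0.58
g 11 7 0.53 0.53
h 11 7 -2.69 -2.69
g 11 8 1.80 1.80
h 11 8 -1.08 -1.08
g 11 9 0.16 0.16
h 11 9 -1.58 -1.58
g 11 10 0.96 0.96
h 11 10 -1.90 -1.90
g 11 11 3.99 3.99
h 11 11 -1.39 -1.39
g 12 0 -2.15 -2.15
g 12 1 -0.29 -0.29
h 12 1 -0.55 -0.55
g 12 2 0.21 0.21
h 12 2 0.23 0.23
g 12 3 0.89 0.89
h 12 3 2.38 2.38
g 12 4 -0.38 -0.38
h 12 4 -2.63 -2.63
g 12 5 0.96 0.96
h 12 5 0.61 0.61
g 12 6 -0.30 -0.30
h 12 6 0.40 0.40
g 12 7 0.46 0.46
h 12 7 0.01 0.01
g 12 8 -0.35 -0.35
h 12 8 0.02 0.02
g 12 9 -0.36 -0.36
h 12 9 0.28 0.28
g 12 10 0.08 0.08
h 12 10 -0.87 -0.87
g 12 11 -0.49 -0.49
h 12 11 -0.34 -0.34
g 12 12 -0.08 -0.08
h 12 12 0.88 0.88
g 13 0 -0.16 -0.16
g 13 1 -0.88 -0.88
h 13 1 -0.76 -0.76
g 13 2 0.30 0.30
h 13 2 0.33 0.33
g 13 3 0.28 0.28
h 13 3 1.72 1.72
g 13 4 -0.43 -0.43
h 13 4 -0.54 -0.54
g 13 5 1.18 1.18
h 13 5 -1.07 -1.07
g 13 6 -0.37 -0.37
h 13 6 -0.04 -0.04
g 13 7 0.75 0.75
h 13 7 0.63 0.63
g 13 8 -0.26 -0.26
h 13 8 0.21 0.21
g 13 9 0.35 0.35
h 13 9 0.53 0.53
g 13 10 -0.05 -0.05
h 13 10 0.38 0.38
g 13 11 0.41 0.41
h 13 11 -0.22 -0.22
g 13 12 -0.10 -0.10
h 13 12 -0.57 -0.57
g 13 13 -0.18 -0.18
h 13 13 -0.82 -0.82
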