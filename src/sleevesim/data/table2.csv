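bougie_fr,pressure_mmhg,grouping,mean_percent,sd_percent
27,7.5,whole,11.42,4.03
27,7.5,antrum,14.30,4.55
27,7.5,corpus,10.43,3.30
27,7.5,mucosa,13.96,2.99
27,7.5,muscularis,10.00,3.84
27,15,whole,18.73,6.00
27,15,antrum,23.76,6.25
27,15,corpus,16.99,4.82
27,15,mucosa,22.90,4.56
27,15,muscularis,16.38,5.42
27,22.5,whole,24.41,7.41
27,22.5,antrum,31.15,7.30
27,22.5,corpus,22.09,5.87
27,22.5,mucosa,29.80,5.81
27,22.5,muscularis,21.39,6.43
27,37.5,whole,32.97,9.42
27,37.5,antrum,42.56,8.48
27,37.5,corpus,29.66,7.20
27,37.5,mucosa,39.76,7.65
27,37.5,muscularis,29.16,8.08
30,7.5,whole,11.66,3.90
30,7.5,antrum,14.94,4.29
30,7.5,corpus,10.59,3.09
30,7.5,mucosa,14.06,3.06
30,7.5,muscularis,10.34,3.69
30,15,whole,19.31,6.07
30,15,antrum,25.36,5.99
30,15,corpus,17.33,4.62
30,15,mucosa,23.08,4.81
30,15,muscularis,17.22,5.68
30,22.5,whole,25.28,7.43
30,22.5,antrum,33.24,6.73
30,22.5,corpus,22.67,5.55
30,22.5,mucosa,30.04,6.06
30,22.5,muscularis,22.64,6.77
30,37.5,whole,33.99,9.12
30,37.5,antrum,44.54,7.43
30,37.5,corpus,30.53,6.63
30,37.5,mucosa,39.92,7.68
30,37.5,muscularis,30.69,8.14
34,7.5,whole,12.52,4.10
34,7.5,antrum,16.03,4.43
34,7.5,corpus,11.31,3.19
34,7.5,mucosa,14.91,3.21
34,7.5,muscularis,11.49,3.93
34,15,whole,20.67,6.44
34,15,antrum,27.07,6.42
34,15,corpus,18.47,4.83
34,15,mucosa,24.44,5.02
34,15,muscularis,18.51,6.16
34,22.5,whole,26.79,7.71
34,22.5,antrum,34.85,7.03
34,22.5,corpus,24.01,5.73
34,22.5,mucosa,31.65,6.29
34,22.5,muscularis,24.00,7.04
34,37.5,whole,35.85,9.49
34,37.5,antrum,46.43,7.96
34,37.5,corpus,32.20,6.88
34,37.5,mucosa,41.82,7.94
34,37.5,muscularis,32.41,8.56
36,7.5,whole,13.37,4.19
36,7.5,antrum,17.01,4.41
36,7.5,corpus,12.11,3.28
36,7.5,mucosa,15.69,3.32
36,7.5,muscularis,11.99,4.05
36,15,whole,21.99,6.55
36,15,antrum,28.60,6.17
36,15,corpus,19.70,4.93
36,15,mucosa,25.59,5.16
36,15,muscularis,19.85,6.35
36,22.5,whole,28.26,7.70
36,22.5,antrum,36.39,6.81
36,22.5,corpus,25.46,5.76
36,22.5,mucosa,32.90,6.37
36,22.5,muscularis,25.52,7.08
36,37.5,whole,37.47,9.41
36,37.5,antrum,48.18,7.66
36,37.5,corpus,33.81,6.81
36,37.5,mucosa,43.09,7.97
36,37.5,muscularis,34.15,8.58
38,7.5,whole,13.75,4.26
38,7.5,antrum,17.35,4.34
38,7.5,corpus,12.51,3.46
38,7.5,mucosa,15.88,3.58
38,7.5,muscularis,12.49,4.14
38,15,whole,22.42,6.50
38,15,antrum,29.37,5.88
38,15,corpus,20.03,4.75
38,15,mucosa,25.82,5.70
38,15,muscularis,20.43,6.10
38,22.5,whole,29.08,8.07
38,22.5,antrum,37.52,6.77
38,22.5,corpus,25.81,5.49
38,22.5,mucosa,33.39,6.97
38,22.5,muscularis,26.55,7.32
38,37.5,whole,38.85,10.47
38,37.5,antrum,49.66,8.01
38,37.5,corpus,34.20,6.39
38,37.5,mucosa,44.03,9.95
38,37.5,muscularis,35.82,9.54
40,7.5,whole,14.13,4.14
40,7.5,antrum,17.88,4.26
40,7.5,corpus,12.86,3.23
40,7.5,mucosa,16.25,3.42
40,7.5,muscularis,12.92,4.03
40,15,whole,23.04,6.34
40,15,antrum,29.83,5.74
40,15,corpus,20.74,4.67
40,15,mucosa,26.28,5.26
40,15,muscularis,21.20,6.17
40,22.5,whole,29.57,7.50
40,22.5,antrum,38.06,6.30
40,22.5,corpus,26.69,5.40
40,22.5,mucosa,33.63,6.45
40,22.5,muscularis,27.25,7.06
40,37.5,whole,39.08,9.18
40,37.5,antrum,50.36,6.88
40,37.5,corpus,35.25,6.25
40,37.5,mucosa,44.36,7.97
40,37.5,muscularis,36.37,8.72
42,7.5,whole,14.84,4.27
42,7.5,antrum,18.78,4.35
42,7.5,corpus,13.50,3.31
42,7.5,mucosa,16.93,3.48
42,7.5,muscularis,13.63,4.21
42,15,whole,24.09,6.46
42,15,antrum,31.00,5.83
42,15,corpus,21.75,4.77
42,15,mucosa,27.31,5.37
42,15,muscularis,22.23,6.31
42,22.5,whole,30.92,7.80
42,22.5,antrum,39.84,6.55
42,22.5,corpus,27.90,5.56
42,22.5,mucosa,34.90,6.62
42,22.5,muscularis,28.63,7.51
42,37.5,whole,40.24,9.23
42,37.5,antrum,51.33,7.14
42,37.5,corpus,36.48,6.41
42,37.5,mucosa,45.08,8.08
42,37.5,muscularis,37.47,8.69
46,7.5,whole,15.66,2.51
46,7.5,antrum,19.62,2.55
46,7.5,corpus,13.75,2.14
46,7.5,mucosa,17.52,2.23
46,7.5,muscularis,14.52,1.99
46,15,whole,24.59,4.24
46,15,antrum,32.24,4.19
46,15,corpus,22.14,3.53
46,15,mucosa,28.61,3.75
46,15,muscularis,23.65,3.34
46,22.5,whole,31.25,5.46
46,22.5,antrum,4.12,5.25
46,22.5,corpus,28.46,4.46
46,22.5,mucosa,35.69,4.79
46,22.5,muscularis,30.01,4.39
46,37.5,whole,41.23,6.92
46,37.5,antrum,52.46,6.47
46,37.5,corpus,37.98,5.57
46,37.5,mucosa,46.32,6.06
46,37.5,muscularis,38.88,5.61
48,7.5,whole,16.18,4.44
48,7.5,antrum,20.47,4.38
48,7.5,corpus,14.73,3.39
48,7.5,mucosa,18.16,3.68
48,7.5,muscularis,15.05,4.44
48,15,whole,25.99,6.49
48,15,antrum,33.13,5.65
48,15,corpus,23.57,4.73
48,15,mucosa,29.00,5.55
48,15,muscularis,24.27,6.36
48,22.5,whole,33.31,7.96
48,22.5,antrum,42.51,6.66
48,22.5,corpus,30.13,5.57
48,22.5,mucosa,36.87,6.84
48,22.5,muscularis,31.28,7.84
48,37.5,whole,42.85,9.24
48,37.5,antrum,54.27,6.88
48,37.5,corpus,38.98,6.25
48,37.5,mucosa,47.08,8.21
48,37.5,muscularis,40.43,8.92
50,7.5,whole,16.85,4.57
50,7.5,antrum,21.32,4.42
50,7.5,corpus,15.33,3.49
50,7.5,mucosa,18.88,3.83
50,7.5,muscularis,15.71,4.55
50,15,whole,26.90,6.59
50,15,antrum,34.17,5.66
50,15,corpus,24.44,4.82
50,15,mucosa,29.93,5.64
50,15,muscularis,25.22,6.47
50,22.5,whole,34.28,7.96
50,22.5,antrum,43.59,6.40
50,22.5,corpus,31.10,5.62
50,22.5,mucosa,37.83,6.97
50,22.5,muscularis,32.27,7.79
50,37.5,whole,43.97,9.28
50,37.5,antrum,55.45,6.89
50,37.5,corpus,40.07,6.28
50,37.5,mucosa,48.10,8.30
50,37.5,muscularis,41.67,9.00
54,7.5,whole,17.42,4.62
54,7.5,antrum,22.08,4.41
54,7.5,corpus,15.86,3.51
54,7.5,mucosa,19.42,3.89
54,7.5,muscularis,16.37,4.62
54,15,whole,27.82,6.66
54,15,antrum,35.34,5.65
54,15,corpus,25.31,4.83
54,15,mucosa,30.74,5.72
54,15,muscularis,26.29,6.60
54,22.5,whole,35.19,7.88
54,22.5,antrum,44.58,6.24
54,22.5,corpus,32.06,5.54
54,22.5,mucosa,38.66,6.97
54,22.5,muscularis,33.38,7.72
54,37.5,whole,45.19,9.32
54,37.5,antrum,56.94,6.80
54,37.5,corpus,41.28,6.25
54,37.5,mucosa,49.63,8.31
54,37.5,muscularis,43.18,9.18
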