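bougie_fr,pressure_mmhg,volume_ml
27,7.5,3.24
27,15,6.52
27,22.5,9.70
27,37.5,16.04
27,75,27.30
30,7.5,4.07
30,15,8.38
30,22.5,12.63
30,37.5,20.41
30,75,35.53
34,7.5,5.22
34,15,10.80
34,22.5,16.15
34,37.5,26.36
34,75,45.05
36,7.5,6.54
36,15,13.56
36,22.5,20.07
36,37.5,32.62
36,75,56.05
38,7.5,7.29
38,15,15.38
38,22.5,23.16
38,37.5,38.74
38,75,67.01
40,7.5,8.06
40,15,16.61
40,22.5,24.79
40,37.5,40.71
40,75,68.52
42,7.5,9.76
42,15,20.04
42,22.5,30.39
42,37.5,48.39
42,75,82.04
46,7.5,11.70
46,15,23.90
46,22.5,36.77
46,37.5,58.49
46,75,95.25
48,7.5,13.89
48,15,28.29
48,22.5,43.41
48,37.5,68.53
48,75,113.77
50,7.5,16.37
50,15,33.24
50,22.5,50.29
50,37.5,79.84
50,75,131.59
54,7.5,19.05
54,15,38.89
54,22.5,57.92
54,37.5,93.38
54,75,150.84
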