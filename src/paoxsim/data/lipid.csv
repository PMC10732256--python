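# Lipid (soybean oil) absorption coefficient, cm^-1, standard compilation values.
wavelength_nm,mu_a_per_cm
400,0.01
410,0.0094
420,0.0088
430,0.0082
440,0.0076
450,0.007
460,0.0066
470,0.0062
480,0.0058
490,0.0054
500,0.005
510,0.0048
520,0.0046
530,0.0044
540,0.0042
550,0.004
560,0.0038
570,0.0036
580,0.0034
590,0.0032
600,0.003
610,0.003
620,0.003
630,0.003
640,0.003
650,0.003
660,0.00388
670,0.00476
680,0.00564
690,0.00652
700,0.0074
710,0.0067
720,0.006
730,0.00753333
740,0.00906667
750,0.0106
760,0.012
770,0.0105
780,0.009
790,0.0092
800,0.0094
810,0.00964
820,0.00988
830,0.01012
840,0.01036
850,0.0106
860,0.0114
870,0.0122
880,0.013
890,0.0166
900,0.0202
910,0.03
920,0.077
930,0.107
940,0.069
950,0.043
960,0.0365
970,0.03
980,0.028
990,0.026
1000,0.024
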