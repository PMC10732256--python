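# Pure water absorption coefficient, cm^-1, standard compilation values.
wavelength_nm,mu_a_per_cm
400,0.00058
410,0.000525
420,0.00047
430,0.00043
440,0.00039
450,0.00037
460,0.00037
470,0.0004
480,0.00043
490,0.000515
500,0.0006
510,0.000675
520,0.00075
530,0.000825
540,0.0009
550,0.001
560,0.0012
570,0.0014
580,0.0016
590,0.00191
600,0.00222
610,0.00249
620,0.00276
630,0.002935
640,0.00311
650,0.0034
660,0.004
670,0.004325
680,0.00465
690,0.005335
700,0.00602
710,0.00739
720,0.0104
730,0.0168
740,0.0266
750,0.028
760,0.0256
770,0.024
780,0.0223
790,0.0224
800,0.0224
810,0.023
820,0.0255
830,0.0287
840,0.034
850,0.0433
860,0.0499
870,0.053
880,0.055
890,0.0582
900,0.0679
910,0.0739
920,0.112
930,0.264
940,0.335
950,0.388
960,0.42
970,0.45
980,0.43
990,0.4
1000,0.363
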