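# Oxyhemoglobin absorption of whole blood (150 g/L hemoglobin), cm^-1.
# Converted from the standard compilation of molar extinction coefficients e(lambda)
# via mu_a = ln(10) * e * 150 / 64500.
wavelength_nm,mu_a_per_cm
400,1425.63
410,2499.86
420,2572.26
430,1317.68
440,549.3
450,336.37
460,177.829
470,130.005
480,86.5129
490,77.5382
500,112.093
510,108.168
520,129.598
530,213.964
540,285.071
550,230.344
560,174.638
570,237.295
580,238.269
590,77.1098
600,17.1355
610,8.0644
620,5.04427
630,3.26646
640,2.36684
650,1.97058
660,1.71355
670,1.57433
680,1.48865
690,1.47794
700,1.55291
710,1.68142
720,1.86349
730,2.08839
740,2.38826
750,2.77381
760,3.13794
770,3.48065
780,3.80194
790,4.08039
800,4.36956
810,4.62659
820,4.90504
830,5.21562
840,5.47266
850,5.66543
860,5.81537
870,5.97601
880,6.1795
890,6.37227
900,6.41511
910,6.54363
920,6.60788
930,6.7364
940,6.84885
950,6.88634
960,6.95059
970,7.01485
980,7.03627
990,7.06305
1000,7.07911
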