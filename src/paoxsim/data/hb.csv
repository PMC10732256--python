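# Deoxyhemoglobin absorption of whole blood (150 g/L hemoglobin), cm^-1.
# Converted from the standard compilation of molar extinction coefficients e(lambda)
# via mu_a = ln(10) * e * 150 / 64500.
wavelength_nm,mu_a_per_cm
400,1195.72
410,1627.64
420,2182.42
430,2830.57
440,2213.05
450,553.113
460,389.405
470,214.687
480,149.079
490,127.858
500,111.713
510,111.702
520,138.016
530,209.032
540,249.493
550,286.013
560,288.027
570,240.615
580,198.237
590,128.516
600,78.5931
610,55.1764
620,39.7758
630,27.5721
640,23.2668
650,20.0807
660,17.2801
670,14.9668
680,12.8945
690,10.9882
700,9.6066
710,8.24647
720,7.10053
730,5.90104
740,5.97601
750,7.52356
760,8.29466
770,7.02556
780,5.75646
790,4.77117
800,4.08039
810,3.83943
820,3.71627
830,3.71091
840,3.70556
850,3.7002
860,3.72697
870,3.77517
880,3.88762
890,3.96794
900,4.08039
910,4.17678
920,4.31601
930,4.44452
940,4.59446
950,4.76582
960,4.87291
970,5.01214
980,5.12995
990,5.25846
1000,5.38698
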