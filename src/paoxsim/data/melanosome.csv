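# Melanosome (interior of cutaneous melanin organelle) absorption coefficient.
# Power law C*(lambda/500 nm)^-3.5 with C = 519.2 cm^-1, the standard tissue-optics
# compilation form, calibrated so 2% v/v melanosomes give 3.45 cm^-1 at 685 nm.
wavelength_nm,mu_a_per_cm
400,1133.69
410,1039.83
420,955.726
430,880.17
440,812.123
450,750.693
460,695.11
470,644.709
480,598.91
490,557.211
500,519.172
510,484.407
520,452.579
530,423.39
540,396.577
550,371.909
560,349.179
570,328.204
580,308.822
590,290.887
600,274.269
610,258.852
620,244.532
630,231.214
640,218.815
650,207.257
660,196.473
670,186.399
680,176.98
690,168.164
700,159.905
710,152.16
720,144.891
730,138.063
740,131.642
750,125.601
760,119.911
770,114.548
780,109.49
790,104.716
800,100.205
810,95.9419
820,91.9089
830,88.0913
840,84.4751
850,81.0475
860,77.7968
870,74.7117
880,71.7822
890,68.9987
900,66.3525
910,63.8353
920,61.4396
930,59.1583
940,56.9847
950,54.9128
960,52.9367
970,51.0511
980,49.251
990,47.5317
1000,45.8887
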