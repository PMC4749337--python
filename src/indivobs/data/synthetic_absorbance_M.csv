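# synthetic basis table 'absorbance_M' (synthetic-v1); see indivobs.synthbasis
wavelength_nm,value
390,0.215716198832
395,0.204914283876
400,0.195138050567
405,0.187153074153
410,0.181707982932
415,0.179514834763
420,0.18123132988
425,0.187444158936
430,0.198652567931
435,0.215251302572
440,0.237512514055
445,0.265566937372
450,0.299385571582
455,0.338763981548
460,0.383311916332
465,0.432450916474
470,0.485421783854
475,0.541302249028
480,0.599033191617
485,0.65744986986
490,0.715313392516
495,0.771337603141
500,0.824207859881
505,0.872590783486
510,0.915137545773
515,0.950487125536
520,0.977279439316
525,0.994190361309
530,1
535,0.993700557265
540,0.9746394565
545,0.942677860702
550,0.89832837775
555,0.842826568514
560,0.778097456061
565,0.70660379965
570,0.631100034003
575,0.554347933257
580,0.478861077731
585,0.406730077328
590,0.339548212563
595,0.2784236318
600,0.224042602275
605,0.176743921142
610,0.136575925581
615,0.103328452008
620,0.0765528519889
625,0.055592793747
630,0.0396413448179
635,0.0278214279382
640,0.0192710624545
645,0.0132121128417
650,0.00899038094505
655,0.00608707506606
660,0.00410961417145
665,0.00277162460313
670,0.00186998225855
675,0.00126358800798
680,0.000855894964814
685,0.000581529320266
690,0.000396527882712
695,0.00027144570317
700,0.000186599221003
705,0.000128833718407
710,8.93491345553e-05
715,6.22472108071e-05
720,4.3564246575e-05
725,3.0628203664e-05
730,2.16314308871e-05
735,1.53463879922e-05
740,1.09361442504e-05
745,7.82772907212e-06
750,5.62722989385e-06
755,4.06268246734e-06
760,2.94551532035e-06
765,2.14442054958e-06
770,1.56757589692e-06
775,1.1505000966e-06
780,8.47722627971e-07
785,6.27046413133e-07
790,4.65580156503e-07
795,3.46983282033e-07
800,2.59545111355e-07
805,1.94840286212e-07
810,1.46783816867e-07
815,1.10964370788e-07
820,8.41720478846e-08
825,6.40626279267e-08
830,4.89179490031e-08
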