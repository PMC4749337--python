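# synthetic basis table 'absorbance_L' (synthetic-v1); see indivobs.synthbasis
wavelength_nm,value
390,0.235574209355
395,0.22501094023
400,0.213601897449
405,0.201864065184
410,0.190342555441
415,0.17959647679
420,0.170186100662
425,0.162661697041
430,0.157554094094
435,0.155366693256
440,0.156568383009
445,0.161586584506
450,0.170799573525
455,0.184527294288
460,0.203020136496
465,0.226445588584
470,0.254873271652
475,0.288259516471
480,0.326433238723
485,0.369085230951
490,0.415762964442
495,0.465872479815
500,0.51868795541
505,0.573368236192
510,0.628978271538
515,0.684512399547
520,0.7389160445
525,0.791102851973
530,0.839965588206
535,0.88438112673
540,0.923212264363
545,0.955311588806
550,0.979534692653
555,0.994771051857
560,1
565,0.994375468321
570,0.977335897815
575,0.94872548171
580,0.908902187377
585,0.858801476017
590,0.799927490986
595,0.734258262556
600,0.664074966117
605,0.591748483359
610,0.51952904685
615,0.449380995724
620,0.382887134453
625,0.32122435251
630,0.265193157617
635,0.215274156215
640,0.171685414069
645,0.134424058714
650,0.103289436167
655,0.0778979085983
660,0.0577048934626
665,0.0420450262545
670,0.0301896653475
675,0.0214102995869
680,0.0150332405306
685,0.0104756038363
690,0.00726040079739
695,0.0050147228274
700,0.00345751200814
705,0.00238293507657
710,0.00164353444078
715,0.00113540006116
720,0.000786181046386
725,0.00054592060028
730,0.000380314161177
735,0.000265882120201
740,0.000186578313087
745,0.000131438433294
750,9.29639982316e-05
755,6.6018188326e-05
760,4.7073988759e-05
765,3.37030517162e-05
770,2.42282989098e-05
775,1.74876299025e-05
780,1.26729532572e-05
785,9.22029524743e-06
790,6.73458459749e-06
795,4.93802099631e-06
800,3.63452044686e-06
805,2.68514954901e-06
810,1.99109335872e-06
815,1.48180442173e-06
820,1.10672702443e-06
825,8.29496985971e-07
830,6.23861586465e-07
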