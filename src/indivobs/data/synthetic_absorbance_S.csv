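# synthetic basis table 'absorbance_S' (synthetic-v1); see indivobs.synthbasis
wavelength_nm,value
390,0.753487546376
395,0.817323191482
400,0.876088150683
405,0.926734673794
410,0.966221991097
415,0.991571195842
420,1
425,0.989188658226
430,0.957682504352
435,0.905355483121
440,0.833774383605
445,0.746279467024
450,0.647686865437
455,0.543691753791
460,0.44018282865
465,0.342649122994
470,0.255696984197
475,0.18258635527
480,0.1248057938
485,0.0819234852414
490,0.0519399567288
495,0.0320421303121
500,0.0193831334504
505,0.0115792193095
510,0.00687130686318
515,0.00406897495263
520,0.00241256385365
525,0.00143568923571
530,0.000858906873975
535,0.000517147063183
540,0.000313597268512
545,0.000191605675906
550,0.000117984830901
555,7.32270395094e-05
560,4.58089354697e-05
565,2.88829195852e-05
570,1.83528946758e-05
575,1.17513809271e-05
580,7.58113945726e-06
585,4.92693515443e-06
590,3.2251412189e-06
595,2.12608966131e-06
600,1.4112581682e-06
605,9.43093811781e-07
610,6.34394180309e-07
615,4.29489810092e-07
620,2.9259763743e-07
625,2.00562373477e-07
630,1.38301476666e-07
635,9.59273704101e-08
640,6.69172263366e-08
645,4.69413891777e-08
650,3.31086234019e-08
655,2.34768402225e-08
660,1.67339784939e-08
665,1.19886154677e-08
670,8.63176892227e-09
675,6.24516109864e-09
680,4.53998111529e-09
685,3.31578099674e-09
690,2.43273691237e-09
695,1.79283094229e-09
700,1.32701857282e-09
705,9.86433649675e-10
710,7.36330594941e-10
715,5.51891705749e-10
720,4.15311501676e-10
725,3.13759694784e-10
730,2.37951512132e-10
735,1.81139794279e-10
740,1.3840132301e-10
745,1.06129313593e-10
750,8.16709940461e-11
755,6.30677243253e-11
760,4.88678886728e-11
765,3.79916475289e-11
770,2.9632794359e-11
775,2.31872654925e-11
780,1.82008694113e-11
785,1.43309278608e-11
790,1.13180244901e-11
795,8.9651239395e-12
800,7.12208481128e-12
805,5.67413395917e-12
810,4.53326009056e-12
815,3.63176609344e-12
820,2.91742299756e-12
825,2.3498161459e-12
830,1.89758167605e-12
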