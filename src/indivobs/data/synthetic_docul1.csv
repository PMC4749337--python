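# synthetic basis table 'docul1' (synthetic-v1); see indivobs.synthbasis
wavelength_nm,value
390,0.679078332499
395,0.628880116163
400,0.575552275055
405,0.520559777299
410,0.465291760964
415,0.411006829582
420,0.358791078888
425,0.309530290385
430,0.263896479012
435,0.222347862051
440,0.185140418714
445,0.152348592687
450,0.123892373614
455,0.0995679628948
460,0.079079441162
465,0.0620692478824
470,0.0481457876191
475,0.0369070242437
480,0.0279594539923
485,0.0209323150887
490,0.015487266171
495,0.0113240344753
500,0.00818269803732
505,0.00584333504272
510,0.00412376561913
515,0.00287604766967
520,0.00198228962615
525,0.00135022783842
530,0.000908899635005
535,0.000604635610506
540,0.000397503023136
545,0.000258259360747
550,0.000165821419664
555,0.000105218984944
560,6.59806376212e-05
565,4.08891262216e-05
570,2.50419459253e-05
575,1.51564411773e-05
580,9.06557436525e-06
585,5.35873564049e-06
590,3.13038866455e-06
595,1.80718708106e-06
600,1.03104325594e-06
605,5.81325775924e-07
610,3.23915101132e-07
615,1.78365860235e-07
620,9.70646720159e-08
625,5.22010900094e-08
630,2.77438592994e-08
635,1.45721319991e-08
640,7.56394289379e-09
645,3.88009454166e-09
650,1.96700423742e-09
655,9.85455924655e-10
660,4.87908108595e-10
665,2.38730434334e-10
670,1.15437380213e-10
675,5.51637850578e-11
680,2.60513704507e-11
685,1.21583884089e-11
690,5.60777232744e-12
695,2.55607536547e-12
700,1.15139902641e-12
705,5.12562680919e-13
710,2.25495058248e-13
715,9.80383506766e-14
720,4.21234453455e-14
725,1.78863076456e-14
730,7.50561750783e-15
735,3.11258401287e-15
740,1.27562980454e-15
745,5.16650857642e-16
750,2.06794304375e-16
755,8.17991730078e-17
760,3.19762973942e-17
765,1.23531113854e-17
770,4.71621355186e-18
775,1.77942418063e-18
780,6.63490082224e-19
785,2.44488425975e-19
790,8.90330180036e-20
795,3.20414976553e-20
800,1.13957638504e-20
805,4.00537327867e-21
810,1.3912701677e-21
815,4.77583013012e-22
820,1.62014987229e-22
825,5.43163317488e-23
830,1.79959424246e-23
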