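# synthetic basis table 'docul2' (synthetic-v1); see indivobs.synthbasis
wavelength_nm,value
390,0.674034236336
395,0.629573897657
400,0.583701516703
405,0.537344706576
410,0.49138463627
415,0.446619172101
420,0.40373454755
425,0.363286513837
430,0.325691091963
435,0.291224300688
440,0.260029636882
445,0.232131673656
450,0.207453931137
455,0.185839154638
460,0.16707027656
465,0.15089060063
470,0.137022083353
475,0.125180952195
480,0.115090253279
485,0.106489232675
490,0.0991397051994
495,0.0928297438546
500,0.0873751320249
505,0.0826190665152
510,0.0784305943795
515,0.0747022240784
520,0.0713470857466
525,0.0682959386272
530,0.0654942459825
535,0.0628994661779
540,0.0604786475565
545,0.0582063661976
550,0.0560630098766
555,0.0540333873919
560,0.0521056280747
565,0.050270329589
570,0.0485199109528
575,0.0468481301731
580,0.0452497304546
585,0.0437201844417
590,0.0422555115782
595,0.0408521489067
600,0.0395068602017
605,0.0382166721373
610,0.0369788292324
615,0.0357907616681
620,0.0346500618403
625,0.0335544668007
630,0.0325018446605
635,0.0314901836753
640,0.0305175831676
645,0.0295822457384
650,0.0286824704126
655,0.0278166464889
660,0.0269832479446
665,0.0261808282947
670,0.0254080158395
675,0.0246635092504
680,0.02394607346
685,0.0232545358256
690,0.0225877825457
695,0.0219447553071
700,0.0213244481474
705,0.0207259045152
710,0.0201482145161
715,0.0195905123293
720,0.0190519737845
725,0.018531814088
730,0.0180292856871
735,0.0175436762638
740,0.0170743068498
745,0.0166205300541
750,0.0161817283951
755,0.0157573127323
760,0.0153467207894
765,0.014949415763
770,0.0145648850124
775,0.0141926388247
780,0.0138322092502
785,0.0134831490041
790,0.0131450304301
795,0.012817444522
800,0.0125
805,0.0121923224383
810,0.0118940534402
815,0.0116048498588
820,0.01132438306
825,0.0110523382249
830,0.0107884136904
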