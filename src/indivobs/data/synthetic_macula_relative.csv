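# synthetic basis table 'macula_relative' (synthetic-v1); see indivobs.synthbasis
wavelength_nm,value
390,0.130288986435
395,0.186084176028
400,0.254345354334
405,0.333537252389
410,0.420921770934
415,0.513010212415
420,0.606108798529
425,0.696688441124
430,0.781393967815
435,0.856757756118
440,0.91899659008
445,0.964447221161
450,0.990984533058
455,1
460,0.997415321449
465,0.991691433346
470,0.988177579207
475,0.982582100059
480,0.959238974056
485,0.898170505683
490,0.788090445191
495,0.636145748565
500,0.466473556828
505,0.308431524021
510,0.18329117463
515,0.0979343604991
520,0.0472368386616
525,0.0207373570193
530,0.00839682205221
535,0.00319444369256
540,0.00116687464778
545,0.000417377203128
550,0.000147784628934
555,5.17563723826e-05
560,1.77653425664e-05
565,5.91017796115e-06
570,1.88853817407e-06
575,5.76305077441e-07
580,1.67428547431e-07
585,4.62394751368e-08
590,1.21318455078e-08
595,3.02318193126e-09
600,7.15462821435e-10
605,1.60798795552e-10
610,3.43200298555e-11
615,6.95633619948e-12
620,1.33900185834e-12
625,2.44765041708e-13
630,4.24898444087e-14
635,7.00468159886e-15
640,1.09662752754e-15
645,1.63041198307e-16
650,2.30198788718e-17
655,3.08657022312e-18
660,3.93021887752e-19
665,4.75252878289e-20
670,5.45758130999e-21
675,5.95172850822e-22
680,6.16386966765e-23
685,6.06221337205e-24
690,5.66208552078e-25
695,5.02214290333e-26
700,4.23028027664e-27
705,3.38389324178e-28
710,2.57058280342e-29
715,1.85444508317e-30
720,1.27046817278e-31
725,8.26572660653e-33
730,5.10699834881e-34
735,2.99652449444e-35
740,1.66969589942e-36
745,8.83536230337e-38
750,4.43995715295e-39
755,2.11885203084e-40
760,9.6026237515e-42
765,4.13282132998e-43
770,1.68915997282e-44
775,6.55635357976e-46
780,2.41669245198e-47
785,8.45956123356e-49
790,2.81217099681e-50
795,8.87775274181e-52
800,2.66153265617e-53
805,7.57753562876e-55
810,2.04876246399e-56
815,5.26044717873e-58
820,1.28268835899e-59
825,2.97020945563e-61
830,6.53161282494e-63
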