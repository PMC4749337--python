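# synthetic CIE 1964 10-degree CMFs, analytic fit (synthetic-v1)
wavelength_nm,x,y,z
380,0.00199487472149,0.000694408910223,0.00256177853765
385,0.0045278029449,0.00104396721982,0.00846448504458
390,0.00955714538454,0.00155116662465,0.0238447592675
395,0.0187809375486,0.00227787586714,0.0582429106101
400,0.0343974486672,0.00330599100362,0.125170594079
405,0.0587784781498,0.00474212823129,0.239721228932
410,0.0938099110414,0.00672271858222,0.413716995734
415,0.139979575383,0.0094192556034,0.649765547363
420,0.195481670905,0.0130433228699,0.936767545067
425,0.255744316396,0.0178508918805,1.24929988391
430,0.313756096184,0.0241452444433,1.55178175358
435,0.361317448762,0.0322777538703,1.80623382134
440,0.390950253296,0.042645677361,1.98093204132
445,0.397854555305,0.0556860919739,2.05706577066
450,0.381204996754,0.0718651730997,2.0315536504
455,0.344309908807,0.0916621888519,1.91576340707
460,0.293609075391,0.115547880542,1.73123589015
465,0.23693313742,0.143957320978,1.50415667761
470,0.181674134995,0.177257875664,1.26021520097
475,0.133444474842,0.215713505615,1.02091223757
480,0.0955138197396,0.259447293971,0.801675624075
485,0.068981168504,0.308404684556,0.611586803843
490,0.0534134875915,0.362320410074,0.45422059024
495,0.0476227571682,0.420692378713,0.32904159215
500,0.0503278957241,0.482765806026,0.232899860828
505,0.0605786410716,0.547530569137,0.161332167282
510,0.0779341015856,0.613734098481,0.109534338889
515,0.102454210663,0.67991112415,0.0729880892582
520,0.134578125802,0.744430319283,0.0477942809704
525,0.174949157154,0.805556434596,0.0307915159202
530,0.224222396713,0.861525033649,0.0195384050034
535,0.28287257901,0.910625576317,0.012223278913
540,0.351010609375,0.951287518782,0.00754628987762
545,0.42821640034,0.982163443716,0.00460155355143
550,0.513399469989,1.00220310666,0.00277365650381
555,0.604703410414,1.01071273042,0.00165388780608
560,0.699472973916,1.00739488007,0.000976271257133
565,0.79430137709,0.99236572265,0.000570862680898
570,0.8851697203,0.966148274599,0.000330869221484
575,0.967680346419,0.929642184532,0.000190192875157
580,1.03737265077,0.884072485848,0.000108487297476
585,1.09009532454,0.83092138994,6.14368791263e-05
590,1.12239594661,0.771848412659,3.455812395e-05
595,1.13188013029,0.708604822999,1.93167643302e-05
600,1.11749057952,0.642948525602,1.07340222763e-05
605,1.07966285499,0.576565056295,5.93204207644e-06
610,1.02032925797,0.510999461915,3.26151310762e-06
615,0.942763083997,0.447602578931,1.78466740019e-06
620,0.851279095478,0.387493774582,9.72209738378e-07
625,0.750828021487,0.331540731406,5.27424360557e-07
630,0.646538887971,0.280355490029,2.85025222011e-07
635,0.543269780362,0.234304835241,1.53478471218e-07
640,0.445223921251,0.193532296097,8.23690715252e-08
645,0.355674649405,0.157988566843,4.40695491778e-08
650,0.276822989958,0.127467034462,2.35109458452e-08
655,0.209789268691,0.101641277908,1.25098607088e-08
660,0.154720122807,0.080101816253,6.64009651756e-09
665,0.110977919794,0.0623899478385,3.51657336125e-09
670,0.0773730087568,0.0480271586232,1.85852166066e-09
675,0.0524004739202,0.0365392119918,9.8037729249e-10
680,0.0344505402299,0.0274746059669,5.16258880895e-10
685,0.0219728571865,0.0204175571704,2.71429929647e-10
690,0.0135866795893,0.0149960230808,1.42504152111e-10
695,0.00813907100204,0.0108855012556,7.47200620234e-11
700,0.00472020564939,0.00780945589386,3.91330802675e-11
705,0.00264821131143,0.00553723726306,2.04739746563e-11
710,0.00143622306743,0.00388030176577,1.07019524559e-11
715,0.000752369441896,0.00268743446287,5.58953097519e-12
720,0.000380393438088,0.00183954440182,2.91732947317e-12
725,0.000185468414747,0.00124446498087,1.52172881254e-12
730,8.71312382398e-05,0.000832060867669,7.93363833115e-13
735,3.94063092901e-05,0.000549828853619,4.13457100464e-13
740,1.71417518355e-05,0.000359087236213,2.15401640993e-13
745,7.16539353718e-06,0.000231778112655,1.1219247907e-13
750,2.87545054436e-06,0.000147858020646,5.84263243021e-14
755,1.10668921581e-06,9.32217746263e-05,3.04239553104e-14
760,4.0809295264e-07,5.80884591339e-05,1.58422066316e-14
765,1.44029737849e-07,3.57735762974e-05,8.24969022058e-15
770,4.86000456105e-08,2.17738322907e-05,4.29644455811e-15
775,1.5661363853e-08,1.30980728112e-05,2.23798232702e-15
780,4.81429214854e-09,7.78717508311e-06,1.16601712554e-15
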