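# Published inter-observer variability estimates, one row per (study, parameter).
# sd is in percent of the mean for the five density parameters and in nm for
# the three peak-wavelength shift parameters.
study,year,meas_type,method,repetitions,subjects,age_range,parameter,sd
Mellerio,1971,Physiological,In Vitro,N/A,20 eyes,19-66,lens,22.7
De Natale et al.,1988,Physiological,LOM,5,266,7-86,lens,17.8
"De Natale, Flammer",1992,Physiological,LOM,5,799,12-89,lens,18.7
Johnson et al.,1993,Physiological,Purkinje Image,16,40,24-77,lens,7.7
Savage et al.,2001,Physiological,Purkinje Image,16,41,18-59,lens,24.3
Cook et al.,1994,Physiological,SP,N/A,100,18-70,lens,24.5
Werner,1982,Physiological,VECP,N/A,50,0-70,lens,22.4
Savage et al.,2001,Psychophysical,SBM,>=3,41,18-59,lens,18.6
"Lutze, Bresnick",1991,Psychophysical,Sct.Thr.,3,50,20-69,lens,19.1
Polo et al.,1996,Psychophysical,Sct.Thr.,3,62,20-71,lens,24.3
Wild et al.,1998,Psychophysical,Sct.Thr.,12,51,24-83,lens,13.1
Hammond et al.,1999,Psychophysical,Sct.Thr.,2,125,20-63,lens,12.6
"van Norren, Vos",1974,Psychophysical,V'(lambda) Analysis,N/A,50,17-30,lens,12.8
Delori et al.,2001,Physiological,AF,N/A,159,15-80,macula,33.3
Wustemeyer et al.,2003,Physiological,AF,N/A,109,18-75,macula,32.6
Liew et al.,2005,Physiological,AF,N/A,300,18-50,macula,39.3
Trieschmann et al.,2006,Physiological,AF,N/A,120,20-86,macula,38.0
Delori et al.,2001,Physiological,FR,N/A,159,15-80,macula,30.4
Berendschot et al.,2002,Physiological,FR,1-2,289,63-73,macula,45.5
Broekmans et al.,2002,Physiological,FR,N/A,376,18-75,macula,45.5
Wustemeyer et al.,2003,Physiological,FR,N/A,109,18-75,macula,38.7
"Berendschot, van Norren",2004,Physiological,FR,N/A,138,18-76,macula,27.1
Berendschot et al.,1996,Physiological,FR,N/A,10,33.5+-9.6,density_L,18.3
"Burns, Elsner",1985,Psychophysical,Rayleigh Match,3,11,23-47,density_L,14.9
Elsner et al.,1988,Psychophysical,Rayleigh Match,10,52,13-69,density_L,20.0
Berendschot et al.,1996,Physiological,FR,N/A,10,33.5+-9.6,density_M,18.3
"Burns, Elsner",1985,Psychophysical,Rayleigh Match,3,11,23-47,density_M,14.9
Elsner et al.,1988,Psychophysical,Rayleigh Match,10,52,13-69,density_M,20.0
Stockman et al.,1999,Psychophysical,CMFs Trans.,N/A,5,N/A,density_S,14.7
Dartnall et al.,1983,Physiological,In Vitro (MSP),N/A,7 eyes,34-70,shift_L,5.2
"Burns, Elsner",1993,Psychophysical,Rayleigh Match,>=2,6,28-41,shift_L,2.1
Dartnall et al.,1983,Physiological,In Vitro (MSP),N/A,7 eyes,34-70,shift_M,3.5
"Burns, Elsner",1993,Psychophysical,Rayleigh Match,>=2,6,28-41,shift_M,2.5
Dartnall et al.,1983,Physiological,In Vitro (MSP),N/A,7 eyes,34-70,shift_S,3.6
"Merbs, Nathans",1992,Physiological,In Vitro (MSP),4,6-7 cones,N/A,shift_S,1.4
Stockman et al.,1999,Psychophysical,Test Sensitivity,20,5,N/A,shift_S,1.8
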