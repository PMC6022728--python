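# Bundled vegetation-index registry: name<TAB>formula<TAB>scale_invariant<TAB>reference
# Bands are reflectance at integer nm within 400-1000; formulas are closed-form band math.
NDVI	(R800-R670)/(R800+R670)	y	Rouse et al. 1974
SR	R800/R670	y	Jordan 1969
DVI	R800-R670	n	Tucker 1979
IPVI	R800/(R800+R670)	y	Crippen 1990
NLI	(R800*R800-R670)/(R800*R800+R670)	n	Goel & Qin 1994
MNLI	1.5*(R800*R800-R670)/(R800*R800+R670+0.5)	n	Yang et al. 2008
GDVI2	(R800*R800-R670*R670)/(R800*R800+R670*R670)	y	Wu 2014
GDVI3	(R800*R800*R800-R670*R670*R670)/(R800*R800*R800+R670*R670*R670)	y	Wu 2014
EVI	2.5*((R800-R670)/(R800+6*R670-7.5*R475+1))	n	Huete et al. 2002
EVI2	2.5*((R800-R670)/(R800+2.4*R670+1))	n	Jiang et al. 2008
SAVI	1.5*(R800-R670)/(R800+R670+0.5)	n	Huete 1988
OSAVI	1.16*(R800-R670)/(R800+R670+0.16)	n	Rondeaux et al. 1996
TSAVI	(1.22*(R800-1.22*R670-0.03))/(1.22*R800+R670-0.0366+0.08*(1+1.22*1.22))	n	Baret & Guyot 1989
PVI	(R800-1.22*R670-0.03)/1.5775	n	Richardson & Wiegand 1977
WDVI	R800-1.22*R670	n	Clevers 1989
ARVI	(R800-(2*R670-R475))/(R800+(2*R670-R475))	y	Kaufman & Tanre 1992
SARVI	1.5*(R800-(2*R670-R475))/(R800+(2*R670-R475)+0.5)	n	Huete & Liu 1994
GARI	(R800-(R550-1.7*(R475-R670)))/(R800+(R550-1.7*(R475-R670)))	y	Gitelson et al. 1996
GEMI	((2*(R800*R800-R670*R670)+1.5*R800+0.5*R670)/(R800+R670+0.5))*(1-0.25*((2*(R800*R800-R670*R670)+1.5*R800+0.5*R670)/(R800+R670+0.5)))-((R670-0.125)/(1-R670))	n	Pinty & Verstraete 1992
GNDVI	(R800-R550)/(R800+R550)	y	Gitelson et al. 1996
GRVI	R800/R550	y	Sripada et al. 2006
GDVI	R800-R550	n	Sripada et al. 2006
GSAVI	1.5*(R800-R550)/(R800+R550+0.5)	n	Sripada et al. 2006
GOSAVI	1.16*(R800-R550)/(R800+R550+0.16)	n	Sripada et al. 2006
BNDVI	(R800-R475)/(R800+R475)	y	Wang et al. 2007
GBNDVI	(R800-(R550+R475))/(R800+(R550+R475))	y	Wang et al. 2007
RBNDVI	(R800-(R670+R475))/(R800+(R670+R475))	y	Wang et al. 2007
PanNDVI	(R800-(R475+R550+R670))/(R800+(R475+R550+R670))	y	Wang et al. 2007
hNDVI	(R827-R668)/(R827+R668)	y	Oppelt & Mauser 2004
NDVI2	(R750-R705)/(R750+R705)	y	Gitelson & Merzlyak 1994
NDVI3	(R682-R553)/(R682+R553)	y	Gandia et al. 2004
mNDVI	(R800-R680)/(R800+R680-2*R445)	y	Sims & Gamon 2002
mND705	(R750-R705)/(R750+R705-2*R445)	y	Sims & Gamon 2002
mSR	(R800-R445)/(R680-R445)	y	Sims & Gamon 2002
mSR705	(R750-R445)/(R705-R445)	y	Sims & Gamon 2002
NDRE	(R790-R720)/(R790+R720)	y	Barnes et al. 2000
CCCI	((R790-R720)/(R790+R720))/((R800-R670)/(R800+R670))	y	Barnes et al. 2000
OSAVI2	1.16*(R750-R705)/(R750+R705+0.16)	n	Wu et al. 2008
MCARI	((R700-R670)-0.2*(R700-R550))*(R700/R670)	n	Daughtry et al. 2000
MCARI1	1.2*(2.5*(R800-R670)-1.3*(R800-R550))	n	Haboudane et al. 2004
MCARI705	((R750-R705)-0.2*(R750-R550))*(R750/R705)	n	Wu et al. 2008
TCARI	3*((R700-R670)-0.2*(R700-R550)*(R700/R670))	n	Haboudane et al. 2002
TCARI2	3*((R750-R705)-0.2*(R750-R550)*(R750/R705))	n	Wu et al. 2008
TCARIOSAVI	(3*((R700-R670)-0.2*(R700-R550)*(R700/R670)))/(1.16*(R800-R670)/(R800+R670+0.16))	n	Haboudane et al. 2002
TCARI2OSAVI2	(3*((R750-R705)-0.2*(R750-R550)*(R750/R705)))/(1.16*(R750-R705)/(R750+R705+0.16))	n	Wu et al. 2008
MCARIOSAVI	(((R700-R670)-0.2*(R700-R550))*(R700/R670))/(1.16*(R800-R670)/(R800+R670+0.16))	n	Daughtry et al. 2000
MCARI705OSAVI2	(((R750-R705)-0.2*(R750-R550))*(R750/R705))/(1.16*(R750-R705)/(R750+R705+0.16))	n	Wu et al. 2008
MTVI1	1.2*(1.2*(R800-R550)-2.5*(R670-R550))	n	Haboudane et al. 2004
TVI	0.5*(120*(R750-R550)-200*(R670-R550))	n	Broge & Leblanc 2000
MTCI	(R754-R709)/(R709-R681)	y	Dash & Curran 2004
REPLI	700+40*((((R670+R780)/2)-R700)/(R740-R700))	y	Guyot & Baret 1988
S2REP	705+35*((((R783+R665)/2)-R705)/(R740-R705))	y	Frampton et al. 2013
IRECI	(R783-R665)/(R705/R740)	n	Frampton et al. 2013
CIgreen	R800/R550-1	y	Gitelson et al. 2003
CIrededge	R800/R710-1	y	Gitelson et al. 2003
CI2	R760/R700-1	y	Gitelson et al. 2003
Gitelson	1/R700	n	Gitelson et al. 1999
Gitelson2	(R750-R800)/(R695-R740)-1	y	Gitelson et al. 2003
GMI1	R750/R550	y	Gitelson & Merzlyak 1997
GMI2	R750/R700	y	Gitelson & Merzlyak 1997
Vogelmann	R740/R720	y	Vogelmann et al. 1993
Vogelmann2	(R734-R747)/(R715+R726)	y	Vogelmann et al. 1993
Vogelmann4	(R734-R747)/(R715+R720)	y	Vogelmann et al. 1993
Maccioni	(R780-R710)/(R780-R680)	y	Maccioni et al. 2001
Datt	(R850-R710)/(R850-R680)	y	Datt 1999
Datt2	R850/R710	y	Datt 1999
Datt3	R754/R704	y	Datt 1999
Datt4	R672/(R550*R708)	n	Datt 1998
Datt5	R672/R550	y	Datt 1998
Datt6	R860/(R550*R708)	n	Datt 1998
LCI	(R850-R710)/(R850+R680)	y	Datt 1999
Carter	R695/R420	y	Carter 1994
Carter2	R695/R760	y	Carter 1994
Carter3	R605/R760	y	Carter 1994
Carter4	R710/R760	y	Carter 1994
Carter5	R695/R670	y	Carter 1994
Carter6	R550	n	Carter 1996
SR2	R752/R690	y	Zarco-Tejada et al. 2001
SR4	R700/R670	y	McMurtrey et al. 1994
SR5	R675/R700	y	Chappelle et al. 1992
SR7	R440/R690	y	Lichtenthaler et al. 1996
SR8	R515/R550	y	Hernandez-Clemente et al. 2012
RARSb	R675/(R700*R650)	n	Chappelle et al. 1992
RARSc	R760/R500	y	Chappelle et al. 1992
PARS	R746/R513	y	Chappelle et al. 1992
DCNI	((R720-R700)/(R700-R670))/(R720-R670+0.03)	n	Chen et al. 2010
RTVIcore	100*(R750-R730)-10*(R750-R550)	n	Chen et al. 2010
DD	(R749-R720)-(R701-R672)	n	Le Maire et al. 2004
DDn	2*R710-R660-R760	n	Le Maire et al. 2008
PSSRa	R800/R680	y	Blackburn 1998
PSSRb	R800/R635	y	Blackburn 1998
PSSRc	R800/R470	y	Blackburn 1998
PSNDa	(R800-R680)/(R800+R680)	y	Blackburn 1998
PSNDb	(R800-R635)/(R800+R635)	y	Blackburn 1998
PSND	(R800-R470)/(R800+R470)	y	Blackburn 1998 (carotenoid-specific)
SIPI	(R800-R445)/(R800-R680)	y	Penuelas et al. 1995
SIPI2	(R800-R505)/(R800-R690)	y	Penuelas et al. 1995
SRPI	R430/R680	y	Penuelas et al. 1995
NPCI	(R680-R430)/(R680+R430)	y	Penuelas et al. 1994
NPQI	(R415-R435)/(R415+R435)	y	Barnes et al. 1992
PRI	(R531-R570)/(R531+R570)	y	Gamon et al. 1992
MPRI	(R515-R530)/(R515+R530)	y	Hernandez-Clemente et al. 2011
PRIxCI2	((R531-R570)/(R531+R570))*(R760/R700-1)	y	Garrity et al. 2011
PSRI	(R678-R500)/R750	y	Merzlyak et al. 1999
ARI	1/R550-1/R700	n	Gitelson et al. 2001
mARI	(1/R550-1/R700)*R800	y	Gitelson et al. 2006
CRI1	1/R510-1/R550	n	Gitelson et al. 2002
CRI2	1/R510-1/R700	n	Gitelson et al. 2002
mCRI1	(1/R510-1/R550)*R800	y	Gitelson et al. 2006
mCRI2	(1/R510-1/R700)*R800	y	Gitelson et al. 2006
CUR	(R675*R690)/(R683*R683)	y	Zarco-Tejada et al. 2003
RGR	R690/R550	y	Gamon & Surfus 1999
GI	R554/R677	y	Smith et al. 1995
BGI	R450/R550	y	Zarco-Tejada et al. 2005
BRI	R450/R690	y	Zarco-Tejada et al. 2005
RVSI	(R712+R752)/2-R732	n	Merton & Huntington 1999
HI	(R534-R698)/(R534+R698)-R704/2	n	Mahlein et al. 2013
CLSI	(R698-R570)/(R698+R570)-R734	n	Mahlein et al. 2013
DSWI4	R550/R680	y	Apan et al. 2004
NRI	(R570-R670)/(R570+R670)	y	Filella et al. 1995
VARI	(R550-R670)/(R550+R670-R475)	y	Gitelson et al. 2002
VIgreen	(R550-R670)/(R550+R670)	y	Gitelson et al. 2002
GLI	(2*R550-R670-R475)/(2*R550+R670+R475)	y	Louhaichi et al. 2001
MGRVI	(R550*R550-R670*R670)/(R550*R550+R670*R670)	y	Bendig et al. 2015
RGBVI	(R550*R550-R475*R670)/(R550*R550+R475*R670)	y	Bendig et al. 2015
ExG	2*R550-R670-R475	n	Woebbecke et al. 1995
ExR	1.4*R670-R550	n	Meyer & Neto 2008
ExGR	(2*R550-R670-R475)-(1.4*R670-R550)	n	Meyer & Neto 2008
CIVE	0.441*R670-0.811*R550+0.385*R475+18.787	n	Kataoka et al. 2003
GCC	R550/(R475+R550+R670)	y	Gillespie et al. 1987
CVI	(R800*R670)/(R550*R550)	y	Vincini et al. 2008
TGI	-0.5*(190*(R670-R550)-120*(R670-R480))	n	Hunt et al. 2013
WI	R900/R970	y	Penuelas et al. 1997
WBI	R970/R900	y	Penuelas et al. 1993
WINDVI	(R900/R970)/((R800-R670)/(R800+R670))	y	Penuelas et al. 1997
NWI1	(R970-R900)/(R970+R900)	y	Prasad et al. 2007
NWI2	(R970-R850)/(R970+R850)	y	Prasad et al. 2007
NWI3	(R970-R880)/(R970+R880)	y	Prasad et al. 2007
NWI4	(R970-R920)/(R970+R920)	y	Prasad et al. 2007
ACI	R530/R940	y	Van den Berg & Perkins 2005
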