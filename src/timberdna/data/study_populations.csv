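population,region,latitude,longitude,altitude_m,n_samples
SBadak,Region A,6.47,100.54,240,34
BPerangin,Region A,6.32,100.49,133,35
BEnggang,Region A,5.84,100.73,282,35
GJerai,Region A,5.75,100.44,138,35
RTelui,Region A,5.86,100.84,166,35
GInas,Region A,5.50,100.78,105,27
GBongsu,Region A,5.35,100.67,206,20
Belum,Region A,5.63,101.40,275,39
Piah,Region A,4.99,101.19,110,33
BHijau,Region A,4.87,100.87,550,22
Korbu,Region A,4.89,101.29,616,35
Bubu,Region A,4.70,100.89,289,31
Behrang,Region B,3.74,101.56,440,34
Ampang,Region B,3.16,101.78,55,40
HGombak,Region B,3.31,101.70,158,30
HLangat,Region B,3.10,101.79,343,29
SLalang,Region B,3.09,101.88,65,23
PPanjang,Region B,2.42,101.95,47,32
Berembun,Region B,2.87,102.02,410,36
Angsi,Region B,2.73,102.06,460,32
Kenaboi,Region B,3.07,102.14,458,28
Triang,Region B,2.94,102.15,202,30
Pasoh,Region B,2.99,102.32,140,39
BSenggeh,Region B,2.40,102.46,98,30
GLedang,Region B,2.34,102.62,107,30
Krau,Region B,3.76,101.86,77,20
TNegara,Region B,4.40,102.40,105,39
Terenggun,Region B,4.17,102.00,139,35
SBetis,Region B,4.76,101.77,223,34
USat,Region B,5.73,102.33,68,26
CTongkat,Region B,5.88,102.26,88,32
HTerengganu,Region B,4.97,102.95,57,32
Jengai,Region B,4.55,103.18,84,33
AGading,Region B,4.46,102.02,259,34
Tekam,Region B,3.97,102.59,78,33
Beserah,Region B,3.83,103.36,194,30
Jengka,Region B,3.74,102.58,93,34
Lentang,Region B,3.38,101.99,124,33
Lesong,Region B,2.78,103.04,92,33
ERompin,Region B,2.53,103.38,48,40
GArong,Region B,2.55,103.76,30,35
Labis,Region B,2.35,103.16,65,27
AHitam,Region B,2.05,102.77,25,35
Panti,Region B,1.79,103.94,44,31
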