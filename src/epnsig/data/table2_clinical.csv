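ID,Age (years),Sex,NanoString diagnosis,NGS fusion,Original diagnosis,Relapse months,DOD (months),ADF (months)
1,12,M,RELA+,ZFTA-RELA,EPN III,No,No,168
2,12,F,RELA+,ZFTA-RELA,EPN III,No,No,168
3,5,M,RELA+,ZFTA-RELA,EPN III,No,No,120
4,3,M,RELA+,ZFTA-RELA,EPN III,No,No,60
5,6,M,RELA+,ZFTA-RELA,EPN III,No,No,77
6,2,F,RELA+,ZFTA-RELA,EPN III,134/distant,No,168
7,11,F,RELA+,Not detected,EPN III,No,No,72
8,12,M,RELA+,ZFTA-RELA,EPN III,46/local,No,288
9,14,M,RELA+,ZFTA-RELA,EPN III,No,No,24
10,1,M,RELA+,ZFTA-RELA,PNET,22,42,-
11,7,F,YAP1+,YAP1-MAMLD1,EPN II,No,Yes,-
12,1,M,NC,ZFTA-MAML2,EPN II,No,No,156
13,17,F,NC,Not detected,EPN III,No,No,168
14,16,F,NC,Not detected,EPN II,No,No,216
15,2,M,NC,Not detected,EPN III,No,No,96
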