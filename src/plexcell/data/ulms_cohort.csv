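case_id,age,menopause,figo,tmn,size_cm,mitoses_per_10hpf,necrosis,mhc_class_i,mhc_dynamics,desmin,b7h3,axl,ido,total_cells_per_mm2,segmented_over_dapi_pct,predominant_phenotype
1,39,No,IVB,pT3aNxM1,6,20,Present,+++,induced,+,+ het,++,pos,900,31,T_ex-chronic
2,63,Yes,IVB,pT1bNxM1,16,11,Present,+++,constitutive,+,+,+/-,pos weak,1248,23,T_ex-acute
3,34,No,NA,NA,2,9,Absent,+,induced,++,++ het,++,pos,517,15,Deserted
4,36,No,IB,pT1bN0Mx,11,50,Present,+/-,constitutive,+/-,++,+++,pos,210,5,Deserted
5,55,Yes,IIIB,pT3bNxMx,20,18,Absent,+,induced,neg,+++,++ het,pos,2567,77,T_ex-acute
6,61,Yes,IB,pT1bNxMx,12,25,Focal,+,constitutive,++,++ het,+ het,pos,474,8,Deserted
7,44,No,IVB,pT1bNxM1,14,40,Present,+,constitutive,neg,+/-,NA,pos,363,6,T_ex-acute
8,40,No,IIIB,pT3bN0Mx,4,30,Present,+/-,constitutive,+,+++ het,+,pos,481,8,Deserted
9,47,No,IB,pT1bN0Mx,9,35,Focal,+++,constitutive,+,+ het,neg,pos weak,593,14,Deserted
10,62,Yes,IB,pT1bN0Mx,8,25,Focal,+++,induced,++,++/- het,+,pos weak,1780,38,T_ex-acute
11,61,Yes,IIB,pT2bNxMx,13,25,Focal,+++,constitutive,neg,+,+,pos,1644,44,Deserted
12,49,No,IB,pT1bNxMx,11,25,Focal,+ focal,induced,neg,+++,+/-,neg,2890,54,Deserted
13,59,Yes,IB,pT1bNxMx,7,13,Focal,++ het,induced,neg,++,+++,pos weak,3533,93,T_ex-acute
14,35,No,IB,pT1bNxMx,11,50,Absent,+ het,induced,+,++,++,pos,2756,33,T_ex-mixed
15,57,Yes,IIIB,pT3bN0Mx,7,20,Present,+,constitutive,+,+++ het,neg,neg,72,2,Deserted
16,49,No,IIIC,pT3bN1Mx,14,25,Present,+++,induced,neg,-,+,neg,1631,33,T_ex-chronic
17,60,Yes,IB,pT1bN0Mx,19,11,Focal,+,induced,neg,-,++,pos,984,50,T_ex-mixed
18,71,Yes,IB,pT1bN0Mx,9,35,Focal,+,constitutive,+,-,++,pos,645,13,T_ex-mixed
19,51,Yes,IIIC,pT3bN1Mx,19,60,Present,+++,constitutive,+,+/- het,++ het,neg,1296,27,T_ex-chronic
20,69,Yes,IB,pT1bNxMx,10,40,Present,+/-,induced,++,-,++,pos het,666,21,Deserted
21,34,No,IB,pT1bN0Mx,3,10,Absent,++ het,constitutive,+++,-,++,pos,502,10,Deserted
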