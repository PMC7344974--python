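situation_id,task,company,product,duration_min,n,am_ppm,gm_ppm,gsd,min_ppm,max_ppm
FRP-A,FRP lamination,A,Ship,180,8,16.49,11.78,2.39,3.77,40.04
FRP-B,FRP lamination,B,Ship,120,2,25.29,19.07,3.06,8.68,41.89
FRP-C,FRP lamination,C,Ship,60,1,3.10,3.10,,3.10,3.10
FRP-D,FRP lamination,D,Ship,180,2,25.66,25.64,1.05,24.86,26.45
FRP-E,FRP lamination,E,Ship,60,4,9.08,8.02,1.74,4.88,17.38
FRP-F,FRP lamination,F,Ship,180,15,16.44,11.81,2.30,4.25,53.60
FRP-G,FRP lamination,G,Ship,180,3,10.85,9.67,1.77,6.14,18.41
FRP-H,FRP lamination,H,Ship,180,1,32.19,32.19,,32.19,32.19
FRP-I,FRP lamination,I,Ship,180,5,27.27,15.74,4.29,1.67,45.15
FRP-J,FRP lamination,J,Ship,180,16,19.68,14.77,2.45,1.82,43.67
FRP-K,FRP lamination,K,Automotive products and repair parts,120,9,19.07,11.97,3.09,2.28,46.45
FRP-L,FRP lamination,L,Automotive products and repair parts,180,20,49.72,26.06,3.89,1.07,186.34
FRP-M,FRP lamination,M,Automotive products and repair parts,180,6,13.02,9.27,2.65,2.11,30.21
FRP-N,FRP lamination,N,Double-walled underground storage tank (UST),180,1,34.88,34.88,,34.88,34.88
FRP-O,FRP lamination,O,Double-walled underground storage tank (UST),180,4,17.93,10.27,3.54,3.52,45.90
FRP-P,FRP lamination,P,Double-walled underground storage tank (UST),180,14,17.21,11.04,2.95,1.68,36.60
FRP-Q,FRP lamination,Q,Double-walled underground storage tank (UST),180,3,12.56,11.51,1.71,6.36,17.95
FRP-R,FRP lamination,R,Double-walled underground storage tank (UST),120,4,9.89,7.66,2.66,1.80,15.00
FRP-S,FRP lamination,S,Sluice,120,10,11.16,7.59,2.56,2.31,37.51
FRP-T,FRP lamination,T,Sluice,120,4,15.98,9.76,3.06,4.10,43.52
FRP-U,FRP lamination,U,Sluice,60,1,3.12,3.12,,3.12,3.12
FRP-V,FRP lamination,V,Double-walled underground storage tank (UST),180,4,25.85,25.54,1.20,19.52,28.99
INSP-A,Inspection,A,Ship,60,1,0.07,0.07,,0.07,0.07
INSP-B,Inspection,B,Ship,60,1,0.14,0.14,,0.14,0.14
INSP-E,Inspection,E,Ship,60,1,0.95,0.95,,0.95,0.95
INSP-G,Inspection,G,Ship,60,1,0.01,0.01,,0.01,0.01
INSP-H,Inspection,H,Ship,60,1,0.32,0.32,,0.32,0.32
INSP-J,Inspection,J,Ship,60,1,0.16,0.16,,0.16,0.16
INSP-L,Inspection,L,Automotive products and repair parts,60,6,0.58,0.27,5.84,0.02,1.43
INSP-M,Inspection,M,Automotive products and repair parts,60,3,0.64,0.54,2.14,0.23,0.99
INSP-N,Inspection,N,Double-walled underground storage tank (UST),60,2,0.04,0.03,1.12,0.03,0.04
INSP-O,Inspection,O,Double-walled underground storage tank (UST),120,1,0.14,0.14,,0.14,0.14
INSP-R,Inspection,R,Double-walled underground storage tank (UST),60,2,0.46,0.46,1.02,0.45,0.46
INSP-S,Inspection,S,Sluice,60,1,1.03,1.03,,1.03,1.03
INSP-T,Inspection,T,Sluice,60,1,0.86,0.86,,0.86,0.86
INSP-V,Inspection,V,Double-walled underground storage tank (UST),60,1,0.28,0.28,,0.28,0.28
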