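situation_id,task,company,product,n,meas_gm_ppm,meas_p90_ppm,daily_average_ppm,p50_ppm,p90_ppm,score,category
FRP-A,FRP lamination,A,Ship,8,11.78,36.02,1.57,0.46,4.2,6.32,3
FRP-B,FRP lamination,B,Ship,2,19.07,79.86,10.49,4.65,42.02,7.23,3
FRP-C,FRP lamination,C,Ship,1,3.1,,9.93,8.8,79.35,7.17,3
FRP-D,FRP lamination,D,Ship,2,25.64,27.32,15.73,4.65,42.02,7.86,3
FRP-E,FRP lamination,E,Ship,4,8.02,16.25,0.85,0.76,6.82,6.25,3
FRP-F,FRP lamination,F,Ship,15,11.81,34.39,28.41,8.37,75.59,8.04,3
FRP-G,FRP lamination,G,Ship,3,9.67,20.07,15.73,4.65,42.02,7.17,3
FRP-H,FRP lamination,H,Ship,1,32.19,,28.64,8.48,76.53,8.78,3
FRP-I,FRP lamination,I,Ship,5,15.74,101.93,29.81,8.8,79.35,8.04,3
FRP-J,FRP lamination,J,Ship,16,14.77,46.55,15.73,4.65,42.02,7.35,3
FRP-K,FRP lamination,K,Automotive products and repair parts,9,11.97,50.93,20.08,8.9,80.29,8.74,3
FRP-L,FRP lamination,L,Automotive products and repair parts,20,26.06,148.93,65.03,19.17,173.02,10.57,4
FRP-M,FRP lamination,M,Automotive products and repair parts,6,9.27,32.32,15.22,4.5,40.61,7.86,3
FRP-N,FRP lamination,N,Double-walled underground storage tank (UST),1,34.88,,29.11,8.59,77.47,8.78,3
FRP-O,FRP lamination,O,Double-walled underground storage tank (UST),4,10.27,51.82,30.99,9.14,82.63,8.74,3
FRP-P,FRP lamination,P,Double-walled underground storage tank (UST),14,11.04,44.2,27.94,8.26,74.42,8.74,3
FRP-Q,FRP lamination,Q,Double-walled underground storage tank (UST),3,11.51,22.87,32.63,9.62,86.86,8.74,3
FRP-R,FRP lamination,R,Double-walled underground storage tank (UST),4,7.66,26.88,17.05,7.55,68.31,7.45,3
FRP-S,FRP lamination,S,Sluice,10,7.59,25.31,1.84,0.81,7.35,6.72,3
FRP-T,FRP lamination,T,Sluice,4,9.76,40.85,19.86,8.8,79.35,7.23,3
FRP-U,FRP lamination,U,Sluice,1,3.12,,9.19,8.14,73.48,7.17,3
FRP-V,FRP lamination,V,Double-walled underground storage tank (UST),4,25.54,32.36,1.57,0.46,4.18,7.92,3
INSP-A,Inspection,A,Ship,1,0.07,,0.01,0.01,0.1,2.93,2
INSP-B,Inspection,B,Ship,1,0.14,,0.01,0.01,0.1,3.84,2
INSP-E,Inspection,E,Ship,1,0.95,,0.02,0.02,0.17,3.84,2
INSP-G,Inspection,G,Ship,1,0.01,,0.02,0.02,0.17,4.07,2
INSP-H,Inspection,H,Ship,1,0.32,,0.23,0.21,1.86,4.76,2
INSP-J,Inspection,J,Ship,1,0.16,,0.13,0.11,1.02,3.84,2
INSP-L,Inspection,L,Automotive products and repair parts,6,0.27,2.61,0.07,0.06,0.55,4.94,3
INSP-M,Inspection,M,Automotive products and repair parts,3,0.54,1.43,0.2,0.18,1.62,4.76,2
INSP-N,Inspection,N,Double-walled underground storage tank (UST),2,0.03,0.04,0.23,0.21,1.89,4.76,2
INSP-O,Inspection,O,Double-walled underground storage tank (UST),1,0.14,,0.08,0.04,0.33,4.6,2
INSP-R,Inspection,R,Double-walled underground storage tank (UST),2,0.46,0.47,0.21,0.18,1.66,4.76,2
INSP-S,Inspection,S,Sluice,1,1.03,,0.02,0.02,0.18,3.62,2
INSP-T,Inspection,T,Sluice,1,0.86,,0.24,0.21,1.93,4.54,2
INSP-V,Inspection,V,Double-walled underground storage tank (UST),1,0.28,,0.02,0.02,0.17,3.62,2
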