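grade,n,metric,mean,sd,min,max
0,6,suv_max,1.85,0.26,1.33,2.27
0,6,smat20,0.78,0.25,0.48,1.12
0,6,smat40,0.98,0.20,0.72,1.22
0,6,smat60,1.31,0.22,0.99,1.53
1,2,suv_max,2.79,0.53,2.25,3.32
1,2,smat20,1.25,0.20,1.11,1.39
1,2,smat40,1.49,0.31,1.27,1.71
1,2,smat60,1.96,0.53,1.59,2.34
2,15,suv_max,14.05,3.07,8.60,18.10
2,15,smat20,5.98,1.45,3.69,8.44
2,15,smat40,8.14,1.98,4.86,11.31
2,15,smat60,10.23,2.65,6.05,15.40
3,5,suv_max,15.26,4.34,10.40,22.30
3,5,smat20,5.94,1.38,4.47,8.11
3,5,smat40,7.62,1.65,5.88,10.33
3,5,smat60,9.47,1.92,7.41,12.53
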