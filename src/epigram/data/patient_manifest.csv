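patient_id,n_seizures,preictal_hours,origin,electrodes,interictal_hours
1,4,4.65,F,"g,s",23.00
2,3,3.62,T,d,24.00
3,5,6.65,F,"g,s",24.00
4,5,5.51,T,"d,g,s",24.00
5,5,6.03,F,"g,s",24.00
6,3,3.31,T/O,"d,g,s",24.00
7,3,4.08,T,d,24.61
8,2,2.68,F,"g,s",23.16
9,5,6.10,T/O,"g,s",23.93
10,5,7.05,T,d,24.46
11,4,4.65,P,"g,s",24.05
12,4,5.91,T,"d,g,s",24.81
13,2,2.38,T/O,"d,s",24.00
14,4,5.41,F/T,"d,s",23.86
15,4,6.13,T,"d,s",24.00
16,5,6.53,T,"d,s",24.00
17,5,8.80,T,s,24.07
18,5,8.20,F,s,22.87
19,4,4.60,F,s,24.38
20,5,8.42,T/P,"d,g,s",25.62
21,5,7.66,T,"g,s",23.94
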