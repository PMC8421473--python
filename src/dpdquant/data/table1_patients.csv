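patient_id,sex,age_years,visual_grade,grade_ambiguous,suv_max,smat20,smat40,smat60,diagnosis
1,M,75,2,0,17.4,,,,ATTR
2,M,80,2,0,14.0,,,,ATTR
3,M,60,3,1,12.3,,,,ATTR
4,M,74,3,0,18.1,,,,ATTR
5,M,80,2,0,14.3,,,,ATTR
6,M,80,2,0,13.6,3.66,4.88,6.05,AL
7,F,71,1,0,2.25,1.11,1.27,1.59,ATTR
8,M,81,2,0,13.1,,,,ATTR
9,M,68,1,0,3.32,1.39,1.71,2.34,ATTR
10,M,84,3,0,13.2,,,,ATTR
11,M,85,2,0,11.0,,,,ATTR
12,M,74,2,0,17.6,,,,ATTR
13,F,89,3,1,22.3,,,,ATTR senile
14,M,82,2,0,15.2,,,,ATTR
15,M,88,3,0,10.4,,,,ATTR
16,M,85,2,0,18.0,,,,ATTR
17,M,89,2,0,9.2,,,,ATTR
18,M,82,2,0,18.1,,,,ATTR
19,M,83,2,0,13.6,,,,ATTR
20,M,85,2,0,16.6,,,,ATTR
21,M,79,2,0,8.6,,,,ATTR
22,M,87,2,0,10.4,,,,ATTR
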