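patient,planar,spect_noc,spect_ac,spect_acsc,spect_noc_noexcl,spect_acsc_noexcl,pet,pet_noexcl
1,2.5,2.0,1.4,0.6,4.7,2.4,1.1,4.5
2,15.0,3.2,2.2,1.1,6.4,3.5,2.7,15.5
3,6.3,3.1,2.1,1.8,3.5,1.9,,
4,10.1,7.2,5.0,4.0,11.7,7.5,,
5,8.4,3.9,1.6,1.2,6.1,3.1,0.5,1.0
6,12.0,5.0,2.7,1.7,6.2,3.9,,
7,3.7,4.7,2.9,2.3,5.0,2.4,,
8,3.2,2.6,1.9,1.6,6.3,4.7,0.9,2.7
9,2.9,2.4,1.7,0.8,8.4,4.7,1.3,8.8
10,2.6,1.2,0.9,0.4,3.6,2.3,0.6,4.1
11,2.8,2.3,1.4,0.8,4.1,1.6,,
12,2.5,2.7,1.6,0.5,5.6,2.0,,
13,4.6,2.2,1.4,0.8,3.9,2.1,,
14,3.8,1.3,1.1,0.7,2.6,1.6,0.4,1.4
15,1.4,1.1,0.9,0.5,3.3,2.0,0.9,4.4
16,9.8,1.3,1.1,0.7,2.9,2.0,,
17,5.9,4.2,2.7,1.8,6.3,3.3,,
18,9.0,7.2,4.1,2.7,13.4,7.2,,
19,4.3,3.6,2.5,2.2,17.9,12.6,,
20,3.2,1.9,1.4,1.2,2.7,1.8,,
21,11.0,6.0,4.0,3.4,7.1,4.0,,
22,4.9,3.1,2.1,1.4,3.6,1.5,0.3,0.3
23,2.1,1.4,0.3,0.7,2.1,1.3,0.4,2.2
24,2.4,1.7,1.4,0.8,5.5,4.4,,
25,15.7,10.6,7.5,6.0,13.8,8.7,,
26,2.0,3.1,2.2,1.0,6.0,2.6,1.5,3.0
27,8.0,3.5,3.2,2.5,3.8,2.5,,
28,2.1,2.0,1.2,0.6,3.6,1.7,,
29,5.9,5.6,4.1,4.1,13.1,9.1,,
30,2.1,2.8,1.7,0.6,7.0,2.5,,
31,2.8,2.4,2.1,1.6,14.1,9.6,1.0,4.7
32,13.6,5.5,3.6,2.5,7.5,4.3,,
33,4.2,1.3,0.9,0.4,2.0,1.0,0.5,1.0
34,6.0,3.0,2.0,1.5,7.5,5.0,0.6,3.1
35,5.8,4.2,2.8,1.6,5.8,3.2,1.5,3.7
36,2.9,2.6,1.9,0.8,5.9,3.3,1.2,2.4
37,2.8,2.4,1.6,1.0,2.4,1.1,0.4,0.4
38,1.2,1.6,1.3,0.7,3.9,3.0,0.4,8.9
39,3.5,1.3,0.9,0.4,2.7,1.3,0.6,1.9
40,4.4,3.8,2.6,1.4,8.7,5.4,2.8,4.4
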