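age,life_expectancy
0,86.02
1,85.21
5,81.25
10,76.27
15,71.29
20,66.35
25,61.45
30,56.57
35,51.72
40,46.88
45,42.10
50,37.44
55,32.89
60,28.41
65,23.97
70,19.51
75,15.14
80,11.01
85,7.92
90,5.37
95,3.70
100,2.50
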