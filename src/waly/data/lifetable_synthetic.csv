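age,life_expectancy
0,13.7
1,12.7264
2,11.7611
3,10.8064
4,9.86532
5,8.94137
6,8.03879
7,7.1625
8,6.31813
9,5.51183
10,4.75015
11,4.03964
12,3.38645
13,2.79583
14,2.27154
15,1.81544
16,1.42709
17,1.10377
18,0.840613
19,0.631126
20,0.467842
21,0.343
22,0.249164
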