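0 1
0 2
0 3
1 4
1 26
2 10
2 11
3 18
3 19
4 5
4 33
5 6
5 29
6 7
6 27
7 8
7 14
8 9
8 38
9 10
9 37
10 39
11 12
11 39
12 13
12 35
13 14
13 15
14 34
15 16
15 22
16 17
16 44
17 18
17 43
18 45
19 20
19 45
20 21
20 41
21 22
21 23
22 40
23 24
23 27
24 25
24 32
25 26
25 31
26 33
27 28
28 29
28 32
29 30
30 31
30 33
31 32
34 35
34 38
35 36
36 37
36 39
37 38
40 41
40 44
41 42
42 43
42 45
43 44
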