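# Synthetic 32-node schematic: three communities (1-11, 13-21, 22-32)
# joined only through connector nodes. Node 12 is overlapping (4 edges
# into each of the first two communities); nodes 16 and 24 are bridging
# (intra-community hubs with two cross-community edges each).
1	2
1	4
1	7
1	8
1	9
1	10
1	24
2	3
2	4
2	5
2	6
2	8
2	9
3	6
3	7
3	8
3	9
3	10
3	11
3	12
4	5
4	9
4	10
4	11
5	6
5	7
5	11
6	10
6	11
7	10
7	11
7	12
8	9
8	10
8	12
9	24
10	11
10	12
12	16
12	17
12	19
12	20
13	15
13	16
13	18
13	19
13	20
13	21
14	15
14	16
14	17
14	18
14	19
14	21
15	16
15	17
16	17
16	18
16	19
16	20
16	21
16	22
16	31
17	18
17	19
17	20
17	21
18	19
18	20
19	21
20	21
22	24
22	27
22	28
22	29
22	30
22	32
23	24
23	25
23	29
23	31
23	32
24	25
24	26
24	27
24	28
24	29
24	30
24	31
24	32
25	29
25	30
26	29
26	31
26	32
28	30
29	30
29	31
29	32
30	31
30	32
31	32
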