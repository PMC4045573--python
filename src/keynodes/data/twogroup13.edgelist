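# Two-group example network: two mirrored 6-node groups (1-6 and 8-13),
# gateways 6 and 8 joined directly and via the central connector node 7.
# Node 7 lies on no shortest path but carries current between the groups.
1	2
1	4
1	5
2	3
2	5
3	5
3	6
4	5
4	6
5	6
6	7
6	8
7	8
8	9
8	12
8	13
9	11
9	13
10	11
10	12
10	13
11	13
12	13
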