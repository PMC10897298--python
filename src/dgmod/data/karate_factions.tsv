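0	instructor
1	instructor
2	instructor
3	instructor
4	instructor
5	instructor
6	instructor
7	instructor
8	instructor
9	president
10	instructor
11	instructor
12	instructor
13	instructor
14	president
15	president
16	instructor
17	instructor
18	president
19	instructor
20	president
21	instructor
22	president
23	president
24	president
25	president
26	president
27	president
28	president
29	president
30	president
31	president
32	president
33	president
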