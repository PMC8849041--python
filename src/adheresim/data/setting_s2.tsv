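scenario	arm	alpha0	alpha1	alpha2	alpha3	alpha4	nonadherence	theta0	theta1	theta2	theta3	theta4	theta5
1	Z=1	0.55	0.25	0.02	0.04	0.05	11	0.35	-0.2	0.02	0.05	0.05	0
1	Z=0	0.02	0.25	0.02	0.04	0.05	11	0.35	-0.2	0.02	0.05	0.05	0
2	Z=1	0.46	0.25	0.02	0.04	0.05	20	0.35	-0.2	0.02	0.05	0.05	0
2	Z=0	0.12	0.25	0.02	0.04	0.05	21	0.35	-0.2	0.02	0.05	0.05	0
3	Z=1	0.25	0.25	0.02	0.04	0.05	41	0.35	-0.2	0.02	0.05	0.05	0
3	Z=0	0.32	0.25	0.02	0.04	0.05	41	0.35	-0.2	0.02	0.05	0.05	0
4	Z=1	0.05	0.25	0.02	0.04	0.05	61	0.35	-0.2	0.02	0.05	0.05	0
4	Z=0	0.52	0.25	0.02	0.04	0.05	61	0.35	-0.2	0.02	0.05	0.05	0
5	Z=1	-0.15	0.25	0.02	0.04	0.05	81	0.35	-0.2	0.02	0.05	0.05	0
5	Z=0	0.7	0.25	0.02	0.04	0.05	80	0.35	-0.2	0.02	0.05	0.05	0
6	Z=1	-0.25	0.25	0.02	0.04	0.05	91	0.35	-0.2	0.02	0.05	0.05	0
6	Z=0	0.8	0.25	0.02	0.04	0.05	89	0.35	-0.2	0.02	0.05	0.05	0
7	Z=1	0.55	0.25	0.02	0.04	0.05	11	0.2	-0.2	0.02	0.05	0.4	0
7	Z=0	0.02	0.25	0.02	0.04	0.05	11	0.2	-0.2	0.02	0.05	0.4	0
8	Z=1	0.46	0.25	0.02	0.04	0.05	20	0.2	-0.2	0.02	0.05	0.4	0
8	Z=0	0.12	0.25	0.02	0.04	0.05	21	0.2	-0.2	0.02	0.05	0.4	0
9	Z=1	0.25	0.25	0.02	0.04	0.05	41	0.2	-0.2	0.02	0.05	0.4	0
9	Z=0	0.32	0.25	0.02	0.04	0.05	41	0.2	-0.2	0.02	0.05	0.4	0
10	Z=1	0.05	0.25	0.02	0.04	0.05	61	0.2	-0.2	0.02	0.05	0.4	0
10	Z=0	0.52	0.25	0.02	0.04	0.05	61	0.2	-0.2	0.02	0.05	0.4	0
11	Z=1	-0.15	0.25	0.02	0.04	0.05	81	0.2	-0.2	0.02	0.05	0.4	0
11	Z=0	0.7	0.25	0.02	0.04	0.05	80	0.2	-0.2	0.02	0.05	0.4	0
12	Z=1	-0.25	0.25	0.02	0.04	0.05	91	0.2	-0.2	0.02	0.05	0.4	0
12	Z=0	0.8	0.25	0.02	0.04	0.05	89	0.2	-0.2	0.02	0.05	0.4	0
13	Z=1	0.55	0.25	0.02	0.04	0.05	11	0.3	-0.05	0.02	0.05	0.05	0
13	Z=0	0.02	0.25	0.02	0.04	0.05	11	0.3	-0.05	0.02	0.05	0.05	0
14	Z=1	0.46	0.25	0.02	0.04	0.05	20	0.3	-0.05	0.02	0.05	0.05	0
14	Z=0	0.12	0.25	0.02	0.04	0.05	21	0.3	-0.05	0.02	0.05	0.05	0
15	Z=1	0.25	0.25	0.02	0.04	0.05	41	0.3	-0.05	0.02	0.05	0.05	0
15	Z=0	0.32	0.25	0.02	0.04	0.05	41	0.3	-0.05	0.02	0.05	0.05	0
16	Z=1	0.05	0.25	0.02	0.04	0.05	61	0.3	-0.05	0.02	0.05	0.05	0
16	Z=0	0.52	0.25	0.02	0.04	0.05	61	0.3	-0.05	0.02	0.05	0.05	0
17	Z=1	-0.15	0.25	0.02	0.04	0.05	81	0.3	-0.05	0.02	0.05	0.05	0
17	Z=0	0.7	0.25	0.02	0.04	0.05	80	0.3	-0.05	0.02	0.05	0.05	0
18	Z=1	-0.25	0.25	0.02	0.04	0.05	91	0.3	-0.05	0.02	0.05	0.05	0
18	Z=0	0.8	0.25	0.02	0.04	0.05	89	0.3	-0.05	0.02	0.05	0.05	0
19	Z=1	0.55	0.25	0.02	0.04	0.05	11	0.15	-0.05	0.02	0.05	0.4	0
19	Z=0	0.02	0.25	0.02	0.04	0.05	11	0.15	-0.05	0.02	0.05	0.4	0
20	Z=1	0.46	0.25	0.02	0.04	0.05	20	0.15	-0.05	0.02	0.05	0.4	0
20	Z=0	0.12	0.25	0.02	0.04	0.05	21	0.15	-0.05	0.02	0.05	0.4	0
21	Z=1	0.25	0.25	0.02	0.04	0.05	41	0.15	-0.05	0.02	0.05	0.4	0
21	Z=0	0.32	0.25	0.02	0.04	0.05	41	0.15	-0.05	0.02	0.05	0.4	0
22	Z=1	0.05	0.25	0.02	0.04	0.05	61	0.15	-0.05	0.02	0.05	0.4	0
22	Z=0	0.52	0.25	0.02	0.04	0.05	61	0.15	-0.05	0.02	0.05	0.4	0
23	Z=1	-0.15	0.25	0.02	0.04	0.05	81	0.15	-0.05	0.02	0.05	0.4	0
23	Z=0	0.7	0.25	0.02	0.04	0.05	80	0.15	-0.05	0.02	0.05	0.4	0
24	Z=1	-0.25	0.25	0.02	0.04	0.05	91	0.15	-0.05	0.02	0.05	0.4	0
24	Z=0	0.8	0.25	0.02	0.04	0.05	89	0.15	-0.05	0.02	0.05	0.4	0
25	Z=1	0.55	0.25	0.02	0.04	0.05	11	0.28	0	0.02	0.05	0.05	0
25	Z=0	0.02	0.25	0.02	0.04	0.05	11	0.28	0	0.02	0.05	0.05	0
26	Z=1	0.46	0.25	0.02	0.04	0.05	20	0.28	0	0.02	0.05	0.05	0
26	Z=0	0.12	0.25	0.02	0.04	0.05	21	0.28	0	0.02	0.05	0.05	0
27	Z=1	0.25	0.25	0.02	0.04	0.05	41	0.28	0	0.02	0.05	0.05	0
27	Z=0	0.32	0.25	0.02	0.04	0.05	41	0.28	0	0.02	0.05	0.05	0
28	Z=1	0.05	0.25	0.02	0.04	0.05	61	0.28	0	0.02	0.05	0.05	0
28	Z=0	0.52	0.25	0.02	0.04	0.05	61	0.28	0	0.02	0.05	0.05	0
29	Z=1	-0.15	0.25	0.02	0.04	0.05	81	0.28	0	0.02	0.05	0.05	0
29	Z=0	0.7	0.25	0.02	0.04	0.05	80	0.28	0	0.02	0.05	0.05	0
30	Z=1	-0.25	0.25	0.02	0.04	0.05	91	0.28	0	0.02	0.05	0.05	0
30	Z=0	0.8	0.25	0.02	0.04	0.05	89	0.28	0	0.02	0.05	0.05	0
31	Z=1	0.55	0.25	0.02	0.04	0.05	11	0.13	0	0.02	0.05	0.4	0
31	Z=0	0.02	0.25	0.02	0.04	0.05	11	0.13	0	0.02	0.05	0.4	0
32	Z=1	0.46	0.25	0.02	0.04	0.05	20	0.13	0	0.02	0.05	0.4	0
32	Z=0	0.12	0.25	0.02	0.04	0.05	21	0.13	0	0.02	0.05	0.4	0
33	Z=1	0.25	0.25	0.02	0.04	0.05	41	0.13	0	0.02	0.05	0.4	0
33	Z=0	0.32	0.25	0.02	0.04	0.05	41	0.13	0	0.02	0.05	0.4	0
34	Z=1	0.05	0.25	0.02	0.04	0.05	61	0.13	0	0.02	0.05	0.4	0
34	Z=0	0.52	0.25	0.02	0.04	0.05	61	0.13	0	0.02	0.05	0.4	0
35	Z=1	-0.15	0.25	0.02	0.04	0.05	81	0.13	0	0.02	0.05	0.4	0
35	Z=0	0.7	0.25	0.02	0.04	0.05	80	0.13	0	0.02	0.05	0.4	0
36	Z=1	-0.25	0.25	0.02	0.04	0.05	91	0.13	0	0.02	0.05	0.4	0
36	Z=0	0.8	0.25	0.02	0.04	0.05	89	0.13	0	0.02	0.05	0.4	0
37	Z=1	0.55	0.25	0.02	0.04	0.05	11	0.25	0.05	0.02	0.05	0.05	0
37	Z=0	0.02	0.25	0.02	0.04	0.05	11	0.25	0.05	0.02	0.05	0.05	0
38	Z=1	0.46	0.25	0.02	0.04	0.05	20	0.25	0.05	0.02	0.05	0.05	0
38	Z=0	0.12	0.25	0.02	0.04	0.05	21	0.25	0.05	0.02	0.05	0.05	0
39	Z=1	0.25	0.25	0.02	0.04	0.05	41	0.25	0.05	0.02	0.05	0.05	0
39	Z=0	0.32	0.25	0.02	0.04	0.05	41	0.25	0.05	0.02	0.05	0.05	0
40	Z=1	0.05	0.25	0.02	0.04	0.05	61	0.25	0.05	0.02	0.05	0.05	0
40	Z=0	0.52	0.25	0.02	0.04	0.05	61	0.25	0.05	0.02	0.05	0.05	0
41	Z=1	-0.15	0.25	0.02	0.04	0.05	81	0.25	0.05	0.02	0.05	0.05	0
41	Z=0	0.7	0.25	0.02	0.04	0.05	80	0.25	0.05	0.02	0.05	0.05	0
42	Z=1	-0.25	0.25	0.02	0.04	0.05	91	0.25	0.05	0.02	0.05	0.05	0
42	Z=0	0.8	0.25	0.02	0.04	0.05	89	0.25	0.05	0.02	0.05	0.05	0
43	Z=1	0.55	0.25	0.02	0.04	0.05	11	0.1	0.05	0.02	0.05	0.4	0
43	Z=0	0.02	0.25	0.02	0.04	0.05	11	0.1	0.05	0.02	0.05	0.4	0
44	Z=1	0.46	0.25	0.02	0.04	0.05	20	0.1	0.05	0.02	0.05	0.4	0
44	Z=0	0.12	0.25	0.02	0.04	0.05	21	0.1	0.05	0.02	0.05	0.4	0
45	Z=1	0.25	0.25	0.02	0.04	0.05	41	0.1	0.05	0.02	0.05	0.4	0
45	Z=0	0.32	0.25	0.02	0.04	0.05	41	0.1	0.05	0.02	0.05	0.4	0
46	Z=1	0.05	0.25	0.02	0.04	0.05	61	0.1	0.05	0.02	0.05	0.4	0
46	Z=0	0.52	0.25	0.02	0.04	0.05	61	0.1	0.05	0.02	0.05	0.4	0
47	Z=1	-0.15	0.25	0.02	0.04	0.05	81	0.1	0.05	0.02	0.05	0.4	0
47	Z=0	0.7	0.25	0.02	0.04	0.05	80	0.1	0.05	0.02	0.05	0.4	0
48	Z=1	-0.25	0.25	0.02	0.04	0.05	91	0.1	0.05	0.02	0.05	0.4	0
48	Z=0	0.8	0.25	0.02	0.04	0.05	89	0.1	0.05	0.02	0.05	0.4	0
49	Z=1	0.55	0.25	0.02	0.04	0.05	11	0.2	0.2	0.02	0.05	0.05	0
49	Z=0	0.02	0.25	0.02	0.04	0.05	11	0.2	0.2	0.02	0.05	0.05	0
50	Z=1	0.46	0.25	0.02	0.04	0.05	20	0.2	0.2	0.02	0.05	0.05	0
50	Z=0	0.12	0.25	0.02	0.04	0.05	21	0.2	0.2	0.02	0.05	0.05	0
51	Z=1	0.25	0.25	0.02	0.04	0.05	41	0.2	0.2	0.02	0.05	0.05	0
51	Z=0	0.32	0.25	0.02	0.04	0.05	41	0.2	0.2	0.02	0.05	0.05	0
52	Z=1	0.05	0.25	0.02	0.04	0.05	61	0.2	0.2	0.02	0.05	0.05	0
52	Z=0	0.52	0.25	0.02	0.04	0.05	61	0.2	0.2	0.02	0.05	0.05	0
53	Z=1	-0.15	0.25	0.02	0.04	0.05	81	0.2	0.2	0.02	0.05	0.05	0
53	Z=0	0.7	0.25	0.02	0.04	0.05	80	0.2	0.2	0.02	0.05	0.05	0
54	Z=1	-0.25	0.25	0.02	0.04	0.05	91	0.2	0.2	0.02	0.05	0.05	0
54	Z=0	0.8	0.25	0.02	0.04	0.05	89	0.2	0.2	0.02	0.05	0.05	0
55	Z=1	0.55	0.25	0.02	0.04	0.05	11	0.02	0.2	0.02	0.05	0.4	0
55	Z=0	0.02	0.25	0.02	0.04	0.05	11	0.02	0.2	0.02	0.05	0.4	0
56	Z=1	0.46	0.25	0.02	0.04	0.05	20	0.02	0.2	0.02	0.05	0.4	0
56	Z=0	0.12	0.25	0.02	0.04	0.05	21	0.02	0.2	0.02	0.05	0.4	0
57	Z=1	0.25	0.25	0.02	0.04	0.05	41	0.02	0.2	0.02	0.05	0.4	0
57	Z=0	0.32	0.25	0.02	0.04	0.05	41	0.02	0.2	0.02	0.05	0.4	0
58	Z=1	0.05	0.25	0.02	0.04	0.05	61	0.02	0.2	0.02	0.05	0.4	0
58	Z=0	0.52	0.25	0.02	0.04	0.05	61	0.02	0.2	0.02	0.05	0.4	0
59	Z=1	-0.15	0.25	0.02	0.04	0.05	81	0.02	0.2	0.02	0.05	0.4	0
59	Z=0	0.7	0.25	0.02	0.04	0.05	80	0.02	0.2	0.02	0.05	0.4	0
60	Z=1	-0.25	0.25	0.02	0.04	0.05	91	0.02	0.2	0.02	0.05	0.4	0
60	Z=0	0.8	0.25	0.02	0.04	0.05	89	0.02	0.2	0.02	0.05	0.4	0
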