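scenario	arm	alpha0	alpha1	alpha2	alpha3	alpha4	nonadherence	theta0	theta1	theta2	theta3	theta4	theta5
1	Z=1	0.86	0	0.01	0.04	0	10	0.2	0	0.03	0.1	0.05	0.05
1	Z=0	0.06	0	0.01	0.04	0	10	0.2	0	0.03	0.1	0.05	0.05
2	Z=1	0.76	0	0.01	0.04	0	20	0.2	0	0.03	0.1	0.05	0.05
2	Z=0	0.16	0	0.01	0.04	0	20	0.2	0	0.03	0.1	0.05	0.05
3	Z=1	0.56	0	0.01	0.04	0	41	0.2	0	0.03	0.1	0.05	0.05
3	Z=0	0.36	0	0.01	0.04	0	40	0.2	0	0.03	0.1	0.05	0.05
4	Z=1	0.36	0	0.01	0.04	0	60	0.2	0	0.03	0.1	0.05	0.05
4	Z=0	0.57	0	0.01	0.04	0	60	0.2	0	0.03	0.1	0.05	0.05
5	Z=1	0.16	0	0.01	0.04	0	80	0.2	0	0.03	0.1	0.05	0.05
5	Z=0	0.77	0	0.01	0.04	0	80	0.2	0	0.03	0.1	0.05	0.05
6	Z=1	0.06	0	0.01	0.04	0	90	0.2	0	0.03	0.1	0.05	0.05
6	Z=0	0.86	0	0.01	0.04	0	90	0.2	0	0.03	0.1	0.05	0.05
7	Z=1	0.86	0	0.01	0.04	0	10	0.1	0	0.03	0.1	0.05	0.2
7	Z=0	0.06	0	0.01	0.04	0	10	0.1	0	0.03	0.1	0.05	0.2
8	Z=1	0.76	0	0.01	0.04	0	20	0.1	0	0.03	0.1	0.05	0.2
8	Z=0	0.16	0	0.01	0.04	0	20	0.1	0	0.03	0.1	0.05	0.2
9	Z=1	0.56	0	0.01	0.04	0	41	0.1	0	0.03	0.1	0.05	0.2
9	Z=0	0.36	0	0.01	0.04	0	40	0.1	0	0.03	0.1	0.05	0.2
10	Z=1	0.36	0	0.01	0.04	0	60	0.1	0	0.03	0.1	0.05	0.2
10	Z=0	0.57	0	0.01	0.04	0	60	0.1	0	0.03	0.1	0.05	0.2
11	Z=1	0.16	0	0.01	0.04	0	80	0.1	0	0.03	0.1	0.05	0.2
11	Z=0	0.77	0	0.01	0.04	0	80	0.1	0	0.03	0.1	0.05	0.2
12	Z=1	0.06	0	0.01	0.04	0	90	0.1	0	0.03	0.1	0.05	0.2
12	Z=0	0.86	0	0.01	0.04	0	90	0.1	0	0.03	0.1	0.05	0.2
13	Z=1	0.86	0	0.01	0.04	0	10	0.2	0.2	0.03	0.1	0.05	0.05
13	Z=0	0.06	0	0.01	0.04	0	10	0.2	0.2	0.03	0.1	0.05	0.05
14	Z=1	0.76	0	0.01	0.04	0	20	0.2	0.2	0.03	0.1	0.05	0.05
14	Z=0	0.16	0	0.01	0.04	0	20	0.2	0.2	0.03	0.1	0.05	0.05
15	Z=1	0.56	0	0.01	0.04	0	41	0.2	0.2	0.03	0.1	0.05	0.05
15	Z=0	0.36	0	0.01	0.04	0	40	0.2	0.2	0.03	0.1	0.05	0.05
16	Z=1	0.36	0	0.01	0.04	0	60	0.2	0.2	0.03	0.1	0.05	0.05
16	Z=0	0.57	0	0.01	0.04	0	60	0.2	0.2	0.03	0.1	0.05	0.05
17	Z=1	0.16	0	0.01	0.04	0	80	0.2	0.2	0.03	0.1	0.05	0.05
17	Z=0	0.77	0	0.01	0.04	0	80	0.2	0.2	0.03	0.1	0.05	0.05
18	Z=1	0.06	0	0.01	0.04	0	90	0.2	0.2	0.03	0.1	0.05	0.05
18	Z=0	0.86	0	0.01	0.04	0	90	0.2	0.2	0.03	0.1	0.05	0.05
19	Z=1	0.86	0	0.01	0.04	0	10	0.1	0.2	0.03	0.1	0.05	0.2
19	Z=0	0.06	0	0.01	0.04	0	10	0.1	0.2	0.03	0.1	0.05	0.2
20	Z=1	0.76	0	0.01	0.04	0	20	0.1	0.2	0.03	0.1	0.05	0.2
20	Z=0	0.16	0	0.01	0.04	0	20	0.1	0.2	0.03	0.1	0.05	0.2
21	Z=1	0.56	0	0.01	0.04	0	41	0.1	0.2	0.03	0.1	0.05	0.2
21	Z=0	0.36	0	0.01	0.04	0	40	0.1	0.2	0.03	0.1	0.05	0.2
22	Z=1	0.36	0	0.01	0.04	0	60	0.1	0.2	0.03	0.1	0.05	0.2
22	Z=0	0.57	0	0.01	0.04	0	60	0.1	0.2	0.03	0.1	0.05	0.2
23	Z=1	0.16	0	0.01	0.04	0	80	0.1	0.2	0.03	0.1	0.05	0.2
23	Z=0	0.77	0	0.01	0.04	0	80	0.1	0.2	0.03	0.1	0.05	0.2
24	Z=1	0.06	0	0.01	0.04	0	90	0.1	0.2	0.03	0.1	0.05	0.2
24	Z=0	0.86	0	0.01	0.04	0	90	0.1	0.2	0.03	0.1	0.05	0.2
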