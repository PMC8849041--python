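scenario	arm	alpha0	alpha1	alpha2	alpha3	alpha4	nonadherence	theta0	theta1	theta2	theta3	theta4	theta5
1	Z=1	0.72	0.6	0.4	0.35	0	10	-1	0	0	0	0.5	0
1	Z=0	-4.06	0.6	0.4	0.35	0	10	-1	0	0	0	0.5	0
2	Z=1	-0.23	0.6	0.4	0.35	0	20	-1	0	0	0	0.5	0
2	Z=0	-3.14	0.6	0.4	0.35	0	20	-1	0	0	0	0.5	0
3	Z=1	-1.47	0.6	0.4	0.35	0	40	-1	0	0	0	0.5	0
3	Z=0	-1.92	0.6	0.4	0.35	0	40	-1	0	0	0	0.5	0
4	Z=1	-2.52	0.6	0.4	0.35	0	60	-1	0	0	0	0.5	0
4	Z=0	-0.85	0.6	0.4	0.35	0	60	-1	0	0	0	0.5	0
5	Z=1	-3.76	0.6	0.4	0.35	0	80	-1	0	0	0	0.5	0
5	Z=0	0.39	0.6	0.4	0.35	0	80	-1	0	0	0	0.5	0
6	Z=1	-4.72	0.6	0.4	0.35	0	90	-1	0	0	0	0.5	0
6	Z=0	1.35	0.6	0.4	0.35	0	90	-1	0	0	0	0.5	0
7	Z=1	0.72	0.6	0.4	0.35	0	10	-5.5	0	0	0	8	0
7	Z=0	-4.06	0.6	0.4	0.35	0	10	-5.5	0	0	0	8	0
8	Z=1	-0.23	0.6	0.4	0.35	0	20	-5.5	0	0	0	8	0
8	Z=0	-3.14	0.6	0.4	0.35	0	20	-5.5	0	0	0	8	0
9	Z=1	-1.47	0.6	0.4	0.35	0	40	-5.5	0	0	0	8	0
9	Z=0	-1.92	0.6	0.4	0.35	0	40	-5.5	0	0	0	8	0
10	Z=1	-2.52	0.6	0.4	0.35	0	60	-5.5	0	0	0	8	0
10	Z=0	-0.85	0.6	0.4	0.35	0	60	-5.5	0	0	0	8	0
11	Z=1	-3.76	0.6	0.4	0.35	0	80	-5.5	0	0	0	8	0
11	Z=0	0.39	0.6	0.4	0.35	0	80	-5.5	0	0	0	8	0
12	Z=1	-4.72	0.6	0.4	0.35	0	90	-5.5	0	0	0	8	0
12	Z=0	1.35	0.6	0.4	0.35	0	90	-5.5	0	0	0	8	0
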