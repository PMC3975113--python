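pos	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
background	0.078078	0.019019	0.054054	0.063063	0.039039	0.074074	0.022022	0.051051	0.057057	0.091091	0.022022	0.045045	0.052052	0.043043	0.051051	0.071071	0.058058	0.064064	0.013013	0.032032
1	0.023423	0.005706	0.016216	0.018919	0.011712	0.022222	0.006607	0.015315	0.017117	0.727327	0.006607	0.013514	0.015616	0.012913	0.015315	0.021321	0.017417	0.019219	0.003904	0.009610
2	0.078078	0.019019	0.054054	0.063063	0.039039	0.074074	0.022022	0.051051	0.057057	0.091091	0.022022	0.045045	0.052052	0.043043	0.051051	0.071071	0.058058	0.064064	0.013013	0.032032
3	0.078078	0.019019	0.054054	0.063063	0.039039	0.074074	0.022022	0.051051	0.057057	0.091091	0.022022	0.045045	0.052052	0.043043	0.051051	0.071071	0.058058	0.064064	0.013013	0.032032
4	0.023423	0.005706	0.016216	0.018919	0.011712	0.022222	0.006607	0.015315	0.017117	0.727327	0.006607	0.013514	0.015616	0.012913	0.015315	0.021321	0.017417	0.019219	0.003904	0.009610
5	0.078078	0.019019	0.054054	0.063063	0.039039	0.074074	0.022022	0.051051	0.057057	0.091091	0.022022	0.045045	0.052052	0.043043	0.051051	0.071071	0.058058	0.064064	0.013013	0.032032
6	0.078078	0.019019	0.054054	0.063063	0.039039	0.074074	0.022022	0.051051	0.057057	0.091091	0.022022	0.045045	0.052052	0.043043	0.051051	0.071071	0.058058	0.064064	0.013013	0.032032
7	0.023423	0.005706	0.016216	0.018919	0.011712	0.022222	0.006607	0.015315	0.017117	0.727327	0.006607	0.013514	0.015616	0.012913	0.015315	0.021321	0.017417	0.019219	0.003904	0.009610
8	0.078078	0.019019	0.054054	0.063063	0.039039	0.074074	0.022022	0.051051	0.057057	0.091091	0.022022	0.045045	0.052052	0.043043	0.051051	0.071071	0.058058	0.064064	0.013013	0.032032
9	0.023423	0.005706	0.016216	0.018919	0.011712	0.022222	0.006607	0.015315	0.017117	0.727327	0.006607	0.013514	0.015616	0.012913	0.015315	0.021321	0.017417	0.019219	0.003904	0.009610
10	0.078078	0.019019	0.054054	0.063063	0.039039	0.074074	0.022022	0.051051	0.057057	0.091091	0.022022	0.045045	0.052052	0.043043	0.051051	0.071071	0.058058	0.064064	0.013013	0.032032
11	0.078078	0.019019	0.054054	0.063063	0.039039	0.074074	0.022022	0.051051	0.057057	0.091091	0.022022	0.045045	0.052052	0.043043	0.051051	0.071071	0.058058	0.064064	0.013013	0.032032
12	0.023423	0.005706	0.016216	0.018919	0.011712	0.022222	0.006607	0.015315	0.017117	0.027327	0.006607	0.713514	0.015616	0.012913	0.015315	0.021321	0.017417	0.019219	0.003904	0.009610
13	0.078078	0.019019	0.054054	0.063063	0.039039	0.074074	0.022022	0.051051	0.057057	0.091091	0.022022	0.045045	0.052052	0.043043	0.051051	0.071071	0.058058	0.064064	0.013013	0.032032
14	0.023423	0.005706	0.016216	0.018919	0.011712	0.022222	0.006607	0.015315	0.017117	0.727327	0.006607	0.013514	0.015616	0.012913	0.015315	0.021321	0.017417	0.019219	0.003904	0.009610
15	0.023423	0.005706	0.016216	0.018919	0.011712	0.022222	0.006607	0.015315	0.017117	0.027327	0.006607	0.013514	0.015616	0.012913	0.015315	0.721321	0.017417	0.019219	0.003904	0.009610
16	0.023423	0.005706	0.016216	0.018919	0.011712	0.722222	0.006607	0.015315	0.017117	0.027327	0.006607	0.013514	0.015616	0.012913	0.015315	0.021321	0.017417	0.019219	0.003904	0.009610
17	0.078078	0.019019	0.054054	0.063063	0.039039	0.074074	0.022022	0.051051	0.057057	0.091091	0.022022	0.045045	0.052052	0.043043	0.051051	0.071071	0.058058	0.064064	0.013013	0.032032
18	0.023423	0.005706	0.016216	0.018919	0.011712	0.022222	0.006607	0.715315	0.017117	0.027327	0.006607	0.013514	0.015616	0.012913	0.015315	0.021321	0.017417	0.019219	0.003904	0.009610
19	0.023423	0.005706	0.016216	0.018919	0.011712	0.022222	0.006607	0.015315	0.017117	0.027327	0.006607	0.013514	0.715616	0.012913	0.015315	0.021321	0.017417	0.019219	0.003904	0.009610
20	0.078078	0.019019	0.054054	0.063063	0.039039	0.074074	0.022022	0.051051	0.057057	0.091091	0.022022	0.045045	0.052052	0.043043	0.051051	0.071071	0.058058	0.064064	0.013013	0.032032
21	0.078078	0.019019	0.054054	0.063063	0.039039	0.074074	0.022022	0.051051	0.057057	0.091091	0.022022	0.045045	0.052052	0.043043	0.051051	0.071071	0.058058	0.064064	0.013013	0.032032
22	0.023423	0.005706	0.016216	0.018919	0.011712	0.022222	0.006607	0.015315	0.017117	0.727327	0.006607	0.013514	0.015616	0.012913	0.015315	0.021321	0.017417	0.019219	0.003904	0.009610
23	0.023423	0.005706	0.016216	0.018919	0.011712	0.722222	0.006607	0.015315	0.017117	0.027327	0.006607	0.013514	0.015616	0.012913	0.015315	0.021321	0.017417	0.019219	0.003904	0.009610
24	0.078078	0.019019	0.054054	0.063063	0.039039	0.074074	0.022022	0.051051	0.057057	0.091091	0.022022	0.045045	0.052052	0.043043	0.051051	0.071071	0.058058	0.064064	0.013013	0.032032
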