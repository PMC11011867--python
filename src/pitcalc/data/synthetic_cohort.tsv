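# Synthetic 13-tumor cohort: generator parameters for the analysis drivers.
# Spontaneous-activity fractions and every printed category percentage are
# anchored to the per-tumor values reported for this cohort; the mono/multi
# splits and stimulus weights not reported anywhere are invented, consistent
# with the qualitative descriptions (overwhelmingly responsive vs
# non-responsive, predominant secretagogue). This is a synthetic stand-in,
# not measured data.
tumor_id	frac_spontaneous	frac_non	frac_mono	frac_multi	w_CRH	w_GHRH	w_GnRH	w_TRH	w_TRH_DA
1	0.156	0.560	0.260	0.180	0.05	0.50	0.20	0.20	0.05
2	0.574	0.270	0.159	0.571	0.10	0.10	0.20	0.45	0.15
3	0.028	0.760	0.140	0.100	0.20	0.20	0.20	0.20	0.20
4	0.000	0.979	0.0105	0.0105	0.20	0.20	0.20	0.20	0.20
5	0.117	0.400	0.200	0.400	0.15	0.25	0.20	0.30	0.10
6	0.052	0.180	0.300	0.520	0.10	0.15	0.40	0.25	0.10
7	0.000	0.978	0.012	0.010	0.20	0.20	0.20	0.20	0.20
8	0.000	0.0317	0.9661	0.0022	0.00	0.00	0.00	0.00	1.00
9	0.000	0.750	0.150	0.100	0.15	0.20	0.25	0.25	0.15
10	0.064	0.617	0.253	0.130	0.10	0.15	0.40	0.25	0.10
11	0.000	0.869	0.081	0.050	0.20	0.20	0.20	0.20	0.20
12	0.348	0.350	0.250	0.400	0.10	0.15	0.40	0.25	0.10
13	0.323	0.300	0.300	0.400	0.22	0.22	0.12	0.22	0.22
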