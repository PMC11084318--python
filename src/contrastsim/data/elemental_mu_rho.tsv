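# Elemental mass attenuation coefficients (total, with coherent scattering).
# Transcribed from the public NIST XCOM tabulation; values are anchor points for
# log-log linear interpolation (photoelectric absorption is a power law between
# absorption edges, so sparse anchors suffice to ~1%).
# Duplicated energies mark absorption edges; `side` disambiguates them.
# Below 10 keV the curves are smooth extensions for beam-filtration use only;
# iodine L-edge fine structure (~4.6-5.2 keV) is deliberately smoothed out.
# columns: element  energy_keV  mu_rho_cm2_per_g  side
element	energy_keV	mu_rho_cm2_per_g	side
H	5	0.4204	-
H	8	0.3914	-
H	10	0.3854	-
H	15	0.3764	-
H	20	0.3695	-
H	30	0.3570	-
H	40	0.3458	-
H	50	0.3355	-
H	60	0.3260	-
H	80	0.3091	-
H	100	0.2944	-
H	150	0.2651	-
C	5	18.3	-
C	8	4.54	-
C	10	2.373	-
C	15	0.8071	-
C	20	0.4420	-
C	30	0.2562	-
C	40	0.2076	-
C	50	0.1871	-
C	60	0.1753	-
C	80	0.1610	-
C	100	0.1514	-
C	150	0.1347	-
N	5	29.5	-
N	8	7.54	-
N	10	3.879	-
N	15	1.236	-
N	20	0.6178	-
N	30	0.3066	-
N	40	0.2288	-
N	50	0.1980	-
N	60	0.1817	-
N	80	0.1639	-
N	100	0.1529	-
N	150	0.1353	-
O	5	45.8	-
O	8	11.6	-
O	10	5.952	-
O	15	1.836	-
O	20	0.8651	-
O	30	0.3779	-
O	40	0.2585	-
O	50	0.2132	-
O	60	0.1907	-
O	80	0.1678	-
O	100	0.1551	-
O	150	0.1361	-
Na	5	121.0	-
Na	8	30.7	-
Na	10	15.76	-
Na	15	5.010	-
Na	20	2.219	-
Na	30	0.7197	-
Na	40	0.3969	-
Na	50	0.2804	-
Na	60	0.2268	-
Na	80	0.1796	-
Na	100	0.1585	-
Na	150	0.1335	-
Al	5	193.4	-
Al	8	50.33	-
Al	10	26.23	-
Al	15	7.955	-
Al	20	3.441	-
Al	30	1.128	-
Al	40	0.5685	-
Al	50	0.3681	-
Al	60	0.2778	-
Al	80	0.2018	-
Al	100	0.1704	-
Al	150	0.1378	-
Rh	5	132.0	-
Rh	8	39.6	-
Rh	10	22.30	-
Rh	15	7.700	-
Rh	20	3.800	-
Rh	23.2199	2.680	below
Rh	23.2199	13.60	above
Rh	25	11.10	-
Rh	30	6.810	-
Rh	35	4.500	-
Rh	40	3.180	-
Rh	50	1.800	-
Rh	60	1.170	-
Rh	80	0.6200	-
Rh	100	0.4100	-
Rh	150	0.2400	-
I	5	228.0	-
I	6	142.0	-
I	8	65.6	-
I	10	36.30	-
I	15	12.90	-
I	20	6.170	-
I	25	3.580	-
I	30	2.220	-
I	33.1694	1.730	below
I	33.1694	8.810	above
I	35	7.660	-
I	40	5.300	-
I	50	2.930	-
I	60	1.830	-
I	80	0.9060	-
I	100	0.5520	-
I	150	0.2660	-
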