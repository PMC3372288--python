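# MaxQ percentiles of the dominant periodicity-spectrum peak in Bernoulli
# random sequences, by A-tract method and spacing-range width (s_max - s_min).
# Calibrated from 20,500 simulated chromosomes (20 per chromosome length/
# composition over 1,025 prokaryotic chromosomes).
method	delta	p99	p95	p50
AT	40	3.07	2.57	1.80
AT	70	3.15	2.71	1.99
AT	100	3.18	2.79	2.10
AT	150	3.26	2.89	2.23
AT	200	3.32	2.96	2.31
A2T2	40	2.98	2.52	1.80
A2T2	70	3.08	2.66	1.98
A2T2	100	3.17	2.77	2.09
A2T2	150	3.26	2.90	2.23
A2T2	200	3.36	2.98	2.32
A3T3	40	2.89	2.50	1.80
A3T3	70	3.05	2.65	1.99
A3T3	100	3.17	2.77	2.11
A3T3	150	3.28	2.90	2.24
A3T3	200	3.35	2.99	2.33
A4T4	40	2.90	2.45	1.79
A4T4	70	3.03	2.64	1.99
A4T4	100	3.15	2.76	2.11
A4T4	150	3.27	2.91	2.24
A4T4	200	3.39	3.01	2.34
A5T5	40	2.81	2.42	1.77
A5T5	70	2.96	2.60	1.96
A5T5	100	3.11	2.73	2.09
A5T5	150	3.21	2.88	2.23
A5T5	200	3.33	2.98	2.33
AT2	40	2.97	2.50	1.79
AT2	70	3.08	2.66	1.98
AT2	100	3.16	2.76	2.10
AT2	150	3.24	2.88	2.23
AT2	200	3.32	2.96	2.31
AT3	40	2.94	2.48	1.80
AT3	70	3.07	2.66	1.98
AT3	100	3.15	2.77	2.11
AT3	150	3.28	2.90	2.24
AT3	200	3.37	3.00	2.33
AT4	40	2.88	2.47	1.79
AT4	70	3.05	2.65	1.99
AT4	100	3.17	2.77	2.12
AT4	150	3.27	2.91	2.25
AT4	200	3.39	3.01	2.35
AT5	40	2.90	2.45	1.79
AT5	70	3.01	2.62	1.99
AT5	100	3.14	2.76	2.11
AT5	150	3.27	2.92	2.26
AT5	200	3.40	3.02	2.35
AT6	40	2.78	2.40	1.75
AT6	70	2.96	2.59	1.94
AT6	100	3.08	2.73	2.07
AT6	150	3.24	2.88	2.21
AT6	200	3.35	2.98	2.31
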