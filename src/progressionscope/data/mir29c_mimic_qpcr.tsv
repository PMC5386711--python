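gene_id	control_fold	treated_fold	significant
LAMC2	1.00	0.46	True
ZDHHC21	1.00	0.95	False
TGIF2	1.00	0.21	True
SPRY4	1.00	0.55	True
MAPK10	1.00	1.50	False
AKT3	1.00	0.80	True
MAP2K6	1.00	0.48	True
CDK6	1.00	0.20	True
GSK3B	1.00	1.11	False
CREB5	1.00	0.50	True
FOS	1.00	0.41	True
RPS6KA3	1.00	0.98	False
E2F7	1.00	0.28	True
KPNA1	1.00	1.00	False
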