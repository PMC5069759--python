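# Chicago Area Waterway System ambient monitoring stations: coordinates,
# physicochemistry, and 16S community diversity summaries (published values).
site_id	region	latitude	longitude	temperature_c	shannon_h	pielou_j	dissolved_oxygen_mg_l	ph	ammonia_mg_l	kjeldahl_n_ug_ml	sulfate_mg_l	alkalinity	chloride_mg_l	fluoride_mg_l	total_organic_c_mg_l	phenol_mg_l
WW76	Calumet	41.6575	-87.6411	24.3	5.50782	0.74616	6.7	7.34	0.11	0.6	53.11	137	62	0.38	3.5	4.1
WW56	Calumet	41.6503	-87.6171	24.1	5.11079	0.7205	6.5	8.01	0.12	0.7	29.39	259	70	0.15	2.1	3.1
WW57	Calumet	41.6517	-87.6606	23.5	5.23254	0.70941	6.9	6.64	0.19	0.7	23.73	108	63	0.14	1.9	3.9
WW96	NBCR	41.9743	-87.7061	13.4	5.15931	0.71528	8.1	7.95	0.11	0.5	60.37	165	235	0.36	4.6	4.1
WW73	NBCR	41.9324	-87.6829	17.1	5.23976	0.71988	7.5	7.42	0.1	0.8	50.41	159	63	0.47	5.1	4
WW99	SBCR	41.8386	-87.664	21.1	4.74986	0.67439	7.8	7.06	0.7	2.03	52.38	164	171	0.59	5.9	2.8
WW108	SBCR	41.8459	-87.6606	21.6	5.5954	0.7607	5.6	6.5	0.49	0.6	32.91	116	62	0.43	3.2	3.2
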