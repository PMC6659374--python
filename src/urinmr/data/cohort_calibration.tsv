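# Cohort simulation calibration for the packaged library subset.
# mean_umol_per_L: typical spot-urine concentration used as the simulation
# mean (order-of-magnitude plausible, not a measured value).
# intra_individual_cv / inter_individual_cv: calibration targets in percent
# for the day-to-day and population layers of the generator.
# Creatinine has no published creatinine-scaled CV (it is the normalizer);
# its row calibrates urine-dilution variation for the simulator.
metabolite	mean_umol_per_L	intra_individual_cv	inter_individual_cv
creatinine	11000	25.0	50.0
alanine	240	28.69	49.88
glycine	900	34.71	73.98
histidine	400	30.25	48.81
threonine	150	38.58	75.44
isoleucine	15	23.27	54.06
valine	40	20.28	39.50
glucose	400	13.76	1654.62
lactate	120	44.26	476.52
citrate	2300	27.92	53.35
urea	230000	32.98	39.44
hippurate	2000	58.45	69.26
acetate	40	62.87	394.31
dimethylamine	250	9.79	30.48
formate	160	41.32	584.66
tmao	320	80.89	127.14
hypoxanthine	90	38.80	338.41
trigonelline	100	68.71	74.64
2-hydroxyisobutyrate	45	16.25	35.39
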