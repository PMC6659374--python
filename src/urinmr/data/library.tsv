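metabolite	pathway	center_ppm	n_protons	couplings	mobility_ppm
creatinine	creatine metabolism	3.045	3		0.004
creatinine	creatine metabolism	4.060	2		0.004
glucose	glycolysis-related	5.233	1	3.8:1	0.004
alanine	amino acids	1.480	3	7.26:1	0.004
lactate	glycolysis-related	1.330	3	6.97:1	0.003
threonine	amino acids	1.318	3	6.6:1	0.003
2-hydroxyisobutyrate	miscellaneous	1.360	6		0.003
acetate	microbial metabolism	1.920	3		0.004
citrate	citrate cycle-related	2.540	2	15.1:1	0.006
citrate	citrate cycle-related	2.660	2	15.1:1	0.006
dimethylamine	microbial metabolism	2.720	6		0.004
tmao	microbial metabolism	3.270	9		0.005
glycine	amino acids	3.560	2		0.004
hippurate	phenylalanine metabolism	3.970	2		0.004
hippurate	phenylalanine metabolism	7.830	2	7.8:1	0.005
urea	urea cycle	5.780	4		0.010
histidine	amino acids	7.900	1		0.006
formate	microbial metabolism	8.450	1		0.005
hypoxanthine	purine metabolism	8.200	1		0.005
trigonelline	nicotinate metabolism	9.120	1		0.005
valine	branched-chain amino acids	1.040	3	7.0:1	0.003
valine	branched-chain amino acids	0.990	3	7.0:1	0.003
isoleucine	branched-chain amino acids	1.010	3	7.0:1	0.003
isoleucine	branched-chain amino acids	0.940	3	7.4:2	0.003
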