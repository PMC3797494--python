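species	sexual_system	pollen_vector	seed_dispersal	life_form	marker	F	sp	npop	source
Ficus citrifolia	monoecy	insect	animal/gravity	small tree or hemiepiphyte	microsatellite	-0.113	0.0068	2	this_study
Ficus eximia	monoecy	insect	animal/gravity	tree	microsatellite	-0.209	0.0063	1	this_study
Ficus hispida	dioecy	insect	animal/gravity	small tree	microsatellite	0.230	0.0350	1	Dev_et_al
Ficus exasperata	dioecy	insect	animal/gravity	tree	microsatellite	0.390	0.0311	1	Dev_et_al
Ficus pumila	dioecy	insect	animal/gravity	climbing	microsatellite	0.287	0.0742	1	Wang_et_al
Ficus cyrtophylla	dioecy	insect	animal/gravity	small tree	microsatellite		0.0291	1	Zhou_Chen
Acer pseudoplatanus	monoecy	insect/wind	wind/water	tree	microsatellite		0.0170	2	Pandey_et_al
Carapa guianensis	monoecy	insect	animal/gravity/water	tree	microsatellite	0.029	0.0045	1	Cloutier_et_al
Carapa procera	monoecy	insect	animal	tree	RAPD	0.143	0.0280	1	Hardy_et_al
Fagus sylvatica	monoecy	wind	gravity/animal	tree	microsatellite		0.0219	3	Oddou-Muratorio_et_al
Fagus crenata	monoecy	wind	gravity/animal	tree	microsatellite		0.0032	1	Oddou-Muratorio_et_al
Larix laricina	monoecy	wind	wind	tree	allozyme	0.024	0.0045	1	Vekemans_Hardy
Quercus ilex	monoecy	wind	animal	tree	microsatellite	-0.026	0.0035	1	Soto_et_al
Quercus lobata	monoecy	wind	animal	tree	microsatellite	-0.020	0.0046	1	Dutech_et_al
Quercus petraea	monoecy	wind	animal/gravity	tree	microsatellite	0.059	0.0083	1	Vekemans_Hardy
Quercus robur	monoecy	wind	animal/gravity	tree	microsatellite	0.077	0.0030	1	Vekemans_Hardy
Quercus suber	monoecy	wind		tree	microsatellite	-0.036	0.0229	1	Soto_et_al
Thuja occidentalis	monoecy	wind	wind	tree	microsatellite	0.019	0.0185	2	Pandey_Rajora
Aucoumea klaineana	dioecy	insect	wind	tree	microsatellite	0.088	0.0111	6	Born_et_al
Araucaria angustifolia	dioecy	wind	animal/gravity	tree	microsatellite		0.0130	4	Stefenon_et_al
Milicia excelsa	dioecy	wind	animal	tree	microsatellite	0.077	0.0063	1	Bizoux_et_al
Bagassa guianensis	dioecy	insect		tree	microsatellite	-0.050	0.0388	1	Silva_et_al
Ceratiola ericoides	dioecy	wind	gravity/animal	shrub	allozyme		0.0225	2	Trapnell_et_al
Dioscorea japonica	dioecy	insect	gravity/animal	climbing	microsatellite	0.000	0.0140	1	Mizuki_et_al
Eurya emarginata	dioecy	insect	gravity	tree	allozyme	0.000	0.0246	1	Vekemans_Hardy
Myracrodruon urundeuva	dioecy	insect	wind	tree	microsatellite	-0.153	0.0269	1	Gaiano_et_al
Protium spruceanum	dioecy	insect	animal/gravity	tree	allozyme	-0.143	0.0110	2	Vieira_et_al
Rhus javanica	dioecy	insect	animal/gravity	tree	microsatellite	0.000	0.0145	1	Vekemans_Hardy
Virola michelli	dioecy	insect	animal	tree	RAPD	0.214	0.0150	1	Hardy_et_al
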