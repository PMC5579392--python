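species	gene_name	mod_id	chromosome	position	strand	support_num	kturn_position_label
human	SNORD13	m6A_site_124853	chr8	33371093	+	11	boxD 1n
human	SNORD13	m6A_site_136193	chrX	23525329	-	8	boxD 1n
human	SNORD13	m6A_site_24525	chr11	66988484	+	3	boxD 1n
human	SNORD13	m6A_site_130577	chr9	75142252	+	1	boxD 1n
human	SNORD46	m6A_site_4620	chr1	45242258	+	4	boxD 1n
human	SNORD46	m6A_site_122222	chr7	132437879	+	2	boxD 1n
human	SNORD48	m6A_site_111371	chr6	31803100	+	4	boxD 1n
human	SNORD101	m6A_site_115173	chr6	133136512	+	1	boxD 1n
human	SNORD5	m6A_site_25652	chr11	93466398	-	2	boxD 1n
human	SNORD67	m6A_site_22376	chr11	46783944	-	3	boxD 1n
human	SNORD71	m6A_site_50014	chr16	71792313	-	2	boxD 1n
human	SNORD89	m6A_site_74416	chr2	101889404	-	1	boxD 1n
human	SNORD2	m6A_site_95922	chr3	186502617	+	1	boxD' 1n
human	SNORD29	m6A_site_23425	chr11	62621408	-	1	boxD' 1n
human	SNORD41	m6A_site_64597	chr19	12817310	-	1	boxD' 1n
human	SNORD44	m6A_site_10668	chr1	173835140	-	9	boxD' 1n
human	SNORD57	m6A_site_79190	chr20	2637610	+	1	boxD' 1n
human	SNORD62A	m6A_site_133909	chr9	134361128	+	2	boxD' 1n
human	SNORD62B	m6A_site_133912	chr9	134365904	+	5	boxD' 1n
mouse	SNORD2	m6A_site_29280	chr16	23108986	+	1	boxD' 1n
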