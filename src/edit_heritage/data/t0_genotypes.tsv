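plant_id	generation	parent_id	locus	genotype	zygosity	cas9	unexpected
Ta75	T0		fuct1	No mutation	wild_type	True	False
Ta75	T0		xylt1	+1 bp/-1 bp	bi_allelic	True	False
Ta139	T0		fuct1	No mutation	wild_type	True	False
Ta139	T0		xylt1	+1 bp/-1 bp	bi_allelic	True	False
Ta158	T0		fuct1	No mutation	wild_type	True	False
Ta158	T0		xylt1	+1 bp/+1 bp	bi_allelic	True	False
Ta3	T0		fuct1	-9 bp/-9 bp	homozygous	True	False
Ta3	T0		xylt1	-11 bp/+1 bp	bi_allelic	True	False
Ta12	T0		fuct1	-9 bp/-9 bp	homozygous	True	False
Ta12	T0		xylt1	-11 bp/+1 bp	bi_allelic	True	False
Ta18	T0		fuct1	-9 bp/-9 bp	homozygous	True	False
Ta18	T0		xylt1	-11 bp/+1 bp	bi_allelic	True	False
Ta27	T0		fuct1	-9 bp/-9 bp	homozygous	True	False
Ta27	T0		xylt1	-11 bp/+1 bp	bi_allelic	True	False
Ta105	T0		fuct1	+1 bp/+1 bp	homozygous	True	False
Ta105	T0		xylt1	+1 bp/+1 bp	bi_allelic	True	False
Ta106	T0		fuct1	+1 bp/+1 bp	homozygous	True	False
Ta106	T0		xylt1	+1 bp/+1 bp	bi_allelic	True	False
Ta146	T0		fuct1	-4 bp/-4 bp	homozygous	True	False
Ta146	T0		xylt1	+1 bp/+1 bp	bi_allelic	True	False
Ta161	T0		fuct1	-4 bp/-4 bp	homozygous	True	False
Ta161	T0		xylt1	+1 bp/+1 bp	bi_allelic	True	False
Ta122	T0		fuct1	-113 bp/-113 bp	homozygous	True	False
Ta122	T0		xylt1	+1 bp/+1 bp	bi_allelic	True	False
Ta117	T0		fuct1	+1 bp/-9 bp	bi_allelic	True	False
Ta117	T0		xylt1	+1 bp/-9 bp	bi_allelic	True	False
Ta133	T0		fuct1	+1 bp/-9 bp	bi_allelic	True	False
Ta133	T0		xylt1	+1 bp/-9 bp	bi_allelic	True	False
Ta237	T0		fuct1	+1 bp/-4 bp	bi_allelic	True	False
Ta237	T0		xylt1	+1 bp/-9 bp	bi_allelic	True	False
Ta248	T0		fuct1	+1 bp/+1 bp	bi_allelic	True	False
Ta248	T0		xylt1	+1 bp/+1 bp	bi_allelic	True	False
Ta77	T0		fuct1	+1 bp/-4 bp	bi_allelic	True	False
Ta77	T0		xylt1	No mutation	wild_type	True	False
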