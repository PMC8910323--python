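plant_id	generation	parent_id	locus	genotype	zygosity	cas9	unexpected
Ta75	T0		xylt1	+1 bp(A)/-1 bp	bi_allelic	True	False
Ta75-11	T1	Ta75	xylt1	+1 bp(A)/-1 bp	bi_allelic	False	False
Ta75-14	T1	Ta75	xylt1	+1 bp(A)/-1 bp	bi_allelic	False	False
Ta75-15	T1	Ta75	xylt1	+1 bp(A)/-1 bp	bi_allelic	True	False
Ta75-17	T1	Ta75	xylt1	+1 bp(A)/-1 bp	bi_allelic	False	False
Ta75-16	T1	Ta75	xylt1	+1 bp(T)/-1 bp	bi_allelic	True	True
Ta75-2	T1	Ta75	xylt1	-1 bp/-1 bp	homozygous	True	False
Ta75-12	T1	Ta75	xylt1	-1 bp/-1 bp	homozygous	True	False
Ta75-3	T1	Ta75	xylt1	+1 bp(A)/+1 bp(A)	homozygous	False	False
Ta75-4	T1	Ta75	xylt1	+1 bp(A)/+1 bp(A)	homozygous	False	False
Ta75-13	T1	Ta75	xylt1	+1 bp(A)/+1 bp(A)	homozygous	True	False
Ta75-18	T1	Ta75	xylt1	+1 bp(T)/-1 bp/+1 bp(A)	chimeric	False	True
Ta139	T0		xylt1	+1 bp(A)/-1 bp	bi_allelic	True	False
Ta139-1	T1	Ta139	xylt1	+1 bp(A)/-1 bp	bi_allelic	True	False
Ta139-11	T1	Ta139	xylt1	+1 bp(A)/-1 bp	bi_allelic	False	False
Ta139-12	T1	Ta139	xylt1	+1 bp(A)/-1 bp	bi_allelic	False	False
Ta139-15	T1	Ta139	xylt1	+1 bp(A)/+1 bp(T)	bi_allelic	False	True
Ta139-13	T1	Ta139	xylt1	+1 bp(A)/+1 bp(A)	homozygous	False	False
Ta139-14	T1	Ta139	xylt1	+1 bp(A)/+1 bp(A)	homozygous	False	False
Ta139-16	T1	Ta139	xylt1	+1 bp(A)/+1 bp(A)	homozygous	True	False
Ta139-2	T1	Ta139	xylt1	+1 bp(A)/+1 bp(T)/-1 bp	chimeric	True	True
Ta105	T0		xylt1	+1 bp(T)/+1 bp(C)	bi_allelic	True	False
Ta105-2	T1	Ta105	xylt1	+1 bp(T)/+1 bp(C)	bi_allelic	False	False
Ta105-11	T1	Ta105	xylt1	+1 bp(T)/+1 bp(C)	bi_allelic	False	False
Ta105-14	T1	Ta105	xylt1	+1 bp(T)/+1 bp(C)	bi_allelic	False	False
Ta105-15	T1	Ta105	xylt1	+1 bp(T)/+1 bp(C)	bi_allelic	False	False
Ta105-17	T1	Ta105	xylt1	+1 bp(T)/+1 bp(C)	bi_allelic	True	False
Ta105-12	T1	Ta105	xylt1	+1 bp(T)/+1 bp(T)	homozygous	False	False
Ta105-16	T1	Ta105	xylt1	+1 bp(C)/+1 bp(C)	homozygous	True	False
Ta105-3	T1	Ta105	xylt1	+1 bp(A)/+1 bp(A)	homozygous	True	True
Ta105-4	T1	Ta105	xylt1	+1 bp(A)/+1 bp(A)	homozygous	True	True
Ta105-18	T1	Ta105	xylt1	+1 bp(T)/+1 bp(A)/-1 bp	chimeric	False	True
Ta106	T0		xylt1	+1 bp(T)/+1 bp(C)	bi_allelic	True	False
Ta106-1	T1	Ta106	xylt1	+1 bp(T)/+1 bp(C)	bi_allelic	False	False
Ta106-2	T1	Ta106	xylt1	+1 bp(T)/+1 bp(C)	bi_allelic	False	False
Ta106-13	T1	Ta106	xylt1	+1 bp(T)/+1 bp(C)	bi_allelic	False	False
Ta106-14	T1	Ta106	xylt1	+1 bp(T)/+1 bp(T)	homozygous	False	False
Ta106-15	T1	Ta106	xylt1	+1 bp(T)/+1 bp(T)	homozygous	False	False
Ta106-17	T1	Ta106	xylt1	+1 bp(T)/+1 bp(T)	homozygous	False	False
Ta106-12	T1	Ta106	xylt1	+1 bp(C)/+1 bp(C)	homozygous	False	False
Ta106-18	T1	Ta106	xylt1	+1 bp(A)/+1 bp(T)/+1 bp(C)	chimeric	False	True
Ta146	T0		xylt1	+1 bp(A)/+1 bp(T)	bi_allelic	True	False
Ta146-1	T1	Ta146	xylt1	+1 bp(A)/+1 bp(T)	bi_allelic	True	False
Ta146-11	T1	Ta146	xylt1	+1 bp(A)/+1 bp(T)	bi_allelic	True	False
Ta146-12	T1	Ta146	xylt1	+1 bp(A)/+1 bp(T)	bi_allelic	True	False
Ta146-16	T1	Ta146	xylt1	+1 bp(A)/+1 bp(T)	bi_allelic	True	False
Ta146-17	T1	Ta146	xylt1	+1 bp(A)/+1 bp(T)	bi_allelic	True	False
Ta146-15	T1	Ta146	xylt1	-1 bp/+1 bp(T)	bi_allelic	False	True
Ta146-13	T1	Ta146	xylt1	+1 bp(A)/+1 bp(A)	homozygous	True	False
Ta146-2	T1	Ta146	xylt1	+1 bp(A)/+1 bp(T)/-1 bp	chimeric	True	True
Ta146-14	T1	Ta146	xylt1	+1 bp(A)/+1 bp(T)/-1 bp	chimeric	True	True
Ta146-18	T1	Ta146	xylt1	+1 bp(A)/+1 bp(T)/-1 bp	chimeric	True	True
Ta161	T0		xylt1	+1 bp(A)/+1 bp(T)	bi_allelic	True	False
Ta161-11	T1	Ta161	xylt1	+1 bp(A)/+1 bp(T)	bi_allelic	False	False
Ta161-13	T1	Ta161	xylt1	+1 bp(A)/+1 bp(T)	bi_allelic	True	False
Ta161-15	T1	Ta161	xylt1	+1 bp(A)/+1 bp(T)	bi_allelic	True	False
Ta161-1	T1	Ta161	xylt1	+1 bp(T)/+1 bp(T)	homozygous	True	False
Ta161-2	T1	Ta161	xylt1	+1 bp(T)/+1 bp(T)	homozygous	True	False
Ta161-12	T1	Ta161	xylt1	+1 bp(T)/+1 bp(T)	homozygous	True	False
Ta161-16	T1	Ta161	xylt1	+1 bp(T)/+1 bp(T)	homozygous	True	False
Ta161-17	T1	Ta161	xylt1	+1 bp(T)/+1 bp(T)	homozygous	False	False
Ta161-14	T1	Ta161	xylt1	+1 bp(A)/+1 bp(A)	homozygous	False	False
Ta161-18	T1	Ta161	xylt1	+1 bp(A)/+1 bp(T)/-1 bp	chimeric	False	True
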