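plant_id	generation	parent_id	locus	genotype	zygosity	cas9	unexpected
Ta161	T0		fuct1	+1 bp(T)/+1 bp(A)	bi_allelic	True	False
Ta161	T0		xylt1	-4 bp/-4 bp	homozygous	True	False
Ta161-1	T1	Ta161	fuct1	+1 bp(T)/+1 bp(T)	homozygous	True	False
Ta161-1	T1	Ta161	xylt1	-4 bp/-4 bp	homozygous	True	False
Ta161-1-1	T2	Ta161-1	fuct1	+1 bp(T)/+1 bp(T)	homozygous	True	False
Ta161-1-1	T2	Ta161-1	xylt1	-4 bp/-4 bp	homozygous	True	False
Ta161-1-2	T2	Ta161-1	fuct1	+1 bp(T)/+1 bp(T)	homozygous	False	False
Ta161-1-2	T2	Ta161-1	xylt1	-4 bp/-4 bp	homozygous	False	False
Ta161-1-3	T2	Ta161-1	fuct1	+1 bp(T)/+1 bp(T)	homozygous	False	False
Ta161-1-3	T2	Ta161-1	xylt1	-4 bp/-4 bp	homozygous	False	False
Ta161-1-4	T2	Ta161-1	fuct1	+1 bp(T)/+1 bp(T)	homozygous	True	False
Ta161-1-4	T2	Ta161-1	xylt1	-4 bp/-4 bp	homozygous	True	False
Ta161-1-5	T2	Ta161-1	fuct1	+1 bp(T)/+1 bp(T)	homozygous	True	False
Ta161-1-5	T2	Ta161-1	xylt1	-4 bp/-4 bp	homozygous	True	False
Ta161-1-6	T2	Ta161-1	fuct1	+1 bp(T)/+1 bp(T)	homozygous	False	False
Ta161-1-6	T2	Ta161-1	xylt1	-4 bp/-4 bp	homozygous	False	False
Ta161-1-7	T2	Ta161-1	fuct1	+1 bp(T)/+1 bp(T)	homozygous	False	False
Ta161-1-7	T2	Ta161-1	xylt1	-4 bp/-4 bp	homozygous	False	False
Ta161-1-8	T2	Ta161-1	fuct1	+1 bp(T)/+1 bp(T)	homozygous	True	False
Ta161-1-8	T2	Ta161-1	xylt1	-4 bp/-4 bp	homozygous	True	False
Ta161-1-9	T2	Ta161-1	fuct1	+1 bp(T)/+1 bp(T)	homozygous	False	False
Ta161-1-9	T2	Ta161-1	xylt1	-4 bp/-4 bp	homozygous	False	False
Ta161-1-10	T2	Ta161-1	fuct1	+1 bp(T)/+1 bp(T)	homozygous	True	False
Ta161-1-10	T2	Ta161-1	xylt1	-4 bp/-4 bp	homozygous	True	False
Ta161-1-11	T2	Ta161-1	fuct1	+1 bp(T)/+1 bp(T)	homozygous	True	False
Ta161-1-11	T2	Ta161-1	xylt1	-4 bp/-4 bp	homozygous	True	False
Ta161-1-12	T2	Ta161-1	fuct1	+1 bp(T)/+1 bp(T)	homozygous	True	False
Ta161-1-12	T2	Ta161-1	xylt1	-4 bp/-4 bp	homozygous	True	False
Ta161-1-13	T2	Ta161-1	fuct1	+1 bp(T)/+1 bp(T)	homozygous	True	False
Ta161-1-13	T2	Ta161-1	xylt1	-4 bp/-4 bp	homozygous	True	False
Ta161-1-14	T2	Ta161-1	fuct1	+1 bp(T)/+1 bp(T)	homozygous	False	False
Ta161-1-14	T2	Ta161-1	xylt1	-4 bp/-4 bp	homozygous	False	False
Ta161-1-15	T2	Ta161-1	fuct1	+1 bp(T)/+1 bp(T)	homozygous	False	False
Ta161-1-15	T2	Ta161-1	xylt1	-4 bp/-4 bp	homozygous	False	False
Ta161-1-16	T2	Ta161-1	fuct1	+1 bp(T)/+1 bp(T)	homozygous	True	False
Ta161-1-16	T2	Ta161-1	xylt1	-4 bp/-4 bp	homozygous	True	False
Ta161-1-17	T2	Ta161-1	fuct1	+1 bp(T)/+1 bp(T)	homozygous	False	False
Ta161-1-17	T2	Ta161-1	xylt1	-4 bp/-4 bp	homozygous	False	False
Ta161-1-18	T2	Ta161-1	fuct1	+1 bp(T)/+1 bp(T)	homozygous	False	False
Ta161-1-18	T2	Ta161-1	xylt1	-4 bp/-4 bp	homozygous	False	False
Ta161-1-19	T2	Ta161-1	fuct1	+1 bp(T)/+1 bp(T)	homozygous	True	False
Ta161-1-19	T2	Ta161-1	xylt1	-4 bp/-4 bp	homozygous	True	False
Ta161-1-20	T2	Ta161-1	fuct1	+1 bp(T)/+1 bp(T)	homozygous	False	False
Ta161-1-20	T2	Ta161-1	xylt1	-4 bp/-4 bp	homozygous	False	False
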