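# synthetic links: DOID	mature	pubmed	target genes (comma separated)
DOID:9000001	zaa-miR-1	99000001	SYNGENE1,SYNGENE2
DOID:9000001	zaa-miR-2	99000002	SYNGENE3
DOID:9000002	zaa-miR-1	99000003	SYNGENE1
DOID:9000002	zab-miR-1	99000004	SYNGENE4,SYNGENE5
DOID:9000003	zab-miR-2	99000005	SYNGENE6
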