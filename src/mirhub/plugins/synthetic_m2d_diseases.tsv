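# synthetic disease table (made-up DOIDs; for plugin mechanics only)
DOID:9000001	synthetic carcinoma
DOID:9000002	synthetic cardiomyopathy
DOID:9000003	synthetic neuropathy
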