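[MILVT] xxx[LV] xxx [LIVT]- [DTS] xxx [LIFVM]xx[CLIAVF]-[ILVME]-x [LMFVA]xxxGxx [PGA], xx [LIV]-[VIAS]x [VILAM]-[VIFLG]
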