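>hsa-miR-372-3p MIMAT0000724 mature
AAAGUGCUGCGACAUUUGAGCGU
>hsa-miR-373-3p MIMAT0000726 mature
GAAGUGCUUCGAUUUUGGGGUGU
>hsa-miR-519c-3p MIMAT0002832 mature
AAAGUGCAUCUUUUUAGAGGAU
>hsa-miR-520c-3p MIMAT0002846 mature
AAAGUGCUUCCUUUUAGAGGGU
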