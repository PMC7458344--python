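sample	class
S01	HI
S02	HI
S03	HI
S04	HI
S05	HI
S06	HI
S07	HI
S08	HI
S09	HI
S10	HI
S11	HI
S12	HI
S13	HI
S14	HI
S15	HI
S16	LOW
S17	LOW
S18	LOW
S19	LOW
S20	LOW
S21	LOW
S22	LOW
S23	LOW
S24	LOW
S25	LOW
S26	LOW
S27	LOW
S28	LOW
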