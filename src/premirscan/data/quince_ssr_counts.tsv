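# Microsatellite counts by motif length for the quince draft assembly (JADOBS000000000)
motif_length	count
1	171414
2	117091
3	15268
4	3081
5	833
6	484
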