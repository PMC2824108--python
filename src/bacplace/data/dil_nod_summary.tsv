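field	count
clones_in_library	196032
attempted_reads	378896
reads_passed	332535
clones_both_ends_passed	150878
reads_aligned	318065
reads_unique	170029
reads_multiple	148036
clones_unique_pairs	41468
clones_rescued	83796
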