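field	count
clones_in_library	110976
attempted_reads	207321
reads_passed	170159
clones_both_ends_passed	75046
reads_aligned	159574
reads_unique	80710
reads_multiple	78864
clones_unique_pairs	18257
clones_rescued	43905
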