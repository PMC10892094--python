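# Demo configuration: a small synthetic dataset that exercises every
# pipeline stage in well under a minute.  All omitted parameters keep the
# package defaults (the emulated study design: 3 IP + 3 input replicates
# per condition, 3x2 RNA-seq, 2x2 polysome-seq, 150-200 nt peaks with
# 3'UTR bias, TGTA motif planted in peaks).
n_transcripts: 300
seed: 0
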