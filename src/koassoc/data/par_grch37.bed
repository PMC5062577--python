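# GRCh37 pseudoautosomal regions on the X chromosome (0-based, half-open)
X	60000	2699520	PAR1
X	154931043	155260560	PAR2
chrX	60000	2699520	PAR1
chrX	154931043	155260560	PAR2
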