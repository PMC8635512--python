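# Canonical RNA-binding domains.
# One Pfam-style domain name per line; lines starting with '#' are ignored.
# An RBP carrying at least one of these is counted as "canonical";
# everything else binds RNA through non-canonical surfaces.
RRM
DEAD
KH
zf-CCCH
zf-CCHC
zf-C2H2
zf-RanBP
zf-met
dsRBD
PUF
La
S1
Helicase_C
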