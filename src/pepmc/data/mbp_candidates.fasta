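>MBP-1 source=reference
SPAGGQDF
>MBP-2 source=reference
WGTNGGTR
>MBP-3 source=reference
APRGGNTS
>MBP-4 source=reference
PQYPPHDN
>MBP-5 source=reference
GLPKPGGN
>MBP-6 source=reference
PQKGGMWD
>MBP-7 source=reference
WSPNFWWR
>MBP-8 source=reference
WHPRPVWE
>MBP-9 source=reference
YHFPYFRF
>MBP-10 source=reference
YGDGYFRF
>MBP-11 source=reference
YHDGYFRF
>poliALA source=reference
AAAAAAAA
>NEG source=reference
AAARRAAA
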