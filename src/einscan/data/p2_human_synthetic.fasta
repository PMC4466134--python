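>p2_human_synthetic | SYNTHETIC stand-in, not a database record | 132-residue chain whose amino-acid composition is constructed to match the published composition characteristics of human myelin P2 (H ~50% of atoms; methyl fraction a1 = 0.26 of non-exchangeable H); residue order is arbitrary
SSSKELVECTKEDANILEDGTVAEVIPFGYAQLKEVRIGMGLDHMVERNWDKGNLFKVFA
GSNKSAQLRNQLDFLVRTSFGDLKKVQEAELIKFKGTKMWGFYKKHEIYECDITYTKVKF
PDAGIVFNSTFK
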