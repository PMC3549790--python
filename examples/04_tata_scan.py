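"""TATA-box scanning in the canonical core-promoter region.

Plants a TATA box 28 nt upstream of the TSS in one synthetic promoter
and scans both it and an unmodified CG-based promoter with the IUPAC
consensus TATAWAW over -40..-19.  Prints hit positions relative to
the TSS.
"""

import promkic as pk

plain = pk.generate(pk.default_recipe("CG_based"), seed=8)

body = list(plain.sequence)
body[472:479] = "TATAAAA"  # TSS at 500, so this sits at -28
with_tata = pk.PromoterSequence(id="planted", sequence="".join(body), tss_offset=500)

for seq in (with_tata, plain):
    res = pk.scan_tata(seq)  # motif TATAWAW, region (-40, -19)
    status = "TATA-containing" if res.tata_containing else "TATA-less"
    print(f"{seq.id}: {status}")
    for pos, word in res.hits:
        print(f"  {word} at {pos - seq.tss_offset:+d} relative to TSS")
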