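"""Classify premature termination codons as NMD-triggering or -evading.

Walks a PTC along a three-exon transcript and prints the classification
under the canonical escape rules (last exon, final 55 nt of the penultimate
exon, start-proximal region) with and without a 3'UTR EJC, plus the stricter
rule set with long-exon evasion and a buffer zone.
"""

from nmdeff import NMDRuleSet, PTCVariant, TranscriptModel, classify_ptc_nmd
from nmdeff.features import NMDFeatureProfile

# three exons of 300 nt; CDS covers the first 900 nt
model = TranscriptModel("tx", "g", "chr1", "+",
                        [(0, 300), (400, 700), (800, 1100)], 0, 900)
no_ejc = NMDFeatureProfile("tx", has_3utr_ejc=False)
with_ejc = NMDFeatureProfile("tx", has_3utr_ejc=True)

positions = [100, 250, 400, 540, 560, 700]
print(f"{'PTC pos':>8} {'region':<28}{'default rules':<16}{'with 3UTR EJC':<16}")
regions = {100: "first 200 nt (start-proximal)", 250: "internal exon 1",
           400: "internal exon 2", 540: "60 nt before last junction",
           560: "last 55 nt of penultimate", 700: "last exon"}
for pos in positions:
    ptc = PTCVariant("v", "chr1", 0, "C", "T", "nonsense", ptc_transcript_pos=pos)
    a = classify_ptc_nmd(ptc, model, no_ejc).value
    b = classify_ptc_nmd(ptc, model, with_ejc).value
    print(f"{pos:>8} {regions[pos]:<28}{a:<16}{b:<16}")

ptc = PTCVariant("v", "chr1", 0, "C", "T", "nonsense", ptc_transcript_pos=300)
model2 = TranscriptModel("tx2", "g", "chr1", "+",
                         [(0, 260), (300, 1000), (1100, 1400)], 0, 1200)
cls = classify_ptc_nmd(ptc, model2, NMDFeatureProfile("tx2"), NMDRuleSet.dnds()).value
print(f"\nstrict rule set, PTC in a 700 nt internal exon: {cls} "
      "(500-1000 nt exons fall in the excluded buffer zone)")
print("A downstream 3'UTR EJC flips last-exon / 55 nt escape calls back to "
      "triggering: the ribosome never displaces that junction's complex.")
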