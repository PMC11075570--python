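"""Published primer sequences for the three FP amplicon sets.

Lowercase marks the 19-nt Tn5 recognition element (a display convention;
comparisons are case-insensitive).  Rows: A forward / B reverse with no
extra linker, C forward with 3 extra linker codons, D forward / E reverse
for the 6-extra-codon linker.  The no-extra amplicon uses A+B, the
3-extra amplicon C+B, and the 6-extra amplicon D+E.
"""

TABLE1_PRIMERS = {
    "GFPmut3": {
        "A": "ctgtctcttatacacatctTGAGTAAAGGAGAAGAAC",
        "B": "ctgtctcttatacacatctAATTTGTATAGTTCATC",
        "C": "ctgtctcttatacacatctTGGAGCAATCCAGTAAAGGAGAAGAAC",
        "D": "ctgtctcttatacacatctTGCACAAACAGGAGCAATCCAGTAAAGGAGAAGAAC",
        "E": "ctgtctcttatacacatctTCGGACTGTTTGTATAGTTCATC",
    },
    "mCherry2": {
        "A": "ctgtctcttatacacatctTGGTGAGCAAGGGCG",
        "B": "ctgtctcttatacacatctAACTTGTACAGCTCGTCC",
        "C": "ctgtctcttatacacatctTGGAGCAATCCGTGAGCAAGGGCG",
        "D": "ctgtctcttatacacatctTGCACAAACAGGAGCAATCCGTGAGCAAGGGCG",
        "E": "ctgtctcttatacacatctTCGGACTGCTTGTACAGCTCGTCC",
    },
    "mYPET": {
        "A": "ctgtctcttatacacatctTGTCTAAAGGTGAAGAATTATTCACTGG",
        "B": "ctgtctcttatacacatctAATTTGTACAATTCATTCATACCCTCGG",
        "C": "ctgtctcttatacacatctTGGAGCAATCCTCTAAAGGTGAAGAATTATTCACTGG",
        "D": "ctgtctcttatacacatctTGCACAAACAGGAGCAATCCTCTAAAGGTGAAGAATTATTCACTGG",
        "E": "ctgtctcttatacacatctTCGGACTGTTTGTACAATTCATTCATACCCTCGG",
    },
}

# which primer rows each linker variant pairs
VARIANT_ROWS = {"none": ("A", "B"), "extra3": ("C", "B"), "extra6": ("D", "E")}
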