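"""Independent brute-force oracle for insertion-event classification.

Deliberately implemented with plain string splicing and Biopython
translation only — it never calls the package's classifier or product
assembly — so that agreement with ``classify_event`` is a genuine
two-route check.

The oracle decides whether an insertion yields an in-frame fusion
candidate purely from the assembled product sequence:

* splice ``duplication + insert`` into the plasmid circle before the cut;
* locate a 15-nt backbone anchor immediately upstream of the target ORF
  on its sense strand and translate from the ORF start until the first
  stop codon;
* the event is a candidate iff the translation contains the FP junction
  marker (5' linker peptide, the Leu from the modified start codon, then
  the FP interior), runs through to the target's native C-terminus, and
  the target-derived prefix before the marker is at least 4 codons
  (insertions whose duplicated 9-mer touches the start codon leave a
  prefix of <= 3 codons; ones touching the stop codon never reach the FP).
"""

from __future__ import annotations

from Bio.Seq import Seq

ANCHOR_LEN = 15
STOPS = {"TAA", "TAG", "TGA"}


def _rc(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _translate(seq: str) -> str:
    seq = seq[: len(seq) - len(seq) % 3]
    return str(Seq(seq).translate(table=11))


def assemble_product(plasmid_seq: str, insert: str, cut: int, forward: bool) -> str:
    """Splice the oriented insert plus its 9-nt duplication into the circle."""
    P = plasmid_seq
    dup = (P + P)[cut : cut + 9]
    ins = insert if forward else _rc(insert)
    return P[:cut] + dup + ins + P[cut:]


def is_candidate(
    plasmid_seq: str,
    orf_start: int,
    orf_end: int,
    strand: str,
    amplicon_seq: str,
    junction_marker: str,
    target_pep: str,
    cut: int,
    orientation: str,
) -> bool:
    """Translate-and-inspect decision for one cut/orientation combination."""
    product = assemble_product(plasmid_seq, amplicon_seq, cut, orientation == "forward")
    L = len(plasmid_seq)
    if strand == "+":
        sense_plasmid, s0 = plasmid_seq, orf_start
        sense_product = product
    else:
        sense_plasmid, s0 = _rc(plasmid_seq), L - orf_end
        sense_product = _rc(product)
    anchor = (sense_plasmid + sense_plasmid)[s0 + L - ANCHOR_LEN : s0 + L]
    doubled = sense_product + sense_product
    i = doubled.find(anchor)
    if i == -1:  # the insertion destroyed the region upstream of the ORF
        return False
    coding = doubled[i + ANCHOR_LEN : i + ANCHOR_LEN + len(product) + 3]
    pep_full = _translate(coding)
    stop_at = pep_full.find("*")
    if stop_at == -1:
        return False
    pep = pep_full[:stop_at]
    j = pep.find(junction_marker)  # j = N + 3: target codons precede the marker
    if j < 4 or pep[:j] != target_pep[:j]:
        return False
    # read-through must resume at codon N+1 and run to the native C-terminus
    return pep.endswith(target_pep[j - 3 :])


def junction_marker_for(fp_orf: str, extra5: str) -> str:
    """5' junction signature: element codons, the tTG Leu, linker extras,
    then the first FP-interior codons — computed from the raw inputs."""
    # the first 18 element bases; the 19th base + fp[1:3] always reads Leu
    me18_pep = _translate("CTGTCTCTTATACACATC")
    extra_pep = _translate(extra5) if extra5 else ""
    fp_core_pep = _translate(fp_orf[3:-3])
    return me18_pep + "L" + extra_pep + fp_core_pep[:8]
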