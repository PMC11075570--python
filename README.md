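# morfin

An in-silico toolkit for **M**utagenesis by **O**pen **R**eading **F**rame
**IN**sertion: creating random, in-frame fluorescent-protein (FP) fusions
into a target gene by Tn5 transposition, and screening *E. coli* colonies
for fluorescence.

The bench method is disarmingly simple — one in-vitro transposition
reaction, one transformation, plates screened for glowing colonies — but
everything that makes it work is sequence arithmetic: a donor amplicon
that is a single continuous ORF from its first to its last base, a
transposase that duplicates 9 bp of target sequence at every insertion,
and a reading-frame lottery that decides which insertions can ever
fluoresce. This package implements that arithmetic for people designing,
teaching, or sizing such screens:

* **`amplicon_designer`** — builds frame-preserving donor amplicons and the
  PCR primer pair for any FP ORF. The 19-nt Tn5 mosaic-end element (ME,
  `ctgtctcttatacacatct`) is placed as an inverted repeat at both ends; the
  FP start codon loses its first base (the 19th element base completes a
  tTG Leu codon) and the stop codon is ablated into a read-through codon,
  so the amplicon translates without a stop in frame 0. Three linker
  variants (none / 3 extra / 6 extra codons) tune the junction peptide.
* **`transposition_sim`** — simulates Tn5 insertion into a circular
  plasmid: uniform random cut sites, random orientation, and the 9-bp
  target-site duplication produced by the staggered cut
  (`product length = plasmid + amplicon + 9`).
* **`fusion_classifier`** — classifies each insertion against an annotated
  target ORF: `backbone`, `orf_edge`, `wrong_orientation`, `out_of_frame`,
  or `in_frame_candidate`, with full junction bookkeeping (codon *N*, the
  duplicated codons *N+1..N+3*, linker peptides, translated chimera).
* **`screen_model`** — the expected-frequency product

  ```
  p(positive colony) = p_single · (L_ORF / L_plasmid) · 1/2 · 1/3
  ```

  (single-insertion probability ≈ 1/200, ORF/plasmid length ratio, random
  orientation, codon-boundary lottery) and the derived plating plan. For
  the elongation-factor-G worked example (2,109 bp ORF on a 6,837 bp
  plasmid) the reciprocal rounds to **3,890 colonies per positive**.
* **`junction_caller`** — the universal-sequencing-primer strategy in
  reverse: from a Sanger read across the 3′ FP/target junction, find the
  ME element, map the downstream flank to the target, verify the frame
  and the duplicated codons, and call the insertion codon.
* **`fixtures`** — deterministic synthetic plasmids/FP ORFs, the published
  FP termini for byte-level primer checks, and the packaged EF-4
  insertion-site recovery map (159 student experiments) with its
  domain-level summary.

## Worked example

```python
from morfin import *
from morfin import fixtures

# 1. design a GFPmut3 donor amplicon (no extra linker codons)
fp = fixtures.synth_fp_with_termini("GFPmut3", seed=0)   # real termini, synthetic interior
amp = design_amplicon(fp, "none", fp_name="GFPmut3", anneal_fwd=18, anneal_rev=15)
print(amp.fwd_primer)   # CTGTCTCTTATACACATCTTGAGTAAAGGAGAAGAAC
print(amp.rev_primer)   # CTGTCTCTTATACACATCTAATTTGTATAGTTCATC
print(amp.linker5_peptide, amp.linker3_peptide)   # LSLIHI DVYKRQ

# 2. how hard is the screen? (EF-G geometry)
params = ScreenModelParams(orf_len=2109, plasmid_len=6837)
plan = screening_burden(params, k=3)
print(plan.colonies_per_positive, plan.plates)   # 3890 24

# 3. simulate a library and classify it
plasmid = fixtures.synth_plasmid(0, label="EFG")         # 6,837 bp, 2,109 bp ORF
events = simulate_library(plasmid, amp, 100_000, seed=0)
summary = summarize_library([classify_event(e, plasmid, "EFG") for e in events])
print(summary.class_counts)
# {'backbone': 68899, 'wrong_orientation': 15368, 'out_of_frame': 10231,
#  'in_frame_candidate': 5168, 'orf_edge': 334}
print(empirical_vs_expected(summary, params).agrees)     # True

# 4. confirm an insertion site from its junction read
ev = next(e for e in events
          if classify_event(e, plasmid, "EFG").classification == "in_frame_candidate")
print(call_insertion(simulate_read(ev), amp, plasmid, "EFG"))
# JunctionCall(read_name='read_event24', status='confirmed_in_frame', codon_N=110,
#              matched_flank_len=599, mismatches=0, orientation='+',
#              duplicated_codons='RQG')
```

The simulated in-frame fraction (0.0517 here) sits on the model's
(2109/6837)·(1/2)·(1/3) ≈ 0.0514, and the caller recovers the planted
codon exactly. The two printed primers are the published no-extra-linker
pair for GFPmut3.

The same workflow is available from the shell:

```bash
morfin fixtures make-plasmid --seed 1 --out target.gb
morfin fixtures make-fp --seed 2 --out fp.fasta
morfin design --fp fp.fasta --linker extra6 --out amp.fasta --primers primers.tsv
morfin simulate --plasmid target.gb --amplicon amp.fasta --n 10000 --seed 7 --out events.tsv
morfin classify --plasmid target.gb --events events.tsv --amplicon amp.fasta \
       --target target_orf --out fusions.tsv
morfin screen-plan --plasmid target.gb --target target_orf -k 3
morfin run --config run.yaml       # the whole pipeline, manifest + checksums
```

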