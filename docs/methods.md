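# Methods

## The system being modelled

Tn5 transposase inserts a linear blunt-end donor DNA into target DNA at
effectively random positions. The donor needs nothing but a 19-nt
recognition element ("mosaic end", ME) as an inverted repeat at both
ends. The insertion mechanism cleaves the two target strands 9 nt apart;
after ligation and host gap repair the 9-nt target sequence appears as a
direct repeat flanking the insert (target-site duplication, TSD).

The mutagenesis strategy exploited here places a fluorescent-protein ORF
between the two ME elements, edited so the whole donor is one continuous
ORF. When such a donor lands inside a target gene, in the right
orientation, exactly between two codons, the result is an in-frame
target–FP–target fusion — and only those insertions produce fluorescent
colonies, so the plate screen does the library selection. The package
implements the sequence-level part of this chain; it deliberately does
not model expression level, folding, protein turnover, or temperature
effects, which the bench screen folds in but which cannot be assigned
numbers.

## Coordinates and conventions

* 0-based, half-open intervals everywhere. Bonds (positions between
  bases) are indexed `0..L`; bond `i` lies after base `i-1`.
* `cut_bond` is the bond at the **left edge** of the duplicated 9-mer.
  When the cut falls on a codon boundary, "codon N" is the codon ending
  at base `cut_bond - 1`, and codons N+1..N+3 form the 9-nt overhang.
  This makes the codon bookkeeping literal:
  `… N | N+1 N+2 N+3 | donor | N+1 N+2 N+3 | N+4 …`.
  Published site lists do not state on which side of the duplication
  "insertion after codon X" sits, so reports expose both `codon_N` and
  `codon_N3`.
* Plasmids are circular; interval arithmetic is modulo L. Linear records
  refuse cuts within 9 nt of an end.
* Translation is NCBI table 11, `*` for stop, no start-codon
  special-casing. Lowercase input is accepted and normalized; IUPAC
  codes other than N are rejected.

## Donor amplicon design

Layout (coding strand):

```
ME(19) | fp[1:3] | extra5 | fp[3:-3] | readthrough | revcomp(ME)(19)
```

* Dropping the first base of the FP's ATG lets the 19th element base
  complete a `tTG` (Leu) codon — no internal start, and the element's
  first 18 bases read LSLIHI in frame. (A published description of this
  element gives LSLIQI; translating the printed DNA yields His at
  position 5, and the printed DNA is treated as authoritative — the
  peptide is always computed, never hard-coded.)
* The FP stop codon is ablated by the rule reconstructed from the
  published primer set: for the `none`/`extra3` variants the stop is
  replaced by `TT`, which the 3′ element's first base completes to a
  `TTa` Leu read-through codon; for `extra6` it is replaced by
  `CAGTCCGA`, read through as Gln-Ser-Glu. The same rule is applied to
  TAG/TGA stops, giving an identical junction peptide regardless of stop
  identity. (Prose descriptions of the 3′ edit — "the element's first
  base replaces the stop's third base" — would leave TAA → TAa, still a
  stop; the primer sequences show the middle base is edited too.)
* Extra linker codons (`extra3`: +EQS, `extra6`: +HKQEQS 5′ and +QSE 3′)
  sit between the modified start codon and the second FP codon, exactly
  as in the published primers. The resulting non-native codons at an
  eventual fusion junction are 6/9/12 on the 5′ side and 9/9/12 on the
  3′ side (element codons plus the duplicated triplet) for
  none/extra3/extra6. Convention: the read-through Leu counts as the
  FP's substituted terminal codon, not linker; for `extra6` the three
  replacement codons are linker. This reproduces the published 6/9 and
  12/12 accounting.
* Primer emission: forward = the amplicon head through
  `19 + len(extra5) + anneal_fwd` nt; reverse = reverse complement of
  the tail of equal construction. Annealing lengths default to 15 nt
  (the shortest length appearing in the published set); no Tm or
  secondary-structure optimization is attempted because the source
  protocol specifies none. The designs for GFPmut3, mCherry2 and mYPET
  reproduce all fifteen published primers byte-for-byte
  (case-insensitively) using only the published termini.

## Transposition simulation

Cut bonds are i.i.d. uniform over the plasmid and orientation is a fair
coin — insertion-site sequence bias is deliberately not modelled (the
method treats insertion as random), though `simulate_library` accepts a
position-weight vector as a hook. Each event carries exactly one
insertion, the regime enforced on the bench by the 1:1 amplicon:target
molar ratio; multiply-inserted plasmids enter only through the
single-insertion factor of the screening model. All randomness flows
from one `numpy` generator seeded per call, and the seed is echoed into
outputs. Products are assembled lazily so 10^5-event libraries stay
cheap.

## Classification rules

Ordered rules, applied per event against one annotated target ORF:

1. the cut and its whole 9-mer must lie inside the ORF interior, codon 2
   through the last sense codon; overlapping the start or stop codon is
   `orf_edge` (terminal-codon insertions are never reported in practice
   and an explicit rule keeps counts reproducible), no overlap is
   `backbone`;
2. donor strand must match target strand, else `wrong_orientation`;
3. the cut must sit on a codon boundary, else `out_of_frame`;
4. the reconstructed fusion ORF must translate stop-free to the native
   stop, else `out_of_frame`.

Survivors are `in_frame_candidate` = "passes every sequence-level
requirement of the plate screen". Reverse-strand targets are classified
in their sense frame; `codon_N` is always in target codon coordinates.
Any annotated ORF can be the target, so off-target fusions (e.g. into a
resistance gene) are one extra run with a different annotation.

The test suite pins these rules to an independent brute-force oracle
(string-splice the product, translate from an anchor upstream of the
ORF, inspect the peptide) over **every** cut × orientation of a 300-bp
plasmid, all linker variants, both strands.

## Screening-burden model

`p = p_single · (L_ORF/L_plasmid) · orientation · frame` with defaults
1/200, 1/2, 1/3. Colonies-per-positive is the reciprocal rounded to the
nearest integer — the worked example (2,109/6,837) gives 3890.2 → 3890 —
and plates = ⌈k · colonies / 500⌉ at the recommended high plating
density of 5×10² colonies per plate.

The factor product is a desk estimate, not the mechanistic count: it
implies L_ORF/3 usable codon boundaries, while the edge rules above
admit `n_sense − 3` of them (699 vs 703 for the worked example, a 0.6%
relative offset). At 10^5 simulated events this offset is ~0.4 binomial
SE, well inside the comparison tolerance; `empirical_vs_expected` checks
the model against the exact (Clopper–Pearson) 95% interval of the
simulated fraction scaled by `p_single`. Observed bench frequencies can
sit far above the model because expression level and domain structure —
explicitly unmodelled — also gate fluorescence.

## Junction-read calling

One "universal" primer per amplicon anneals ~60 nt upstream of the FP 3′
end and reads across the read-through codon(s), the 3′ ME element, the
duplicated codons and into the target. Only the 3′ junction is assessed;
the 5′ junction must already be correct for the colony to fluoresce.
Calling: locate the element (exact substring first, then a Hamming scan
with ≤2 mismatches), take the following ≥24 nt of flank, match it
against the target ORF on both strands (extended a few bases past the
stop so near-terminal insertions still map). Because the flank begins at
the duplicated copy, a match at codon M implies codon N = M − 1; frame
is confirmed iff the matched offset is ≡ 0 (mod 3). Repeated target
sequence yields `ambiguous` — never a silent tie-break, since the bench
confirmation is positional and a guessed site would be fabricated data.
Thresholds (flank 24 nt, ≤2 mismatches, 20-nt primer, 700-nt reads) are
declared defaults, configurable, not inferred from any source; the read
simulator uses a substitution-only error model, mirroring high-quality
Sanger base calls.

## Synthetic data

Generators are deterministic under an explicit seed. `synth_plasmid`
emulates the expression-vector geometry (circular backbone + one
annotated ORF; defaults 4,728 + 2,109 = 6,837 bp, the worked-example
ratio). `synth_fp_orf` produces stop-free random coding sequence
(default 238 codons, a typical FP length). `synth_fp_with_termini`
grafts the published GFPmut3/mCherry2/mYPET termini onto a synthetic
interior — primer design only reads the termini, so byte-level primer
tests need no full FP genes. What synthetic data do **not** emulate:
insertion hotspots, expression/folding effects, chromatogram-level read
artefacts (indels, quality decay), or real backbone features. Passing
tests therefore demonstrate the sequence arithmetic, not bench
frequencies.

The packaged EF-4 site map contains only the insertion sites whose
recovery counts were published as text (11 sites in five clusters, modal
site codon 128 with 20 recoveries) plus the five domain intervals and
the experiment total (159) as metadata; sites shown only graphically are
excluded, so per-site counts need not sum to the total.

## Problem sizes and numerical choices

Default test/acceptance scales, chosen to make binomial tolerances
meaningful at interactive runtimes: 10^5 events for Monte-Carlo
consistency (3-SE bands), exhaustive 2·L classification on 300-bp
plasmids for oracle equivalence, 200 reads per configuration for caller
round-trips, 1,000 events/designs for structural invariants. Stochastic
tests fix seed 0. Rounding: banker's vs half-up is immaterial for the
3890 example (3890.18); `round()` is used and tested. Ties in flank
mapping are reported as ambiguity, not broken. Degenerate inputs (empty
libraries, empty summaries) warn or raise typed errors
(`ParameterError`, `ConfigurationError`, …) rather than returning
silent defaults.

## Known limitations

* No fluorescence, expression, maturation-temperature or turnover
  modelling: `in_frame_candidate` is a sequence-level superset of
  bench-positive colonies.
* No Tn5 sequence preference; the uniform model is the stated
  assumption of the method, not a measured insertion bias.
* The junction caller is substitution-only and single-read; no indel
  alignment, quality trimming, or consensus.
* GenBank support reads the first record only; donor amplicons are
  always blunt linear molecules.
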