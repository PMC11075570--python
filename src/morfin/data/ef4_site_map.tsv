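---
target: EF4
target_length_codons: 599
total_experiments: 159
provenance: enumerated subset; only insertion sites whose recovery counts were
  published as text are included, so per-site counts need not sum to the
  experiment total
domains:
- label: domain1
  start: 1
  end: 188
- label: domain2
  start: 189
  end: 281
- label: domain3
  start: 291
  end: 371
- label: domain4
  start: 398
  end: 486
- label: c_terminal
  start: 487
  end: 599
---
codon	count
128	20
129	2
167	2
168	13
169	1
282	1
283	5
284	1
292	2
293	1
294	4
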